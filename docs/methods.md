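# Methods

## Codon substitution model

The substitution process runs over the 61 sense codons of the standard
genetic code (NCBI table 1; other tables selectable). The instantaneous
rate from codon *i* to *j* is

    q_ij = π_j · κ^[i→j is a transition] · ω_c^[i→j is nonsynonymous]

for codons differing at exactly one position, and 0 for multi-position
changes and changes into stop codons. `π` is the equilibrium codon
distribution, `κ` the transition/transversion rate ratio, and `ω_c` the
nonsynonymous/synonymous rate ratio of branch class *c*. Q is normalized so
that one unit of branch length is one expected substitution per codon site
(`−Σ_i π_i q_ii = 1`), the PAML convention. The model is time-reversible
(`π_i q_ij = π_j q_ji`), so transition matrices `exp(Qt)` are computed by
the symmetric spectral decomposition `Q = D⁻¹ U Λ Uᵀ D`, `D = diag(√π)` —
one `eigh` per ω class per likelihood evaluation, after which `P(t)` for
every branch is two matrix products. Reversibility also means the root
placement is immaterial (verified as the rerooting invariance test).

Likelihoods use Felsenstein pruning over site patterns (identical codon
columns are collapsed and weighted). Cells that are not a sense codon —
gap-containing or otherwise ambiguous codons, and stop-containing cells
masked at construction — contribute a partial-likelihood vector of ones
(full marginalization). Per-node rescaling guards against underflow on
larger trees. The pruning implementation is checked against an independent
oracle that sums over every joint assignment of interior-node states on
trees of up to 4 leaves.

### Equilibrium frequencies

`π` is estimated from data counts, not optimized: `equal` (1/61), `F3x4`
(position-specific nucleotide frequencies, products renormalized over sense
codons) or `F61` (codon counts). The default is F3x4, PAML's default for
this model family. Zero frequencies are floored at 1e-8 and renormalized so
the spectral decomposition stays defined for codons unobserved in a sample;
at the alignment sizes used here the perturbation is far below estimation
noise.

### ML fitting

`fit_codon_model` maximizes the likelihood over κ, one ω per branch class,
and all branch lengths, by bounded L-BFGS-B on log-transformed parameters.
Bounds (log scale): κ ∈ [1e-3, 100], ω ∈ [1e-6, 50], t ∈ [1e-8, 20].
Convergence: relative lnL change < 1e-8, at most 500 iterations;
non-convergence flags the result rather than raising. The starting point is
fixed and documented — κ = 2, ω = 0.4 per class, branch lengths from the
input tree (0.1 where absent) — so a given input always produces the same
fit. κ and individual ω values can be pinned; pinned parameters leave the
free-parameter count. `n_params = (#branches) + 1 + (#ω classes)` when
nothing is pinned, and `AIC = 2·n_params − 2·lnL`.

### dS/dN branch decomposition

Branch lengths are split as `dN = t·ρ_N`, `dS = t·ρ_S`, where ρ_N (ρ_S) is
the nonsynonymous (synonymous) fraction of the equilibrium substitution
flux `π_i q_ij` under that branch's fitted Q. This closed-form partition is
exact under the model, sums to t by construction, and avoids stochastic
ancestral-state reconstruction; it is the package's own choice of
decomposition for the "synonymous tree / nonsynonymous tree" display.
The reported S and N site counts are the mutational-opportunity fractions
(flux at ω = 1 under the fitted κ and π) scaled to 3 sites per codon.

## Inactivation dating

With a focal clade (the avian lineage carrying the pseudogene) marked on a
fixed topology, five branch models are fitted: one-ω; two-ω *early* (stem +
crown share ω₁); two-ω *late* (crown only); three-ω
(background / stem / crown — the natural refinement that distinguishes the
two timing hypotheses, since no finer split is identifiable from the
question); and free-ω (every branch its own class). Candidates are ranked
by Akaike weight; the 95% confidence set keeps the top-weighted models
until the cumulative weight reaches 0.95, including boundary ties
(conservative — the excluded weight never exceeds 0.05). The verdict is
`early`/`late` only when exactly one timing model survives in the
confidence set, otherwise `indeterminate`; the full table is always
reported because near-neutral data rarely excludes either timing model
decisively, and the ω estimates themselves carry much of the evidence.

## Pseudogene lesion scan

Lesion detection consumes a *given* pairwise alignment of candidate versus
functional reference CDS (the aligner is external and swappable, keeping
the scan deterministic). The reference reading frame is projected through
the alignment onto the candidate: in-frame candidate codons that are stops
(where the reference codon is not) are premature stops, indexed by
reference codon; gap runs with length ≢ 0 (mod 3) are frameshifts,
positioned at the candidate coordinate of the first inserted/deleted base
(0-based, half-open everywhere). In-frame indels are recorded nowhere — they
do not disrupt the frame. Splice checks are motif-only: GT after the donor,
AG before the acceptor, the same dinucleotide rule used to recognize intron
remnants in degenerate loci. Fragment matching translates all six frames
and locally aligns them (BLOSUM62) against a reference protein — a
candidate-locus scan, not a genome-wide homology search.

## Gene dosage (2^−ΔΔCt)

ΔCt = mean Ct(target) − mean Ct(reference gene) per sample; relative
quantity 2^−(ΔCt − calibrator); replicate SDs combine in quadrature on the
ΔCt scale and are reported, not used for calls. Amplification efficiency is
fixed at the ideal 2.0 (no efficiency correction), matching the assay's
standard form. The female/male ratio of relative copy numbers classifies
sex linkage: ratio ∈ [1.6, 2.5] → X-linked (heterologous region), ratio ∈
[0.8, 1.25] → autosomal or pseudoautosomal, otherwise ambiguous. The bands
are this package's interpretation rule for "approximately 2:1" versus
"approximately 1:1" — chosen to separate a 2-fold from a 1-fold signal with
a guard gap, and configurable.

## Bisulfite methylation

Unmethylated C reads as T after conversion; 5-methyl-C stays C. Calls are
made at plus-strand reference CpGs (clones are plus-strand PCR amplicons;
other bases/gaps give `missing`, which is excluded from clone-fraction
denominators). Conversion efficiency per clone is the fraction of non-CpG
reference cytosines read as T; clones below 0.95 are excluded from
summaries (a standard QC practice; the threshold is configurable, and 1.0
is reported when a clone has no informative non-CpG C). A clone is
*hypermethylated* when its methylated-CpG fraction is ≥ 0.5 (inclusive,
configurable) — a binary per-clone classification invented here to
quantify the "roughly half the clones" pattern that one inactivated X
produces in female somatic tissue.

## Synthetic data

The generators produce data with exactly the structure each analysis
assumes, which is what passing tests demonstrate — and no more:

- **Codon alignments** evolve by exact transition-matrix sampling (root
  from π, each branch by a categorical draw from `exp(Q_c t)` rows). No
  indels, no rate variation across sites, no alignment error; real
  alignments violate all three.
- **Pseudogene degradation** injects premature stops (default TAA),
  frameshift indels and splice-dinucleotide mutations at stated
  coordinates, returning the ground-truth lesion report *and* the exact
  candidate/reference alignment. Random lesion sets keep a 1-nt buffer
  between indels: adjacent indels coalesce into a single gap run in any
  alignment and are unrecoverable as separate events in principle.
- **Ct tables** follow the ideal model Ct = 30 − log₂(copies) + N(0, σ)
  (baseline 30 cycles for a single copy — arbitrary, fixed, and cancelled
  by the ΔΔCt arithmetic). Real assays add efficiency and pipetting
  structure the model omits.
- **Bisulfite clones** draw an allele uniformly per clone (default 10
  clones per sample, the typical colony count per sample), convert in
  silico, and optionally add uniform per-base error. PCR bias and chimeras
  are not modeled.

All randomness flows from one explicit seed per generator call; simulated
alignments carry a truth record (sidecar JSON in the drivers/CLI) with the
generating parameters.

## Problem sizes and defaults in the shipped analyses

The drivers and checks use a 5-taxon amniote-like topology (two mammals,
two birds as the focal clade, one squamate outgroup) with 500-codon
alignments for model-selection runs and 1000 codons for single-ω recovery —
sizes at which ω is recovered with median absolute error ≤ 0.1 and the
generating timing regime wins the weight comparison in the majority of
replicates, while a full five-model selection completes in a few seconds.
Dosage checks use 3 replicates (triplicate reactions); methylation
convergence checks use hundreds of clones where a converged fraction is the
quantity of interest, and 10 clones where the per-sample display is.

## Known limitations

- Branch models only: no site- or branch-site ω heterogeneity, no
  Γ-distributed rates, no protein-model likelihoods, no topology search or
  bootstrap.
- F3x4/F61 frequencies are plug-in counts, as is conventional; their
  sampling error is not propagated into AIC.
- The rooted-tree parameterization leaves the two root-adjacent branch
  lengths individually unidentifiable under reversibility (only their sum
  matters); fits are still deterministic, and all reported quantities are
  functions of identifiable combinations.
- The ΔΔCt module assumes perfect doubling; no standard-curve efficiency
  correction.
- Methylation calling is plus-strand, alignment-given; there is no read
  mapping and no differential-methylation statistics.
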