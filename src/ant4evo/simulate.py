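"""Synthetic data generators for every stage of the pipeline.

Each generator reproduces the statistical structure its downstream analysis
assumes: codon sequences evolved along a class-labeled tree by exact
transition-matrix sampling, pseudogenes built by injecting known lesions
into a clean CDS (with the matching ground-truth report for round-trip
tests), Ct tables under the ideal 2^-ddCt model, and bisulfite clones drawn
from allele methylation patterns. All randomness flows from one explicit
seed per call.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .codon import CodonModelParams, build_rate_matrix, _Spectral
from .methylation import BisulfiteClone, bisulfite_convert, cpg_positions
from .pseudogene import Frameshift, LesionReport, SpliceDefect
from .seqio import CodonAlignment, GeneticCode, STANDARD_CODE
from .trees import Tree, parse_newick

# Ct of a single-copy template; arbitrary but fixed so tables are reproducible
CT_BASELINE = 30.0


@dataclass
class SimTreeSpec:
    newick: str  # with #k branch-class marks
    omega_by_class: list[float]
    kappa: float = 2.0
    n_codons: int = 500
    codon_freqs: np.ndarray | None = None  # default: equal over sense codons
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")

    def tree(self) -> Tree:
        return parse_newick(self.newick)


@dataclass
class SimTruth:
    """Generating parameters, stored alongside every simulated alignment."""

    newick: str
    omega_by_class: list[float]
    kappa: float
    n_codons: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _sample_transitions(
    P: np.ndarray, parent_states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw child states site-by-site from rows of P selected by parent state."""
    u = rng.random(len(parent_states))
    child = np.empty_like(parent_states)
    for s in np.unique(parent_states):
        mask = parent_states == s
        cdf = np.cumsum(P[s])
        cdf[-1] = 1.0
        child[mask] = np.searchsorted(cdf, u[mask], side="right")
    return np.minimum(child, P.shape[0] - 1)


def simulate_codon_alignment(
    spec: SimTreeSpec, code: GeneticCode = STANDARD_CODE
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve codons along the tree: root from pi, each branch via exp(Q t)."""
    tree = spec.tree()
    K = tree.n_classes
    if K > len(spec.omega_by_class):
        raise ValueError(
            f"tree uses {K} branch classes but only "
            f"{len(spec.omega_by_class)} omega values given"
        )
    pi = (
        np.full(code.n, 1.0 / code.n)
        if spec.codon_freqs is None
        else np.asarray(spec.codon_freqs, dtype=float)
    )
    params = CodonModelParams(spec.kappa, np.asarray(spec.omega_by_class, float), pi, "explicit")
    spectral = [
        _Spectral(build_rate_matrix(params, k, code).Q, pi)
        for k in range(len(spec.omega_by_class))
    ]
    rng = np.random.default_rng(spec.seed)
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(code.n, size=spec.n_codons, p=pi)
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        P = spectral[node.cls].transition(node.length)
        P = P / P.sum(axis=1, keepdims=True)
        states[id(node)] = _sample_transitions(P, states[id(node.parent)], rng)
    taxa = tree.leaf_names
    codons = [
        [code.sense_codons[s] for s in states[id(tree.find(name))]] for name in taxa
    ]
    truth = SimTruth(
        spec.newick, list(map(float, spec.omega_by_class)), spec.kappa, spec.n_codons, spec.seed
    )
    return CodonAlignment(taxa, codons), truth


@dataclass
class DegradeSpec:
    """Lesions to inject into a clean coding sequence.

    Coordinates refer to the input CDS (exonic frame): stop injections by
    codon index, frameshifts by nucleotide position. Splice mutations apply
    to the ends of ``intron_span`` when the input is genomic (exon-intron-
    exon); the coding coordinates then refer to the exon-concatenated
    sequence.
    """

    stop_codon_indices: list[int] = field(default_factory=list)
    frameshifts: list[tuple[int, int, str]] = field(default_factory=list)  # (pos, len, type)
    splice_mutations: list[tuple[str, str]] = field(default_factory=list)  # (role, dinuc)
    intron_span: tuple[int, int] | None = None
    stop_codon: str = "TAA"
    seed: int = 0

    def __post_init__(self):
        for _, length, kind in self.frameshifts:
            if length % 3 == 0:
                raise ValueError("frameshift lengths must not be divisible by 3")
            if kind not in ("insertion", "deletion"):
                raise ValueError(f"unknown indel type {kind!r}")
        for role, dinuc in self.splice_mutations:
            if role not in ("donor", "acceptor"):
                raise ValueError(f"splice role must be donor/acceptor, got {role!r}")
            if len(dinuc) != 2:
                raise ValueError("splice mutation must be a dinucleotide")


def degrade_to_pseudogene(
    cds: str, spec: DegradeSpec, code: GeneticCode = STANDARD_CODE
) -> tuple[str, LesionReport, tuple[str, str]]:
    """Inject lesions, returning (sequence, ground-truth report, aligned pair).

    The aligned pair is (degraded exonic sequence, original exonic CDS) with
    gaps marking the injected indels — exactly the input detect_lesions
    expects, so generator and scanner round-trip. Lesions must not overlap
    (a stop injection occupies its 3-nt codon).
    """
    cds = cds.upper()
    rng = np.random.default_rng(spec.seed)
    if spec.intron_span is not None:
        istart, iend = spec.intron_span
        if not (0 <= istart < iend <= len(cds)):
            raise ValueError(f"intron span {spec.intron_span} out of bounds")
        exonic = cds[:istart] + cds[iend:]
        intron = cds[istart:iend]
    else:
        exonic = cds
        intron = ""

    spans: list[tuple[int, int, str]] = []  # (start, end, kind) on exonic coords
    for idx in spec.stop_codon_indices:
        if not 0 <= 3 * idx + 3 <= len(exonic):
            raise ValueError(f"stop codon index {idx} out of bounds")
        spans.append((3 * idx, 3 * idx + 3, "stop"))
    for pos, length, kind in spec.frameshifts:
        end = pos + (length if kind == "deletion" else 0)
        if not 0 <= pos <= len(exonic) or end > len(exonic):
            raise ValueError(f"frameshift at {pos} out of bounds")
        spans.append((pos, max(end, pos + 1), kind))
    spans.sort()
    for (s1, e1, k1), (s2, e2, k2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping lesions at {s1}-{e1} and {s2}-{e2}")

    report = LesionReport("synthetic")
    bases = "ACGT"
    # apply substitution lesions first (coordinates unaffected)
    seq = list(exonic)
    for idx in spec.stop_codon_indices:
        stop = spec.stop_codon
        if code.is_stop("".join(seq[3 * idx : 3 * idx + 3])):
            raise ValueError(f"codon {idx} is already a stop")
        seq[3 * idx : 3 * idx + 3] = list(stop)
        report.premature_stops.append((idx, stop))
    # apply indels in ascending order, tracking the coordinate shift
    cand_rows: list[str] = []
    ref_rows: list[str] = []
    prev = 0
    shift = 0
    for pos, length, kind in sorted(spec.frameshifts):
        cand_rows.append("".join(seq[prev:pos]))
        ref_rows.append(exonic[prev:pos])
        if kind == "insertion":
            ins = "".join(rng.choice(list(bases), size=length))
            cand_rows.append(ins)
            ref_rows.append("-" * length)
            report.frameshifts.append(Frameshift(pos + shift, length, "insertion"))
            shift += length
            prev = pos
        else:
            cand_rows.append("-" * length)
            ref_rows.append(exonic[pos : pos + length])
            report.frameshifts.append(Frameshift(pos + shift, length, "deletion"))
            shift -= length
            prev = pos + length
    cand_rows.append("".join(seq[prev:]))
    ref_rows.append(exonic[prev:])
    cand_aln = "".join(cand_rows)
    ref_aln = "".join(ref_rows)
    degraded_exonic = cand_aln.replace("-", "")

    report.premature_stops.sort()
    report.frameshifts.sort(key=lambda f: f.position)

    if spec.intron_span is not None:
        mutated_intron = intron
        for role, dinuc in spec.splice_mutations:
            if role == "donor":
                mutated_intron = dinuc + mutated_intron[2:]
                if dinuc != "GT":
                    report.splice_defects.append(SpliceDefect("donor", dinuc))
            else:
                mutated_intron = mutated_intron[:-2] + dinuc
                if dinuc != "AG":
                    report.splice_defects.append(SpliceDefect("acceptor", dinuc))
        exon1_len = spec.intron_span[0]
        # exon1 length in the degraded sequence, shifted by indels before it
        d_exon1 = exon1_len + sum(
            (l if k == "insertion" else -l)
            for p, l, k in spec.frameshifts
            if p < exon1_len
        )
        out_seq = degraded_exonic[:d_exon1] + mutated_intron + degraded_exonic[d_exon1:]
    else:
        if spec.splice_mutations:
            raise ValueError("splice mutations require an intron_span")
        out_seq = degraded_exonic

    return out_seq, report, (cand_aln, ref_aln)


def random_degrade_spec(
    cds_len_codons: int, rng: np.random.Generator, max_lesions: int = 4
) -> DegradeSpec:
    """Random separated stop/frameshift lesion set for round-trip tests.

    Indel spans keep a 1-nt buffer from each other: adjacent indels would
    coalesce into a single gap run in the pairwise alignment, making the
    injected lesion list unrecoverable in principle.
    """
    n_stops = int(rng.integers(0, max_lesions // 2 + 1))
    n_indels = int(rng.integers(0, max_lesions // 2 + 1))
    taken: set[int] = set()
    stops = []
    # keep lesions off the first and last codon
    candidates = list(range(1, cds_len_codons - 1))
    rng.shuffle(candidates)
    for idx in candidates[:n_stops]:
        if taken & set(range(3 * idx, 3 * idx + 3)):
            continue
        stops.append(idx)
        taken |= set(range(3 * idx, 3 * idx + 3))
    frameshifts = []
    for _ in range(n_indels):
        length = int(rng.choice([1, 2, 4, 5]))
        kind = str(rng.choice(["insertion", "deletion"]))
        pos = int(rng.integers(3, 3 * cds_len_codons - 6))
        end = pos + (length if kind == "deletion" else 1)
        if end > 3 * cds_len_codons - 3:
            continue
        span = set(range(pos - 1, end + 1))
        if taken & span:
            continue
        frameshifts.append((pos, length, kind))
        taken |= span
    return DegradeSpec(
        stop_codon_indices=sorted(stops),
        frameshifts=sorted(frameshifts),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def random_cds(n_codons: int, rng: np.random.Generator, code: GeneticCode = STANDARD_CODE) -> str:
    """Uniform-random sense codons, ATG start, no internal stops."""
    sense = [c for c in code.sense_codons]
    body = rng.choice(len(sense), size=n_codons - 1)
    return "ATG" + "".join(sense[i] for i in body)


def simulate_ct_table(
    copy_numbers: dict[str, dict[str, float]],  # sex -> gene -> copies
    reference_gene: str = "actb",
    reference_copies: float = 2.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Long Ct table under the ideal model: Ct = baseline - log2(copies) + noise.

    The reference gene is generated identically for every sex at
    ``reference_copies``. Columns: sample, sex, gene, replicate, ct.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sex, genes in copy_numbers.items():
        merged = dict(genes)
        merged.setdefault(reference_gene, reference_copies)
        for gene, copies in merged.items():
            if copies <= 0:
                raise ValueError(f"{sex}/{gene}: copy number must be positive")
            for rep in range(n_replicates):
                ct = CT_BASELINE - np.log2(copies) + rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "sample": f"{sex}_sample",
                        "sex": sex,
                        "gene": gene,
                        "replicate": rep,
                        "ct": float(ct),
                    }
                )
    return pd.DataFrame(rows)


def simulate_bisulfite_clones(
    reference: str,
    allele_states: list[set[int]],  # per allele: methylated CpG positions
    n_clones: int = 10,
    error_rate: float = 0.0,
    seed: int = 0,
    sample: str = "sample",
    sex: str = "NA",
) -> list[BisulfiteClone]:
    """Clones drawn uniformly from alleles, bisulfite-converted, with optional
    per-base sequencing error (random substitution)."""
    reference = reference.upper()
    valid = set(cpg_positions(reference))
    for i, allele in enumerate(allele_states):
        if not set(allele) <= valid:
            raise ValueError(
                f"allele {i} methylates non-CpG positions {sorted(set(allele) - valid)}"
            )
    if not allele_states:
        raise ValueError("need at least one allele pattern")
    rng = np.random.default_rng(seed)
    clones = []
    bases = np.array(list("ACGT"))
    for k in range(n_clones):
        allele = allele_states[int(rng.integers(len(allele_states)))]
        seq = bisulfite_convert(reference, set(allele))
        if error_rate > 0:
            arr = np.array(list(seq))
            hits = rng.random(len(arr)) < error_rate
            if hits.any():
                arr[hits] = bases[rng.integers(0, 4, size=int(hits.sum()))]
            seq = "".join(arr)
        clones.append(BisulfiteClone(f"clone{k:02d}", sample, sex, seq))
    return clones
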