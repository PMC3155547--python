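#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes, under results/data/:
  - codon alignments (500 codons, 5 amniote-like taxa) simulated under three
    selection regimes: purifying everywhere (omega=0.2), early relaxation
    (avian stem + crown at omega=1), late relaxation (avian crown only)
  - a neutral alignment (omega=1 everywhere, 1000 codons)
  - a synthetic pseudogene: a clean CDS degraded with one nonsense codon,
    a 2-bp frameshift insertion and a donor-site GT->AT mutation
  - noiseless genomic-qPCR Ct tables for an X-linked-like and an
    autosomal-like gene
  - bisulfite clone sets: a 50/50 methylated/unmethylated allele mixture
    (female-mouse-like) and fully unmethylated (anole-like)
"""
from pathlib import Path

import numpy as np

import ant4evo as a
from ant4evo.seqio import SequenceRecord, alignment_from_codons, write_fasta

SEED = 20110812
OUT = Path(__file__).resolve().parent.parent / "results" / "data"

AMNIOTE = "((human:0.2,mouse:0.2):0.05,(chicken:0.25,finch:0.25):0.05,anole:0.3);"
EARLY = "((human:0.2,mouse:0.2):0.05,(chicken:0.25 #1,finch:0.25 #1):0.05 #1,anole:0.3);"
LATE = "((human:0.2,mouse:0.2):0.05,(chicken:0.25 #1,finch:0.25 #1):0.05,anole:0.3);"

PROMOTER = "ACGTACGTACGTACGTCCACACGTTACGGA"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    regimes = {
        "purifying": (AMNIOTE, [0.2], 500),
        "early": (EARLY, [0.1, 1.0], 500),
        "late": (LATE, [0.1, 1.0], 500),
        "neutral": (AMNIOTE, [1.0], 1000),
    }
    for i, (name, (nwk, omegas, n)) in enumerate(regimes.items()):
        spec = a.SimTreeSpec(nwk, omegas, kappa=2.0, n_codons=n, seed=SEED + i)
        aln, truth = a.simulate_codon_alignment(spec)
        write_fasta(alignment_from_codons(aln).records, OUT / f"codon_{name}.fasta")
        (OUT / f"codon_{name}.tree.nwk").write_text(nwk + "\n")
        truth.to_json(OUT / f"codon_{name}.truth.json")
        print(f"codon alignment '{name}': {aln.n_taxa} taxa x {aln.n_sites} codons, "
              f"omega={omegas}")

    rng = np.random.default_rng(SEED)
    exon1 = a.random_cds(20, rng)
    exon2 = a.random_cds(20, rng)[3:]
    intron = "GTAAGTATCT" + "".join(rng.choice(list("ACGT"), size=20)) + "TTTCAG"
    genomic = exon1 + intron + exon2
    spec = a.DegradeSpec(
        stop_codon_indices=[10],
        frameshifts=[(45, 2, "insertion")],
        splice_mutations=[("donor", "AT")],
        intron_span=(len(exon1), len(exon1) + len(intron)),
        seed=SEED,
    )
    degraded, truth_report, pair = a.degrade_to_pseudogene(genomic, spec)
    write_fasta([SequenceRecord("functional_cds", exon1 + exon2)], OUT / "reference_cds.fasta")
    write_fasta([SequenceRecord("pseudogene", degraded)], OUT / "pseudogene.fasta")
    write_fasta(
        [SequenceRecord("candidate", pair[0]), SequenceRecord("reference", pair[1])],
        OUT / "pseudogene_pair.fasta",
    )
    import json

    (OUT / "pseudogene_truth.json").write_text(json.dumps(truth_report.to_dict(), indent=2))
    # intron span in degraded-genomic coordinates: the 2-bp insertion sits
    # upstream of the intron and shifts it
    d_exon1 = len(exon1) + sum(
        (l if k == "insertion" else -l) for p, l, k in spec.frameshifts if p < len(exon1)
    )
    (OUT / "pseudogene_intron_span.json").write_text(
        json.dumps({"intron_span": [d_exon1, d_exon1 + len(intron)]})
    )
    print(f"pseudogene: stop@codon10 + 2bp insertion + donor GT->AT "
          f"({len(genomic)} nt genomic)")

    tables = {
        "x_linked": {"F": {"ant2": 2}, "M": {"ant2": 1}},
        "autosomal": {"F": {"ant2": 2}, "M": {"ant2": 2}},
    }
    for name, copies in tables.items():
        df = a.simulate_ct_table(copies, noise_sd=0.0, n_replicates=3, seed=SEED)
        df.to_csv(OUT / f"ct_{name}.tsv", sep="\t", index=False)
        print(f"Ct table '{name}': {len(df)} rows")

    cpgs = set(a.cpg_positions(PROMOTER))
    mixtures = {"mouse_female_like": [cpgs, set()], "anole_like": [set()]}
    write_fasta([SequenceRecord("promoter", PROMOTER)], OUT / "promoter.fasta")
    for name, alleles in mixtures.items():
        clones = a.simulate_bisulfite_clones(PROMOTER, alleles, n_clones=10, seed=SEED)
        write_fasta(
            [SequenceRecord(c.clone_id, c.seq) for c in clones],
            OUT / f"clones_{name}.fasta",
        )
        print(f"bisulfite clones '{name}': 10 clones, {len(cpgs)} CpGs")


if __name__ == "__main__":
    main()
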