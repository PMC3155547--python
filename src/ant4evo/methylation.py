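"""Bisulfite-sequencing methylation calls on cloned PCR amplicons.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T)
while 5-methylcytosine stays C. Reading a converted clone against the
unconverted reference therefore gives a per-CpG methylation call (C =
methylated, T = unmethylated), and the non-CpG cytosines — which should
essentially all convert — measure conversion efficiency per clone. Clones
are assumed plus-strand (cloned PCR amplicons); only plus-strand CpGs are
called.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class MethylationError(ValueError):
    pass


@dataclass
class BisulfiteClone:
    clone_id: str
    sample: str
    sex: str
    seq: str  # aligned to the reference (same coordinates)

    def __post_init__(self):
        self.seq = self.seq.upper()


@dataclass
class CpGCall:
    position: int  # 0-based reference coordinate of the CpG cytosine, plus strand
    state: str  # methylated | unmethylated | missing


@dataclass
class PromoterSummary:
    sample: str
    n_clones: int  # clones passing the conversion filter
    n_filtered: int
    per_cpg_fraction: dict[int, float]
    per_clone_fraction: dict[str, float]
    hypermethylated_fraction: float
    mean_conversion: float


def cpg_positions(reference: str) -> list[int]:
    reference = reference.upper()
    return [i for i in range(len(reference) - 1) if reference[i : i + 2] == "CG"]


def bisulfite_convert(seq: str, methylated_positions: set[int]) -> str:
    """In-silico conversion: every C outside the methylated set becomes T."""
    seq = seq.upper()
    for pos in methylated_positions:
        if pos < 0 or pos >= len(seq) or seq[pos] != "C":
            raise MethylationError(f"methylated position {pos} is not a C")
    return "".join(
        "T" if base == "C" and i not in methylated_positions else base
        for i, base in enumerate(seq)
    )


def call_clone(
    reference: str, clone: BisulfiteClone
) -> tuple[list[CpGCall], float]:
    """Per-CpG calls and the clone's bisulfite conversion efficiency.

    At each reference CpG cytosine: clone C -> methylated, T -> unmethylated,
    anything else (gap, N) -> missing. Conversion efficiency is the fraction
    of non-CpG reference cytosines read as T, over positions where the clone
    reads C or T (1.0 when there are none to judge by).
    """
    reference = reference.upper()
    if len(clone.seq) != len(reference):
        raise MethylationError(
            f"clone {clone.clone_id}: length {len(clone.seq)} != reference {len(reference)}"
        )
    cpgs = set(cpg_positions(reference))
    calls = []
    for pos in sorted(cpgs):
        base = clone.seq[pos]
        state = {"C": "methylated", "T": "unmethylated"}.get(base, "missing")
        calls.append(CpGCall(pos, state))
    converted = total = 0
    for i, ref_base in enumerate(reference):
        if ref_base == "C" and i not in cpgs:
            base = clone.seq[i]
            if base in ("C", "T"):
                total += 1
                converted += base == "T"
    efficiency = converted / total if total else 1.0
    return calls, efficiency


def clone_methylation_fraction(calls: list[CpGCall]) -> float:
    """Fraction methylated among called (non-missing) CpGs."""
    called = [c for c in calls if c.state != "missing"]
    if not called:
        raise MethylationError("clone has no called CpGs")
    return sum(c.state == "methylated" for c in called) / len(called)


def summarize_promoter(
    clones: list[BisulfiteClone],
    reference: str,
    min_conversion: float = 0.95,
    hyper_threshold: float = 0.5,
    sample: str = "",
) -> PromoterSummary:
    """Promoter-level summary over clones passing the conversion filter.

    A clone is hypermethylated iff its methylated-CpG fraction is >=
    ``hyper_threshold`` (inclusive). Clones converting fewer than
    ``min_conversion`` of their non-CpG cytosines are excluded and counted.
    """
    if not clones:
        raise MethylationError("no clones provided")
    reference = reference.upper()
    results = []
    efficiencies = {}
    for clone in clones:
        calls, eff = call_clone(reference, clone)
        efficiencies[clone.clone_id] = eff
        if eff >= min_conversion:
            results.append((clone, calls, eff))
    if not results:
        raise MethylationError(
            f"all clones failed the conversion filter (>= {min_conversion}); "
            f"per-clone efficiencies: {efficiencies}"
        )
    positions = cpg_positions(reference)
    per_cpg: dict[int, float] = {}
    for pos in positions:
        states = [
            next(c.state for c in calls if c.position == pos)
            for _, calls, _ in results
        ]
        called = [s for s in states if s != "missing"]
        per_cpg[pos] = (
            sum(s == "methylated" for s in called) / len(called) if called else float("nan")
        )
    per_clone = {
        clone.clone_id: clone_methylation_fraction(calls) for clone, calls, _ in results
    }
    hyper = sum(f >= hyper_threshold for f in per_clone.values()) / len(per_clone)
    mean_eff = sum(eff for _, _, eff in results) / len(results)
    return PromoterSummary(
        sample=sample or (clones[0].sample if clones else ""),
        n_clones=len(results),
        n_filtered=len(clones) - len(results),
        per_cpg_fraction=per_cpg,
        per_clone_fraction=per_clone,
        hypermethylated_fraction=hyper,
        mean_conversion=mean_eff,
    )


def call_matrix(clones: list[BisulfiteClone], reference: str) -> pd.DataFrame:
    """Clones x CpG-position matrix (1 methylated, 0 unmethylated, NA missing),
    the layout behind lollipop plots."""
    positions = cpg_positions(reference.upper())
    rows = {}
    for clone in clones:
        calls, _ = call_clone(reference, clone)
        rows[clone.clone_id] = {
            c.position: {"methylated": 1.0, "unmethylated": 0.0}.get(c.state, float("nan"))
            for c in calls
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=positions)
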