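"""AIC / Akaike-weight model comparison and the pseudogene-inactivation test.

The inactivation test asks when purifying selection on a focal clade (the
avian lineage carrying the degraded gene) was relaxed. Five nested codon
branch models are fitted on a fixed topology:

  one-omega        a single omega for the whole tree
  two-omega-early  stem of the focal clade + branches inside it share omega_1
  two-omega-late   only branches strictly inside the focal clade get omega_1
  three-omega      background / stem / within-clade each their own omega
  free-omega       every branch its own omega

Relaxation on the stem branch (early model preferred) dates the loss before
the focal clade's crown divergence; relaxation only within the clade (late
model) dates it after. Models are compared by Akaike weights,
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) with Delta_i = AIC_i - min AIC,
and by membership in the 95% confidence set (smallest-weight models whose
total excluded weight stays <= 0.05 are dropped).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import FitResult, fit_codon_model
from .seqio import CodonAlignment, GeneticCode, STANDARD_CODE
from .trees import Tree, TreeError

TIMING_MODELS = ("two-omega-early", "two-omega-late")


@dataclass
class ModelCandidate:
    name: str
    tree: Tree  # topology with this candidate's branch-class labels
    fit: FitResult


def akaike_weights(fits: dict[str, FitResult] | list[FitResult]) -> pd.DataFrame:
    """Akaike table: aic, delta = aic - min aic, weight; sorted by weight.

    Weights are invariant to adding a constant to every AIC; ties produce
    equal weights.
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f"model{i}", f) for i, f in enumerate(fits)]
    if len(items) < 2:
        raise ValueError("need at least 2 candidate models")
    aics = np.array([f.aic for _, f in items], dtype=float)
    if np.any(~np.isfinite(aics)):
        raise ValueError("non-finite AIC in candidate set")
    delta = aics - aics.min()
    raw = np.exp(-delta / 2.0)
    weights = raw / raw.sum()
    table = pd.DataFrame(
        {
            "name": [n for n, _ in items],
            "lnL": [f.lnL for _, f in items],
            "n_params": [f.n_params for _, f in items],
            "aic": aics,
            "delta": delta,
            "weight": weights,
        }
    ).sort_values(["weight", "name"], ascending=[False, True], kind="stable")
    table["in_confidence_set"] = True
    return table.reset_index(drop=True)


def confidence_set(table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Flag the Akaike confidence set at the given level.

    Candidates sorted by descending weight are included until the cumulative
    weight reaches ``level``; candidates tied (in weight) with the last
    included member are also included, so the excluded-weight sum is always
    <= 1 - level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    table = table.sort_values(
        ["weight", "name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    weights = table["weight"].to_numpy()
    cum = np.cumsum(weights)
    cutoff = int(np.searchsorted(cum, level - 1e-12)) + 1
    cutoff = min(cutoff, len(weights))
    boundary = weights[cutoff - 1]
    included = (np.arange(len(weights)) < cutoff) | np.isclose(weights, boundary)
    out = table.copy()
    out["in_confidence_set"] = included
    return out


@dataclass
class InactivationReport:
    best_model: str
    table: pd.DataFrame
    omega_focal: dict[str, float]
    verdict: str  # early | late | indeterminate
    candidates: dict[str, ModelCandidate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best_model": self.best_model,
            "verdict": self.verdict,
            "omega_focal": self.omega_focal,
            "table": self.table.to_dict(orient="records"),
        }


def _focal_class_maps(tree: Tree, focal_clade: list[str]) -> dict[str, Tree]:
    """The five candidate trees, each with its branch-class labeling."""
    leaf_set = set(focal_clade)
    if not leaf_set <= set(tree.leaf_names):
        missing = sorted(leaf_set - set(tree.leaf_names))
        raise TreeError(f"focal leaves not in tree: {missing}")
    mrca = tree.mrca(sorted(leaf_set))
    clade_leaves = {n.name for n in tree.clade_nodes(mrca) if n.is_leaf}
    if clade_leaves != leaf_set:
        raise TreeError(
            f"focal clade is not monophyletic: MRCA spans {sorted(clade_leaves)}"
        )
    if mrca.parent is None:
        raise TreeError("focal clade cannot be the whole tree")
    stem_id = mrca.id if not mrca.is_leaf else mrca.name
    inside_ids = {n.id for n in tree.clade_nodes(mrca) if n is not mrca}

    def early(n):
        return 1 if (n.id == stem_id or n.id in inside_ids) else 0

    def late(n):
        return 1 if n.id in inside_ids else 0

    def three(n):
        if n.id == stem_id:
            return 1
        return 2 if n.id in inside_ids else 0

    branch_order = {b.id: i for i, b in enumerate(tree.branches())}

    return {
        "one-omega": tree.with_classes(lambda n: 0),
        "two-omega-early": tree.with_classes(early),
        "two-omega-late": tree.with_classes(late),
        "three-omega": tree.with_classes(three),
        "free-omega": tree.with_classes(lambda n: branch_order[n.id]),
    }


def inactivation_test(
    aln: CodonAlignment,
    tree: Tree,
    focal_clade: list[str],
    level: float = 0.95,
    freq_model: str = "f3x4",
    code: GeneticCode = STANDARD_CODE,
) -> InactivationReport:
    """Fit the five-model candidate set and weigh early vs late inactivation.

    The verdict is 'early' or 'late' only when exactly one of the two timing
    models remains in the confidence set; otherwise 'indeterminate' (the raw
    table is always reported, since near-neutral data rarely excludes either
    timing model decisively).
    """
    trees = _focal_class_maps(tree, focal_clade)
    candidates: dict[str, ModelCandidate] = {}
    for name, t in trees.items():
        fit = fit_codon_model(aln, t, freq_model=freq_model, code=code)
        candidates[name] = ModelCandidate(name, t, fit)

    table = confidence_set(
        akaike_weights({n: c.fit for n, c in candidates.items()}), level
    )
    best = table.iloc[0]["name"]

    focal_ids = {n.id for n in tree.clade_nodes(tree.mrca(sorted(focal_clade)))}
    omega_focal: dict[str, float] = {}
    for name, cand in candidates.items():
        omegas = cand.fit.params.omega_by_class
        cls = [b.cls for b in cand.tree.branches() if b.id in focal_ids]
        omega_focal[name] = float(np.mean([omegas[c] for c in cls]))

    in_set = set(table.loc[table["in_confidence_set"], "name"])
    timing_in = [m for m in TIMING_MODELS if m in in_set]
    if len(timing_in) == 1:
        verdict = "early" if timing_in[0] == "two-omega-early" else "late"
    else:
        verdict = "indeterminate"
    return InactivationReport(best, table, omega_focal, verdict, candidates)
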