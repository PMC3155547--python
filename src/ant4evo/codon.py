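"""Goldman–Yang codon substitution model with branch-specific omega.

The instantaneous rate from sense codon i to j is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

for codons differing at exactly one position, 0 otherwise (and 0 into stop
codons, which are excluded from the state space). Q is normalized so one
unit of branch length equals one expected substitution per codon site.
Branches carry an integer class id; each class has its own omega, so the
same machinery covers the single-omega model, two- and three-omega branch
models, and the free-omega model.

Likelihoods use Felsenstein pruning over site patterns; transition matrices
exp(Q t) come from the symmetric spectral decomposition the reversible model
admits, which makes repeated evaluations during ML fitting cheap.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .seqio import CodonAlignment, GeneticCode, STANDARD_CODE
from .trees import Tree

_NUCS = "TCAG"


@dataclass
class CodonModelParams:
    """kappa, per-class omega, and equilibrium codon frequencies."""

    kappa: float
    omega_by_class: np.ndarray  # (K,)
    codon_freqs: np.ndarray  # (61,)
    freq_model: str = "f3x4"

    def __post_init__(self):
        self.omega_by_class = np.asarray(self.omega_by_class, dtype=float)
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError(f"kappa must be positive and finite, got {self.kappa}")
        if np.any(~np.isfinite(self.omega_by_class)) or np.any(self.omega_by_class < 0):
            raise ValueError("omega values must be finite and >= 0")
        if np.any(self.codon_freqs < 0):
            raise ValueError("codon frequencies must be >= 0")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("codon frequencies must sum to 1 within 1e-12")

    @property
    def n_classes(self) -> int:
        return len(self.omega_by_class)


@dataclass
class RateMatrix:
    Q: np.ndarray
    scale: float  # expected substitutions per unit time of the unnormalized matrix


@dataclass
class FitResult:
    lnL: float
    params: CodonModelParams
    branch_lengths: dict[str, float]
    n_params: int
    aic: float
    converged: bool
    n_iterations: int
    tree: Tree | None = None

    def to_dict(self) -> dict:
        return {
            "lnL": self.lnL,
            "kappa": self.params.kappa,
            "omega_by_class": list(map(float, self.params.omega_by_class)),
            "freq_model": self.params.freq_model,
            "branch_lengths": self.branch_lengths,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class BranchSubstitution:
    branch_id: str
    t: float
    dS_len: float
    dN_len: float
    S: float
    N: float


def equilibrium_frequencies(
    aln: CodonAlignment, freq_model: str, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Empirical codon frequencies: 'equal', 'f3x4' or 'f61'.

    F3x4 uses position-specific nucleotide frequencies from the resolved
    cells; F61 uses raw codon counts. Zero frequencies are floored at 1e-8
    (then renormalized) so the reversible spectral decomposition stays
    defined even for codons unobserved in the data.
    """
    freq_model = freq_model.lower()
    n = code.n
    if freq_model == "equal":
        return np.full(n, 1.0 / n)
    cells = [
        c for row in aln.codons for c in row if c in code.codon_index
    ]
    if not cells:
        raise ValueError("no resolved codon cells to estimate frequencies from")
    if freq_model == "f61":
        counts = np.zeros(n)
        for c in cells:
            counts[code.codon_index[c]] += 1
        pi = counts
    elif freq_model == "f3x4":
        pos = np.zeros((3, 4))
        nuc_index = {b: k for k, b in enumerate(_NUCS)}
        for c in cells:
            for p in range(3):
                pos[p, nuc_index[c[p]]] += 1
        pos /= pos.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos[0, nuc_index[c[0]]] * pos[1, nuc_index[c[1]]] * pos[2, nuc_index[c[2]]]
                for c in code.sense_codons
            ]
        )
    else:
        raise ValueError(f"unknown freq_model {freq_model!r}")
    pi = np.maximum(pi, 1e-8)
    return pi / pi.sum()


def build_rate_matrix(
    params: CodonModelParams, class_id: int, code: GeneticCode = STANDARD_CODE
) -> RateMatrix:
    """Normalized GY94 rate matrix for one branch class."""
    if class_id >= params.n_classes:
        raise ValueError(f"class_id {class_id} out of range ({params.n_classes} classes)")
    pi = params.codon_freqs
    if len(pi) != code.n:
        raise ValueError(f"codon_freqs has length {len(pi)}, expected {code.n}")
    omega = params.omega_by_class[class_id]
    R = np.where(code.single_diff, pi[None, :], 0.0)
    R = R * np.where(code.is_transition, params.kappa, 1.0)
    R = R * np.where(code.is_nonsyn, omega, 1.0)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(R)))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total flux)")
    return RateMatrix(R / scale, scale)


class _Spectral:
    """exp(Q t) via the symmetric decomposition of a reversible Q."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        B = Q * d[:, None] / d[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self.w = w
        self.A = U / d[:, None]
        self.Ainv = (U * d[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.w * t)) @ self.Ainv
        np.clip(P, 0.0, None, out=P)
        return P


class LikelihoodEngine:
    """Pattern-compressed pruning likelihood bound to one alignment + tree.

    The topology and branch classes are fixed; kappa, per-class omega, pi
    and branch lengths vary between calls, which is the access pattern of
    ML fitting.
    """

    def __init__(self, aln: CodonAlignment, tree: Tree, code: GeneticCode = STANDARD_CODE):
        self.code = code
        self.tree = tree
        leaf_names = tree.leaf_names
        missing = [t for t in leaf_names if t not in aln.taxa]
        if missing:
            raise KeyError(f"taxa in tree missing from alignment: {missing}")
        idx = aln.subset(leaf_names).indices(code)
        patterns, counts = np.unique(idx, axis=1, return_counts=True)
        self.patterns = patterns  # (n_leaves, n_patterns)
        self.counts = counts.astype(float)
        self.leaf_row = {name: i for i, name in enumerate(leaf_names)}
        self.n_patterns = patterns.shape[1]
        self.n_resolved_sites = int(self.counts[(patterns >= 0).any(axis=0)].sum())
        self.postorder = [n for n in tree.postorder()]
        self.n_classes = tree.n_classes

    def log_likelihood(
        self,
        kappa: float,
        omega_by_class: np.ndarray,
        pi: np.ndarray,
        lengths: dict[str, float] | None = None,
    ) -> float:
        params = CodonModelParams(kappa, omega_by_class, pi, "explicit")
        spectral = [
            _Spectral(build_rate_matrix(params, k, self.code).Q, pi)
            for k in range(self.n_classes)
        ]
        npat, n = self.n_patterns, self.code.n
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for node in self.postorder:
            if node.is_leaf:
                continue
            part = np.ones((npat, n))
            for child in node.children:
                t = child.length if lengths is None else lengths[child.id]
                P = spectral[child.cls].transition(t)
                if child.is_leaf:
                    states = self.patterns[self.leaf_row[child.name]]
                    contrib = np.ones((npat, n))
                    m = states >= 0
                    contrib[m] = P[:, states[m]].T
                else:
                    contrib = partial.pop(id(child)) @ P.T
                part *= contrib
            mx = part.max(axis=1)
            nz = mx > 0
            part[nz] /= mx[nz, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(nz, np.log(np.where(nz, mx, 1.0)), -np.inf)
            partial[id(node)] = part
        if self.tree.root.is_leaf:
            raise ValueError("tree root must be internal")
        site = partial[id(self.tree.root)] @ pi
        with np.errstate(divide="ignore"):
            lnl = float(np.dot(self.counts, np.log(site) + logscale))
        return lnl


def log_likelihood(
    aln: CodonAlignment,
    tree: Tree,
    params: CodonModelParams,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Pruning log-likelihood of a codon alignment on a class-labeled tree."""
    engine = LikelihoodEngine(aln, tree, code)
    return engine.log_likelihood(params.kappa, params.omega_by_class, params.codon_freqs)


_START_KAPPA = 2.0
_START_OMEGA = 0.4
_START_LENGTH = 0.1
_LOG_BOUNDS = {
    "kappa": (math.log(1e-3), math.log(100.0)),
    "omega": (math.log(1e-6), math.log(50.0)),
    "length": (math.log(1e-8), math.log(20.0)),
}


def fit_codon_model(
    aln: CodonAlignment,
    tree: Tree,
    freq_model: str = "f3x4",
    fixed: dict | None = None,
    code: GeneticCode = STANDARD_CODE,
    max_iter: int = 500,
) -> FitResult:
    """ML fit of kappa, per-class omega and branch lengths.

    Frequencies come from counts under ``freq_model`` and are not optimized.
    The optimizer is L-BFGS-B on log-transformed parameters from a fixed
    starting point (kappa=2, omega=0.4, input branch lengths or 0.1), so a
    given input always yields the same fit. ``fixed`` may pin ``kappa``
    (float) and/or entries of ``omega_by_class`` ({class_id: value}).
    Pinned parameters do not count as free in n_params/AIC.
    """
    fixed = fixed or {}
    if len(tree.leaves()) < 3:
        raise ValueError("need at least 3 taxa to fit")
    engine = LikelihoodEngine(aln, tree, code)
    if engine.n_resolved_sites == 0:
        raise ValueError("no resolved codon columns")
    pi = equilibrium_frequencies(aln, freq_model, code)
    K = engine.n_classes
    branches = tree.branches()
    branch_ids = [b.id for b in branches]

    fixed_kappa = fixed.get("kappa")
    fixed_omega: dict[int, float] = dict(fixed.get("omega_by_class", {}))

    names: list[tuple[str, object]] = []
    x0, lo, hi = [], [], []
    if fixed_kappa is None:
        names.append(("kappa", None))
        x0.append(math.log(_START_KAPPA))
        lo.append(_LOG_BOUNDS["kappa"][0]); hi.append(_LOG_BOUNDS["kappa"][1])
    for k in range(K):
        if k not in fixed_omega:
            names.append(("omega", k))
            x0.append(math.log(_START_OMEGA))
            lo.append(_LOG_BOUNDS["omega"][0]); hi.append(_LOG_BOUNDS["omega"][1])
    for b in branches:
        names.append(("length", b.id))
        start = b.length if b.length > 0 else _START_LENGTH
        x0.append(math.log(start))
        lo.append(_LOG_BOUNDS["length"][0]); hi.append(_LOG_BOUNDS["length"][1])

    def unpack(x: np.ndarray):
        kappa = fixed_kappa if fixed_kappa is not None else None
        omegas = np.empty(K)
        for k, v in fixed_omega.items():
            omegas[k] = v
        lengths = {}
        for (kind, key), val in zip(names, x):
            v = math.exp(val)
            if kind == "kappa":
                kappa = v
            elif kind == "omega":
                omegas[key] = v
            else:
                lengths[key] = v
        return kappa, omegas, lengths

    def objective(x: np.ndarray) -> float:
        kappa, omegas, lengths = unpack(x)
        lnl = engine.log_likelihood(kappa, omegas, pi, lengths)
        if not np.isfinite(lnl):
            return 1e12
        return -lnl

    res = minimize(
        objective,
        np.array(x0),
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"ftol": 1e-8, "maxiter": max_iter, "maxfun": 100000},
    )
    kappa, omegas, lengths = unpack(res.x)
    lnl = -float(res.fun)
    n_free = len(names)
    aic = 2.0 * n_free - 2.0 * lnl
    fitted_tree = tree.with_lengths(lengths)
    params = CodonModelParams(kappa, omegas, pi, freq_model)
    return FitResult(
        lnL=lnl,
        params=params,
        branch_lengths={bid: lengths[bid] for bid in branch_ids},
        n_params=n_free,
        aic=aic,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        tree=fitted_tree,
    )


def _flux_fractions(
    params: CodonModelParams, class_id: int, code: GeneticCode
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractions of equilibrium substitution flux."""
    Q = build_rate_matrix(params, class_id, code).Q
    flux = params.codon_freqs[:, None] * Q
    syn = float(flux[code.single_diff & ~code.is_nonsyn].sum())
    non = float(flux[code.single_diff & code.is_nonsyn].sum())
    total = syn + non
    return syn / total, non / total


def decompose_branch_substitutions(
    tree: Tree, params: CodonModelParams, code: GeneticCode = STANDARD_CODE
) -> list[BranchSubstitution]:
    """Split each branch length into synonymous and nonsynonymous parts.

    dN_len = t * rho_N where rho_N is the nonsynonymous fraction of the
    equilibrium substitution flux under that branch's Q (and likewise for
    dS_len), so dS_len + dN_len = t exactly. S and N are model-based site
    counts: 3 * (flux fraction at omega = 1) per codon, the mutational
    opportunity under kappa and pi alone.
    """
    neutral = CodonModelParams(
        params.kappa, np.ones(params.n_classes), params.codon_freqs, params.freq_model
    )
    out = []
    for branch in tree.branches():
        rho_s, rho_n = _flux_fractions(params, branch.cls, code)
        s1, n1 = _flux_fractions(neutral, branch.cls, code)
        out.append(
            BranchSubstitution(
                branch_id=branch.id,
                t=branch.length,
                dS_len=branch.length * rho_s,
                dN_len=branch.length * rho_n,
                S=3.0 * s1,
                N=3.0 * n1,
            )
        )
    return out


def substitution_trees(
    tree: Tree, params: CodonModelParams, code: GeneticCode = STANDARD_CODE
) -> tuple[Tree, Tree]:
    """(dS tree, dN tree): copies with branch lengths replaced by the
    synonymous / nonsynonymous components from the flux decomposition."""
    parts = {b.branch_id: b for b in decompose_branch_substitutions(tree, params, code)}
    ds = tree.with_lengths({k: v.dS_len for k, v in parts.items()})
    dn = tree.with_lengths({k: v.dN_len for k, v in parts.items()})
    return ds, dn
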