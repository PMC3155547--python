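"""Rate-matrix structure, pruning likelihood vs enumeration, ML recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import ant4evo as a
from ant4evo.codon import build_rate_matrix

from conftest import AMNIOTE_NEWICK

CODE = a.STANDARD_CODE


def random_params(seed, n_classes=1):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(61))
    kappa = float(rng.uniform(0.2, 8.0))
    omegas = rng.uniform(0.05, 3.0, size=n_classes)
    return a.CodonModelParams(kappa, omegas, pi)


class TestRateMatrix:
    def test_neutral_equal_case_symmetric_rates(self, equal_pi):
        params = a.CodonModelParams(1.0, np.array([1.0]), equal_pi)
        Q = build_rate_matrix(params, 0).Q
        off = Q[~np.eye(61, dtype=bool)]
        positive = off[off > 0]
        # every allowed single-nt change has the same rate under kappa=omega=1, equal pi
        assert np.allclose(positive, positive[0])
        assert np.allclose(Q, Q.T)

    def test_kappa_omega_ratio(self, equal_pi):
        # AAA->AAG synonymous transition vs AAA->AAC nonsynonymous transversion
        params = a.CodonModelParams(2.0, np.array([0.5]), equal_pi)
        Q = build_rate_matrix(params, 0).Q
        i = CODE.codon_index["AAA"]
        assert Q[i, CODE.codon_index["AAG"]] / Q[i, CODE.codon_index["AAC"]] == pytest.approx(4.0)

    def test_double_change_forbidden(self, equal_pi):
        params = a.CodonModelParams(2.0, np.array([0.5]), equal_pi)
        Q = build_rate_matrix(params, 0).Q
        assert Q[CODE.codon_index["AAA"], CODE.codon_index["AGG"]] == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_reversibility_and_normalization(self, seed):
        params = random_params(seed)
        Q = build_rate_matrix(params, 0).Q
        pi = params.codon_freqs
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-10
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-10)


def brute_force_lnl(aln, tree, params, code=CODE):
    """Independent oracle: sum over every joint interior-node state assignment.

    Builds the explicit joint tensor over internal states with outer
    products (no pruning recursion); feasible for <= 4 leaves.
    """
    pi = params.codon_freqs
    P = {
        b.id: expm(build_rate_matrix(params, b.cls, code).Q * b.length)
        for b in tree.branches()
    }
    internals = [n for n in tree.preorder() if not n.is_leaf]
    idx = {t: i for i, t in enumerate(aln.taxa)}
    states = aln.indices(code)
    total = 0.0
    n = code.n
    for site in range(aln.n_sites):
        axes = {id(node): k for k, node in enumerate(internals)}
        tensor = np.ones([n] * len(internals))
        # root prior
        shape = [1] * len(internals)
        shape[axes[id(tree.root)]] = n
        tensor = tensor * pi.reshape(shape)
        for b in tree.branches():
            if b.is_leaf:
                s = states[idx[b.name], site]
                vec = np.ones(n) if s < 0 else P[b.id][:, s]
                shape = [1] * len(internals)
                shape[axes[id(b.parent)]] = n
                tensor = tensor * vec.reshape(shape)
            else:
                mat = P[b.id]
                shape = [1] * len(internals)
                shape[axes[id(b.parent)]] = n
                shape[axes[id(b)]] = n
                tensor = tensor * mat.reshape([n if k in (axes[id(b.parent)], axes[id(b)]) else 1 for k in range(len(internals))])
        total += np.log(tensor.sum())
    return total


class TestLikelihood:
    def test_zero_length_branches_give_equilibrium_draw(self, equal_pi):
        tree = a.parse_newick("(A:0.0,B:0.0);")
        aln = a.CodonAlignment(["A", "B"], [["AAA"], ["AAA"]])
        params = a.CodonModelParams(2.0, np.array([1.0]), equal_pi)
        assert a.log_likelihood(aln, tree, params) == pytest.approx(np.log(1 / 61))

    @pytest.mark.parametrize(
        "nwk,taxa",
        [
            ("(A:0.15,B:0.4);", "AB"),
            ("((A:0.12,B:0.3 #1):0.08,C:0.25 #1);", "ABC"),
            ("((A:0.1,B:0.2):0.05,(C:0.12,D:0.3 #1):0.07 #1);", "ABCD"),
            ("(((A:0.1,B:0.2):0.05,C:0.12):0.07,D:0.3);", "ABCD"),
        ],
    )
    def test_pruning_equals_state_enumeration(self, nwk, taxa):
        tree = a.parse_newick(nwk)
        params = random_params(99, n_classes=tree.n_classes)
        rng = np.random.default_rng(5)
        sense = CODE.sense_codons
        rows = [[sense[i] for i in rng.integers(0, 61, size=3)] for _ in taxa]
        rows[0][1] = "NNN"  # one ambiguous cell exercises the marginalization
        aln = a.CodonAlignment(list(taxa), rows)
        assert a.log_likelihood(aln, tree, params) == pytest.approx(
            brute_force_lnl(aln, tree, params), abs=1e-9
        )

    def test_rerooting_leaves_lnl_unchanged(self, small_alignment):
        params = random_params(3)
        t1 = a.parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        t2 = a.parse_newick("((A:0.1,B:0.2):0.02,(C:0.3):0.03);")
        l1 = a.log_likelihood(small_alignment, t1, params)
        l2 = a.log_likelihood(small_alignment, t2, params)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_taxon_reordering_invariance(self, small_alignment):
        tree = a.parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        params = random_params(11)
        shuffled = small_alignment.subset(["C", "A", "B"])
        assert a.log_likelihood(small_alignment, tree, params) == pytest.approx(
            a.log_likelihood(shuffled, tree, params)
        )

    def test_missing_taxon_named_in_error(self, small_alignment):
        tree = a.parse_newick("((A:0.1,B:0.2):0.05,Z:0.3);")
        with pytest.raises(KeyError, match="Z"):
            a.log_likelihood(small_alignment, tree, random_params(1))

    def test_negative_for_resolved_data(self, small_alignment):
        tree = a.parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        assert a.log_likelihood(small_alignment, tree, random_params(2)) < 0


class TestFit:
    def test_parameter_recovery_at_2000_codons(self):
        spec = a.SimTreeSpec(AMNIOTE_NEWICK, [0.2], kappa=2.0, n_codons=2000, seed=77)
        aln, _ = a.simulate_codon_alignment(spec)
        fit = a.fit_codon_model(aln, spec.tree(), freq_model="equal")
        assert fit.converged
        assert 0.15 <= fit.params.omega_by_class[0] <= 0.25
        assert 1.6 <= fit.params.kappa <= 2.4
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.lnL)
        assert fit.n_params == len(spec.tree().branches()) + 1 + 1

    def test_median_omega_recovery_across_regimes(self):
        """Median |omega_hat - omega| <= 0.1 over 21 simulation replicates."""
        errors = []
        for omega in (0.1, 0.5, 1.0):
            for rep in range(7):
                spec = a.SimTreeSpec(
                    AMNIOTE_NEWICK, [omega], kappa=2.0, n_codons=1000, seed=1000 + rep
                )
                aln, _ = a.simulate_codon_alignment(spec)
                fit = a.fit_codon_model(aln, spec.tree(), freq_model="equal")
                errors.append(abs(float(fit.params.omega_by_class[0]) - omega))
        assert np.median(errors) <= 0.1

    def test_free_omega_dominates_one_omega(self):
        spec = a.SimTreeSpec(AMNIOTE_NEWICK, [0.3], kappa=2.0, n_codons=200, seed=8)
        aln, _ = a.simulate_codon_alignment(spec)
        tree = spec.tree()
        one = a.fit_codon_model(aln, tree, freq_model="equal")
        order = {b.id: i for i, b in enumerate(tree.branches())}
        free_tree = tree.with_classes(lambda n: order[n.id])
        free = a.fit_codon_model(aln, free_tree, freq_model="equal")
        assert free.lnL >= one.lnL - 1e-6

    def test_kappa_pinning(self):
        spec = a.SimTreeSpec(AMNIOTE_NEWICK, [0.3], kappa=2.0, n_codons=150, seed=9)
        aln, _ = a.simulate_codon_alignment(spec)
        fit = a.fit_codon_model(aln, spec.tree(), freq_model="equal", fixed={"kappa": 3.5})
        assert fit.params.kappa == 3.5
        assert fit.n_params == len(spec.tree().branches()) + 1  # kappa no longer free

    def test_no_resolved_columns_raises(self, amniote_tree):
        aln = a.CodonAlignment(
            amniote_tree.leaf_names, [["NNN"] for _ in range(5)]
        )
        with pytest.raises(ValueError, match="resolved"):
            a.fit_codon_model(aln, amniote_tree)


class TestDecomposition:
    def test_omega_zero_has_no_nonsynonymous_length(self, equal_pi):
        tree = a.parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        params = a.CodonModelParams(2.0, np.array([0.0]), equal_pi)
        for b in a.decompose_branch_substitutions(tree, params):
            assert b.dN_len == 0.0
            assert b.dS_len == pytest.approx(b.t)

    def test_lengths_conserved(self):
        tree = a.parse_newick("((A:0.1,B:0.2 #1):0.05,C:0.3 #1);")
        params = random_params(21, n_classes=2)
        for b in a.decompose_branch_substitutions(tree, params):
            assert b.dS_len + b.dN_len == pytest.approx(b.t, abs=1e-9)
            assert b.S + b.N == pytest.approx(3.0)

    def test_neutral_fraction_matches_exhaustive_count(self, equal_pi):
        """kappa=1, omega=1, equal pi: dN/t = nonsyn share of all single-nt
        sense-codon changes, counted codon by codon."""
        nonsyn = syn = 0
        for codon in CODE.sense_codons:
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    mutant = codon[:pos] + base + codon[pos + 1 :]
                    if CODE.is_stop(mutant):
                        continue
                    if CODE.aa(mutant) == CODE.aa(codon):
                        syn += 1
                    else:
                        nonsyn += 1
        expected = nonsyn / (nonsyn + syn)
        tree = a.parse_newick("(A:0.3,B:0.1);")
        params = a.CodonModelParams(1.0, np.array([1.0]), equal_pi)
        decomp = a.decompose_branch_substitutions(tree, params)
        assert decomp[0].dN_len / decomp[0].t == pytest.approx(expected, abs=1e-12)

    def test_substitution_trees_write_decomposed_lengths(self, equal_pi):
        tree = a.parse_newick("(A:0.3,B:0.1);")
        params = a.CodonModelParams(1.0, np.array([0.0]), equal_pi)
        ds, dn = a.substitution_trees(tree, params)
        assert ds.find("A").length == pytest.approx(0.3)
        assert dn.find("A").length == 0.0
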