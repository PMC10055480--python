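"""Compositional correlation estimation: fractions, log-ratio variances,
basis variances and the full SparCC estimate."""

import numpy as np
import pytest

from sohpie import (
    AbundanceTable,
    basis_variances,
    logratio_variances,
    sparcc_correlation,
    to_fractions,
)
from sohpie.sparcc import VARIANCE_FLOOR, _rho_from_basis, sparcc_exclusion_pairs

from conftest import lognormal_compositions


class TestFractions:
    def test_simple_row(self):
        out = to_fractions(np.array([[1.0, 1.0, 2.0]]), pseudocount=0)
        np.testing.assert_allclose(out, [[0.25, 0.25, 0.5]])

    def test_pseudocount_symmetry(self):
        out = to_fractions(np.array([[0.0, 0.0]]), pseudocount=0.5)
        np.testing.assert_allclose(out, [[0.5, 0.5]])

    def test_rows_sum_to_one(self, small_table):
        out = to_fractions(small_table, pseudocount=0.5)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out > 0).all()

    def test_degenerate_sample_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            to_fractions(np.zeros((2, 3)), pseudocount=0)


class TestLogratioVariances:
    def test_proportional_taxa_have_zero_variance(self, rng):
        base = rng.lognormal(size=20)
        fracs = to_fractions(np.column_stack([base, 3.0 * base, rng.lognormal(size=20)]), 0)
        t = logratio_variances(fracs)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self, rng):
        fracs = lognormal_compositions(rng, 50, 5)
        t = logratio_variances(fracs)
        np.testing.assert_allclose(t, t.T)
        np.testing.assert_allclose(np.diag(t), 0.0)

    def test_independent_lognormals_variance_two(self, rng):
        # Var(log u_j/u_k) = sigma_j^2 + sigma_k^2 = 2 for independent
        # unit-variance log-normals; Monte-Carlo check at n = 5000
        fracs = lognormal_compositions(rng, 5000, 2, sigma2=1.0)
        t = logratio_variances(fracs)
        assert t[0, 1] == pytest.approx(2.0, abs=0.15)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="variance undefined"):
            logratio_variances(np.ones((1, 3)))


class TestBasisVariances:
    def test_three_taxa_uniform_matches_linear_solve(self):
        t = np.full((3, 3), 2.0)
        np.fill_diagonal(t, 0.0)
        got = basis_variances(t)
        # independent oracle: solve ((m-2) I + J) s = rowsums directly
        M = np.ones((3, 3)) + np.eye(3)
        expected = np.linalg.solve(M, t.sum(axis=1))
        np.testing.assert_allclose(got, expected)

    def test_degenerate_all_zero_floor(self):
        got = basis_variances(np.zeros((4, 4)))
        np.testing.assert_allclose(got, VARIANCE_FLOOR)

    def test_recovers_known_variance(self, rng):
        fracs = lognormal_compositions(rng, 5000, 10, sigma2=1.0)
        sigma2 = basis_variances(logratio_variances(fracs))
        np.testing.assert_allclose(sigma2, 1.0, atol=0.2)

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            basis_variances(np.zeros((4, 4)), included=[0, 1])


class TestRhoClosedForms:
    def test_zero_logratio_variance_equal_sigmas_gives_one(self):
        sigma2 = np.array([0.7, 0.7])
        t = np.zeros((2, 2))
        rho = _rho_from_basis(t, sigma2)
        assert rho[0, 1] == pytest.approx(1.0)

    def test_additive_variance_gives_zero(self):
        sigma2 = np.array([0.5, 1.5])
        t = np.array([[0.0, 2.0], [2.0, 0.0]])  # t_jk = sigma_j^2 + sigma_k^2
        rho = _rho_from_basis(t, sigma2)
        assert rho[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestSparccCorrelation:
    def test_invariants_on_random_counts(self, small_table):
        rho = sparcc_correlation(small_table).rho
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert (np.abs(rho) <= 1.0 + 1e-12).all()

    def test_proportional_pair_estimated_near_one(self, rng):
        base = rng.lognormal(sigma=1.0, size=300)
        counts = np.column_stack(
            [base, 2.0 * base] + [rng.lognormal(sigma=1.0, size=300) for _ in range(4)])
        assoc = sparcc_correlation(AbundanceTable(1000 * counts), pseudocount=0)
        assert assoc.rho[0, 1] > 0.95

    def test_taxon_permutation_equivariance(self, small_table, rng):
        perm = rng.permutation(small_table.n_taxa)
        rho = sparcc_correlation(small_table).rho
        rho_perm = sparcc_correlation(small_table.subset_taxa(perm)).rho
        np.testing.assert_allclose(rho_perm, rho[np.ix_(perm, perm)], atol=1e-10)

    def test_compositional_scale_invariance(self, small_table):
        rho = sparcc_correlation(small_table, pseudocount=0).rho
        scaled = AbundanceTable(small_table.counts * np.array([[10.0]] * 15 + [[0.25]] * 15))
        rho2 = sparcc_correlation(scaled, pseudocount=0).rho
        np.testing.assert_allclose(rho, rho2, atol=1e-10)

    def test_independent_taxa_near_zero(self, rng):
        fracs = lognormal_compositions(rng, 1000, 10)
        counts = np.rint(fracs * 1e6)
        rho = sparcc_correlation(AbundanceTable(counts)).rho
        off = ~np.eye(10, dtype=bool)
        assert np.abs(rho[off]).mean() < 0.1

    def test_correlated_pair_recovery(self, rng):
        fracs = lognormal_compositions(rng, 500, 10, rho=0.7, pair=(0, 1))
        counts = np.rint(fracs * 1e6)
        assoc = sparcc_correlation(AbundanceTable(counts))
        assert 0.55 <= assoc.rho[0, 1] <= 0.85

    def test_needs_four_taxa(self):
        with pytest.raises(ValueError, match="at least 4"):
            sparcc_correlation(np.ones((10, 3)))

    def test_frozen_pairs_replay_matches_adaptive(self, small_table):
        pairs = sparcc_exclusion_pairs(small_table)
        adaptive = sparcc_correlation(small_table)
        replay = sparcc_correlation(small_table, exclusion_pairs=pairs)
        np.testing.assert_allclose(adaptive.rho, replay.rho)
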