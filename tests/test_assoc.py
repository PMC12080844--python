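"""Sum, squared-sum, and adaptive gene-based tests on (z, R)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, norm

from genewas.assoc import (
    DEFAULT_RHO_GRID,
    adaptive_test,
    bonferroni_threshold,
    calibrate_min_p,
    genome_scan,
    ssq_test,
    sum_test,
)
from genewas.genesets import GeneAnnotation, GeneSnpSet
from genewas.mixture import mixture_quantile


def random_correlation(m, rng, n=80):
    X = rng.standard_normal((max(n, m + 5), m))
    return np.corrcoef(X, rowvar=False)


class TestSumTest:
    def test_zero_z_gives_p_one(self):
        p, B = sum_test([0.0, 0.0], np.eye(2))
        assert B == 0.0 and p == 1.0

    def test_independent_pair_closed_form(self):
        p, _ = sum_test([1.0, 1.0], np.eye(2))
        assert p == pytest.approx(2 * norm.sf(np.sqrt(2)), rel=1e-12)
        assert p == pytest.approx(0.157299, abs=5e-7)

    def test_correlated_pair_closed_form(self):
        # v = 1'R1 = 3 for r = 0.5
        p, _ = sum_test([1.0, 1.0], [[1.0, 0.5], [0.5, 1.0]])
        assert p == pytest.approx(2 * norm.sf(2 / np.sqrt(3)), rel=1e-12)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            sum_test([1.0], np.eye(1))


class TestSsqTest:
    def test_zero_z_gives_p_one(self):
        p, Q = ssq_test([0.0, 0.0], np.eye(2))
        assert Q == 0.0 and p == 1.0

    def test_independent_pair_matches_chi2_2(self):
        z = np.sqrt(5.99146 / 2) * np.ones(2)
        p, Q = ssq_test(z, np.eye(2))
        assert Q == pytest.approx(5.99146)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_independent_triple_matches_chi2_3(self):
        p, _ = ssq_test([1.0, 1.0, 1.0], np.eye(3))
        assert p == pytest.approx(chi2.sf(3.0, 3), abs=1e-9)


class TestAdaptiveTest:
    def test_grid_zero_equals_squared_sum(self):
        z = np.array([1.5, -0.5, 2.0])
        at = adaptive_test(z, np.eye(3), rho_grid=[0.0])
        assert at.p == ssq_test(z, np.eye(3))[0]

    def test_zero_z_gives_unit_p(self):
        at = adaptive_test([0.0, 0.0], np.eye(2))
        assert at.t_min == 1.0 and at.p == 1.0

    def test_grid_endpoints_tmin_is_min_of_both_tests(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            R = random_correlation(4, rng)
            z = rng.standard_normal(4)
            at = adaptive_test(z, R, rho_grid=[0.0, 1.0])
            expected = min(ssq_test(z, R)[0], sum_test(z, R)[0])
            assert at.t_min == pytest.approx(expected, rel=1e-9)

    def test_rho_tie_breaks_to_smaller(self):
        at = adaptive_test([0.0, 0.0], np.eye(2), rho_grid=[0.3, 0.7])
        assert at.rho == 0.3

    def test_matches_monte_carlo_oracle_identity_ld(self):
        z = np.array([1.5, -0.5, 2.0])
        R = np.eye(3)
        grid = [0.0, 0.5, 1.0]
        at = adaptive_test(z, R, rho_grid=grid)
        rng = np.random.default_rng(42)
        n = 2 * 10**5
        Z = rng.standard_normal((n, 3))
        Q, B2 = (Z**2).sum(1), Z.sum(1) ** 2
        exceed = np.zeros(n, bool)
        for rho in grid:
            w = [3.0] if rho == 1.0 else np.linalg.eigvalsh(
                (1 - rho) * np.eye(3) + rho * np.ones((3, 3))
            )
            exceed |= (1 - rho) * Q + rho * B2 >= mixture_quantile(at.t_min, w)
        mc = exceed.mean()
        assert at.p == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / n))

    @given(seed=st.integers(0, 200))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bonferroni_sandwich_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 6))
        R = random_correlation(m, rng)
        z = rng.standard_normal(m) * rng.uniform(0.5, 3.0)
        grid = sorted(rng.choice(DEFAULT_RHO_GRID, size=int(rng.integers(2, 6)),
                                 replace=False).tolist())
        at = adaptive_test(z, R, rho_grid=grid)
        assert at.t_min <= at.p <= min(1.0, at.t_min * len(set(grid))) + 1e-12


class TestCalibrateMinP:
    def test_single_element_grid_is_identity(self):
        R = random_correlation(3, np.random.default_rng(0))
        assert calibrate_min_p(0.07, R, rho_grid=[0.4]) == 0.07

    def test_tmin_one_maps_to_one(self):
        assert calibrate_min_p(1.0, np.eye(2), rho_grid=[0.0, 1.0]) == 1.0

    def test_matches_monte_carlo_on_correlated_pair(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        grid = [0.0, 0.5, 1.0]
        z = np.array([1.2, 0.4])
        at = adaptive_test(z, R, rho_grid=grid)
        p_cal = calibrate_min_p(at.t_min, R, rho_grid=grid)
        rng = np.random.default_rng(3)
        n = 10**6
        L = np.linalg.cholesky(R)
        Z = rng.standard_normal((n, 2)) @ L.T
        Q, B2 = (Z**2).sum(1), Z.sum(1) ** 2
        exceed = np.zeros(n, bool)
        for rho in grid:
            w = [float(R.sum())] if rho == 1.0 else np.real(
                np.linalg.eigvals(((1 - rho) * np.eye(2) + rho * np.ones((2, 2))) @ R)
            )
            exceed |= (1 - rho) * Q + rho * B2 >= mixture_quantile(at.t_min, w)
        mc = exceed.mean()
        assert p_cal == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / n))

    def test_invalid_tmin_rejected(self):
        with pytest.raises(ValueError):
            calibrate_min_p(0.0, np.eye(2))


def make_sets(rng, n_genes, m=5, shift=0.0, rho=0.4):
    R = rho * np.ones((m, m))
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    sets = []
    for i in range(n_genes):
        z = L @ rng.standard_normal(m) + shift
        gene = GeneAnnotation(gene_id=f"G{i}", symbol=f"G{i}", chrom="1",
                              tx_start=1000 * (i + 1), tx_end=1000 * (i + 1) + 500)
        sets.append(GeneSnpSet(gene=gene, rsids=[f"rs{i}_{j}" for j in range(m)], z=z, R=R))
    return sets


class TestGenomeScan:
    def test_empty_collection_gives_empty_table(self):
        results, threshold, manhattan = genome_scan([])
        assert len(results) == 0 and threshold is None and len(manhattan) == 0

    def test_shifted_genes_have_smaller_median_p_than_null(self):
        rng = np.random.default_rng(9)
        null = genome_scan(make_sets(rng, 30))[0]
        shifted = genome_scan(make_sets(rng, 30, shift=0.8))[0]
        assert shifted["p_at"].median() < null["p_at"].median()

    def test_threshold_and_manhattan_columns(self):
        rng = np.random.default_rng(1)
        results, threshold, manhattan = genome_scan(make_sets(rng, 10), alpha=0.05)
        assert threshold == pytest.approx(0.005)
        assert list(manhattan.columns) == ["chrom", "pos", "neg_log10_p"]
        assert np.allclose(manhattan["neg_log10_p"], -np.log10(results["p_at"]))


class TestBonferroniThreshold:
    def test_single_test_is_alpha(self):
        assert bonferroni_threshold(1, 0.05) == 0.05

    def test_twenty_thousand_genes(self):
        assert bonferroni_threshold(20000, 0.05) == pytest.approx(2.5e-6)

    def test_thirty_tissues(self):
        assert bonferroni_threshold(30, 0.05) == pytest.approx(0.0016667, abs=5e-8)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)
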