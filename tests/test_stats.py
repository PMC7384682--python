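import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reference import brute_peacock_d
from twocalm.features import DimensionGrid
from twocalm.stats import (
    confidence_band,
    empirical_pvalue,
    ks_2sample,
    multivariate_ks,
    sim_L,
    sim_M,
    tnorm_and,
    verdict,
    wx_2sample,
)


def kolmogorov_series(lam: float, terms: int = 100) -> float:
    """Independent oracle: Q_KS(lam) = 2 sum (-1)^(k-1) exp(-2 k^2 lam^2)."""
    return float(sum(2 * (-1) ** (k - 1) * np.exp(-2 * k**2 * lam**2) for k in range(1, terms + 1)))


class TestKS:
    def test_identical_samples(self):
        x = np.arange(10.0)
        assert ks_2sample(x, x) == pytest.approx(1.0)

    def test_fully_separated_matches_kolmogorov_series(self):
        x = np.arange(1.0, 11.0)
        y = np.arange(100.0, 110.0)
        # D = 1, effective n = sqrt(100/20) = sqrt(5)
        expected = kolmogorov_series(np.sqrt(5.0))
        assert ks_2sample(x, y) == pytest.approx(expected, rel=1e-10)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=30), rng.normal(1.0, size=40)
        assert ks_2sample(x, y) == pytest.approx(ks_2sample(y, x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_2sample([], [1.0])


class TestWX:
    def test_identical_samples_give_one(self):
        x = np.arange(8.0)
        assert wx_2sample(x, x) == pytest.approx(1.0)

    def test_extreme_small_sample_exact(self):
        # all 3 ranks of x below y: 2 * 1/C(6,3) = 2/20 = 0.1
        assert wx_2sample([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_matches_enumeration(self):
        x = np.array([1.3, 2.1, 5.0])
        y = np.array([0.4, 3.3, 4.1, 6.2])
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:3].sum()
        mean = 3 * (len(pooled) + 1) / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), 3):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean) >= abs(obs - mean) - 1e-12:
                count += 1
        assert wx_2sample(x, y) == pytest.approx(count / total)

    def test_argument_swap_symmetry(self, rng):
        x, y = rng.normal(size=25), rng.normal(0.5, size=30)
        assert wx_2sample(x, y) == pytest.approx(wx_2sample(y, x))

    def test_constant_samples(self):
        assert wx_2sample([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0


class TestTnormAnd:
    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_idempotence(self, p, w):
        assert tnorm_and(p, p, w) == pytest.approx(p, abs=1e-12)

    def test_boundaries(self):
        assert tnorm_and(0.0, 0.0, 0.3) == 0.0
        assert tnorm_and(1.0, 1.0, 0.3) == 1.0

    def test_hand_computed_value(self):
        expected = 1 - np.sqrt(0.5 * 0.64 + 0.5 * 0.04)
        assert tnorm_and(0.2, 0.8, 0.5) == pytest.approx(expected)
        assert expected == pytest.approx(0.4169, abs=5e-5)

    def test_vectorised_and_nan_propagation(self):
        out = tnorm_and(np.array([0.2, np.nan]), np.array([0.8, 0.5]), 0.5)
        assert np.isnan(out[1]) and out[0] == pytest.approx(1 - np.sqrt(0.34))


class TestPeacock2D:
    def test_identical_samples(self):
        a = np.random.default_rng(0).uniform(size=(20, 2))
        D, p = multivariate_ks(a, a)
        assert D == 0.0 and p == pytest.approx(1.0)

    def test_margin_separation_matches_1d(self):
        # identical curvature margin, fully separated density margin
        a = np.column_stack([np.arange(10.0), np.zeros(10)])
        b = np.column_stack([np.arange(100.0, 110.0), np.zeros(10)])
        D, _ = multivariate_ks(a, b)
        assert D == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_d_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=(int(r.integers(5, 50)), 2))
        b = r.normal(0.5, size=(int(r.integers(5, 50)), 2))
        D, _ = multivariate_ks(a, b)
        assert D == pytest.approx(brute_peacock_d(a, b), abs=1e-12)


class TestEmpiricalP:
    def test_median_is_capped_at_one(self):
        ref = np.arange(99.0)
        assert empirical_pvalue(49.0, ref) == 1.0

    def test_below_all_reference_values(self):
        ref = np.arange(1.0, 100.0)
        assert empirical_pvalue(0.0, ref) == pytest.approx(0.02)

    def test_null_distribution_superuniform(self, rng):
        # p-values of a draw against its own distribution are ~uniform (or wider)
        hits = 0
        reps = 500
        for _ in range(reps):
            ref = rng.normal(size=99)
            if empirical_pvalue(rng.normal(), ref) <= 0.1:
                hits += 1
        assert hits / reps <= 0.14  # at most ~alpha rejections plus noise


class TestConfidenceBand:
    def test_constant_row_degenerate(self):
        row = np.full(10, 0.4)
        for method in ("normal", "bpci"):
            lo, hi = confidence_band(row, method)
            assert lo == pytest.approx(0.4) and hi == pytest.approx(0.4)

    def test_bpci_outward_rounding(self):
        row = np.arange(0.1, 1.01, 0.1)
        lo, hi = confidence_band(row, "bpci", alpha=0.05)
        assert lo == pytest.approx(0.1) and hi == pytest.approx(1.0)

    def test_normal_band_symmetric(self):
        row = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        lo, hi = confidence_band(row, "normal", alpha=0.05)
        m = row.mean()
        assert (m - lo) == pytest.approx(hi - m)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            confidence_band([0.5], "bpci")


class TestSimilarity:
    def test_sim_m_anchor_points(self):
        assert sim_M([0.05], alpha=0.05) == pytest.approx(0.5)
        assert sim_M([0.0], alpha=0.05) == 0.0
        assert sim_M([1.0], alpha=0.05) == pytest.approx(0.975)
        assert sim_M([0.025], alpha=0.05) == pytest.approx(0.25)

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_sim_m_monotone_in_mean(self, m1, m2):
        lo, hi = sorted([m1, m2])
        assert sim_M([lo], 0.05) <= sim_M([hi], 0.05) + 1e-12

    def test_sim_l_constant_bands(self):
        grid = DimensionGrid(size_min=10, step=10, L=9)  # interval 10..100
        alpha = 0.05
        assert sim_L(np.full(9, alpha), alpha, grid) == pytest.approx(1.0)
        assert sim_L(np.zeros(9), alpha, grid) == pytest.approx(0.0)
        assert sim_L(np.full(9, alpha / 2), alpha, grid) == pytest.approx(0.5)

    def test_sim_l_monotone_in_band(self, rng):
        grid = DimensionGrid(size_min=10, step=10, L=9)
        lb = rng.uniform(0, 0.05, size=9)
        s1 = sim_L(lb, 0.05, grid)
        s2 = sim_L(lb + 0.01, 0.05, grid)
        assert s2 >= s1

    def test_verdict_thresholds(self):
        assert verdict(0.56) == "similar"
        assert verdict(0.50) == "marginal"
        assert verdict(0.44) == "dissimilar"
        assert verdict(0.55) == "similar"
        assert verdict(0.45) == "dissimilar"
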