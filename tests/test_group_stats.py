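"""Second-level robust regression, smoothing, permutation FWE, Spearman tests."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from riskreact.stats import (
    permutation_fwe,
    robust_slope_t,
    second_level_tmap,
    smooth_map,
    spearman_onetailed,
)


class TestRobustRegression:
    def test_matches_statsmodels_bisquare_slope(self, rng):
        x = rng.normal(0, 1, 19)
        y = 0.5 * x + rng.normal(0, 1, 19)
        y[3] += 8.0
        b1, _ = robust_slope_t(x, y)
        ref = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight()).fit()
        assert b1 == pytest.approx(ref.params[1], rel=1e-4)

    def test_outlier_resistance_versus_ols(self, rng):
        """One extreme subject barely moves the robust t but wrecks the OLS t."""
        x = rng.normal(0, 1, 18)
        y = 1.0 * x + rng.normal(0, 0.5, 18)
        _, t_clean = robust_slope_t(x, y)
        ols_clean = sm.OLS(y, sm.add_constant(x)).fit().tvalues[1]
        x_out = np.append(x, 2.5)
        y_out = np.append(y, -20.0)
        _, t_robust = robust_slope_t(x_out, y_out)
        ols_out = sm.OLS(y_out, sm.add_constant(x_out)).fit().tvalues[1]
        assert abs(t_robust - t_clean) / abs(t_clean) < 0.25
        assert abs(ols_out - ols_clean) / abs(ols_clean) > 0.50

    def test_vectorized_matches_scalar(self, rng):
        x = rng.normal(0, 1, 12)
        Y = rng.normal(0, 1, (30, 12))
        b_vec, t_vec = robust_slope_t(x[None, :], Y)
        # stopping is batch-global, so agreement is to the IRLS tolerance
        for c in (0, 7, 29):
            b, t = robust_slope_t(x, Y[c])
            assert b_vec[c] == pytest.approx(b, abs=1e-4)
            assert t_vec[c] == pytest.approx(t, abs=1e-3)

    def test_second_level_null_mean_near_zero(self, rng):
        maps = rng.normal(0, 1, (12, 6, 6))
        cov = rng.normal(0, 1, 12)
        t_map = second_level_tmap(maps, cov)
        assert abs(np.nanmean(t_map)) < 0.5

    def test_nan_cells_dropped_pairwise(self, rng):
        maps = rng.normal(0, 1, (10, 4, 4))
        maps[0, 1, 1] = np.nan  # 9 subjects remain: still estimable
        maps[:6, 2, 2] = np.nan  # 4 remain: below the minimum
        t_map = second_level_tmap(maps, rng.normal(0, 1, 10))
        assert np.isfinite(t_map[1, 1])
        assert np.isnan(t_map[2, 2])

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            second_level_tmap(rng.normal(0, 1, (3, 4, 4)), rng.normal(0, 1, 3))


class TestSmoothing:
    def test_constant_map_unchanged(self):
        out = smooth_map(np.full((9, 9), 3.7), sigma=1.5)
        assert np.allclose(out, 3.7)

    def test_impulse_spread_matches_sigma(self):
        m = np.zeros((41, 41))
        m[20, 20] = 1.0
        out = smooth_map(m, sigma=1.5)
        xs = np.arange(41)
        w = out.sum(axis=1)
        sd = np.sqrt(np.sum(w * (xs - 20) ** 2) / w.sum())
        assert sd == pytest.approx(1.5, abs=0.05)

    def test_gaussian_semigroup_interior(self, rng):
        m = rng.normal(0, 1, (41, 41))
        twice = smooth_map(smooth_map(m, 1.0), 1.0)
        once = smooth_map(m, np.sqrt(2.0))
        assert np.allclose(twice[10:-10, 10:-10], once[10:-10, 10:-10], atol=1e-3)

    def test_nan_cells_preserved_and_renormalized(self):
        m = np.full((7, 7), 2.0)
        m[3, 3] = np.nan
        out = smooth_map(m, sigma=1.5)
        assert np.isnan(out[3, 3])
        finite = np.isfinite(out)
        assert np.allclose(out[finite], 2.0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((3, 3)), sigma=0.0)


class TestPermutationFWE:
    def test_deterministic_and_bounded_below(self, rng):
        maps = rng.normal(0, 1, (10, 6, 6))
        cov = rng.normal(0, 1, 10)
        a = permutation_fwe(maps, cov, n_perm=200, seed=3)
        b = permutation_fwe(maps, cov, n_perm=200, seed=3)
        assert a.p_fwe == b.p_fwe
        assert np.allclose(a.null_extrema, b.null_extrema)
        assert a.p_fwe >= 1.0 / 201.0
        assert len(a.null_extrema) == 200

    def test_planted_negative_effect_localized_min_tail(self, rng):
        n_subj = 14
        cov = rng.normal(0, 1, n_subj)
        maps = rng.normal(0, 0.3, (n_subj, 10, 10))
        maps[:, 3:6, 3:6] -= 2.0 * cov[:, None, None]  # strong negative coupling
        res = permutation_fwe(maps, cov, n_perm=200, tail="min", seed=0)
        assert res.p_fwe <= 0.05
        assert 2 <= res.peak_location[0] <= 6
        assert 2 <= res.peak_location[1] <= 6

    def test_null_rejection_rate_calibrated_small(self, rng):
        rejections = 0
        reps = 40
        for r in range(reps):
            maps = rng.normal(0, 1, (10, 5, 5))
            cov = rng.normal(0, 1, 10)
            res = permutation_fwe(maps, cov, n_perm=200, seed=r)
            rejections += res.p_fwe <= 0.05
        assert rejections / reps <= 0.15  # coarse guard; full calibration elsewhere

    def test_invalid_arguments(self, rng):
        maps = rng.normal(0, 1, (8, 4, 4))
        cov = rng.normal(0, 1, 8)
        with pytest.raises(ValueError):
            permutation_fwe(maps, cov, n_perm=50)
        with pytest.raises(ValueError):
            permutation_fwe(maps, cov, n_perm=200, tail="both")


class TestSpearman:
    def test_agrees_with_scipy(self, rng):
        x = rng.normal(0, 1, 30)
        y = 0.4 * x + rng.normal(0, 1, 30)
        r, t, p = spearman_onetailed(x, y, tail="pos")
        ref = sps.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue / 2, rel=0.05)

    def test_perfect_monotone(self):
        x = np.arange(10.0)
        r, t, p = spearman_onetailed(x, np.exp(x), tail="pos")
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_onetailed(np.ones(5), np.arange(5.0))

    def test_tail_direction(self, rng):
        x = np.arange(20.0)
        y = -x + rng.normal(0, 0.1, 20)
        _, _, p_neg = spearman_onetailed(x, y, tail="neg")
        _, _, p_pos = spearman_onetailed(x, y, tail="pos")
        assert p_neg < 0.01 < p_pos
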