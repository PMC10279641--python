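import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from qpipe.regression import (
    ConvergenceError,
    DegenerateDataError,
    LogLogDataset,
    correction_factor,
    fit_ols,
    fit_random_intercept,
    fit_sma,
    grubbs_critical_value,
    grubbs_filter,
    profile_ci_sigma_species,
    select_model,
)

from conftest import random_loglog


# ---------------------------------------------------------------------- SMA

class TestSMA:
    def test_collinear_data_exact(self):
        x = np.log([1.0, 2, 4, 8])
        y = 2 * x + math.log(2)
        f = fit_sma(LogLogDataset(x, y)).single
        assert f.slope == pytest.approx(2.0, rel=1e-12)
        assert f.elevation == pytest.approx(2.0, rel=1e-12)
        assert f.r2 == pytest.approx(1.0)

    def test_hand_computed_slope(self):
        # sd-ratio slope vs the OLS slope from the normal equations
        d = LogLogDataset(np.array([0.0, 1, 2]), np.array([0.0, 1, 3]))
        f = fit_sma(d).single
        assert f.slope == pytest.approx(math.sqrt(7.0 / 3.0), rel=1e-12)
        o = fit_ols(d)
        assert o.slope == pytest.approx(1.5, rel=1e-12)
        assert o.intercept == pytest.approx(-1.0 / 6.0, rel=1e-10)
        assert abs(f.slope) >= abs(o.slope)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_sma_slope_magnitude_at_least_ols(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_loglog(rng, n=30, sd=0.5)
        d = LogLogDataset(x, y)
        assert abs(fit_sma(d).single.slope) >= abs(fit_ols(d).slope) - 1e-12

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_axis_swap_reciprocity(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_loglog(rng, n=30, sd=0.4)
        b_xy = fit_sma(LogLogDataset(x, y)).single.slope
        b_yx = fit_sma(LogLogDataset(y, x)).single.slope
        assert b_xy == pytest.approx(1.0 / b_yx, rel=1e-9)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_sma(LogLogDataset(np.zeros(5), np.arange(5.0)))

    def test_robust_small_group_falls_back_with_warning(self):
        d = LogLogDataset(np.array([0.0, 1, 2]), np.array([0.1, 1.2, 2.9]))
        with pytest.warns(UserWarning, match="robust"):
            f = fit_sma(d, robust=True).single
        assert math.isfinite(f.slope)

    def test_robust_downweights_outlier(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 60)
        y = 1.0 * x + rng.normal(0, 0.1, 60)
        y[0] += 8.0  # gross outlier
        plain = fit_sma(LogLogDataset(x, y)).single.slope
        robust = fit_sma(LogLogDataset(x, y), robust=True).single.slope
        assert abs(robust - 1.0) < abs(plain - 1.0)

    def test_common_slope_matches_brute_force_grid(self):
        rng = np.random.default_rng(4)
        x1, y1 = random_loglog(rng, n=40, slope=1.1, sd=0.3)
        x2, y2 = random_loglog(rng, n=50, slope=1.25, intercept=1.5, sd=0.3)
        d = LogLogDataset(np.r_[x1, x2], np.r_[y1, y2],
                          group=np.array(["a"] * 40 + ["b"] * 50))
        fit = fit_sma(d)

        # independent brute-force: dense grid over the residual-fitted
        # correlation statistic per group
        def stat(b):
            tot = 0.0
            for mask in (slice(0, 40), slice(40, 90)):
                xx, yy = d.x[mask], d.y[mask]
                u, v = yy - b * xx, yy + b * xx
                r = np.corrcoef(u, v)[0, 1]
                tot += -len(xx) * math.log(1 - r * r)
            return tot

        grid = np.linspace(0.8, 1.6, 20001)
        vals = [stat(b) for b in grid]
        b_grid = grid[int(np.argmin(vals))]
        assert fit.common_slope == pytest.approx(b_grid, abs=1e-3)

    def test_identical_slopes_different_elevations(self):
        # same generating slope, intercepts 2 apart, small noise: the common
        # slope is accepted and the elevation difference flagged
        rng = np.random.default_rng(11)
        x1 = rng.normal(0, 1, 60)
        x2 = rng.normal(0, 1, 60)
        y1 = 1.2 * x1 + rng.normal(0, 0.05, 60)
        y2 = 2.0 + 1.2 * x2 + rng.normal(0, 0.05, 60)
        d = LogLogDataset(np.r_[x1, x2], np.r_[y1, y2],
                          group=np.array(["g1"] * 60 + ["g2"] * 60))
        fit = fit_sma(d)
        assert fit.common_slope_p > 0.05
        assert fit.pairwise_elevation[("g1", "g2")] < 0.001

    def test_common_slope_null_calibration(self):
        # under a genuinely common slope the LR p-value is not anti-conservative
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x1, y1 = random_loglog(rng, n=40, slope=1.1, sd=0.3)
            x2, y2 = random_loglog(rng, n=40, slope=1.1, intercept=1.0, sd=0.3)
            d = LogLogDataset(np.r_[x1, x2], np.r_[y1, y2],
                              group=np.array(["a"] * 40 + ["b"] * 40))
            rejections += fit_sma(d).common_slope_p < 0.05
        assert rejections <= 20  # ≈ 5% nominal; generous binomial headroom


# ------------------------------------------------------------------ Model I

class TestOLS:
    def test_collinear_gives_cf_one(self):
        x = np.linspace(0, 3, 8)
        f = fit_ols(LogLogDataset(x, 0.7 + 1.3 * x))
        assert f.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert f.cf == pytest.approx(1.0)

    def test_aic_prefers_true_group_effect(self):
        rng = np.random.default_rng(2)
        n = 120
        g = np.array(["a", "b"] * (n // 2))
        x = rng.normal(0, 1, n)
        y = 0.5 + 1.1 * x + np.where(g == "b", 1.5, 0.0) + rng.normal(0, 0.3, n)
        d = LogLogDataset(x, y, group=g)
        assert fit_ols(d, include_group=True).aic < fit_ols(d).aic

    def test_zero_x_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_ols(LogLogDataset(np.ones(6), np.arange(6.0)))


class TestRandomIntercept:
    def test_single_species_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        x, y = random_loglog(rng, n=30)
        d = LogLogDataset(x, y, species=np.array(["only"] * 30))
        m = fit_random_intercept(d)
        o = fit_ols(d)
        assert m.kind == "ols"
        assert m.slope == pytest.approx(o.slope)

    def test_zero_noise_recovers_slope_exactly(self):
        rng = np.random.default_rng(8)
        nsp, nper = 10, 6
        off = rng.normal(0, 0.5, nsp)
        x = rng.normal(0, 1, nsp * nper)
        y = 1.0 + 1.3 * x + np.repeat(off, nper)
        d = LogLogDataset(x, y, species=np.repeat([f"s{i}" for i in range(nsp)], nper))
        m = fit_random_intercept(d)
        assert m.slope == pytest.approx(1.3, abs=1e-6)

    def test_variance_component_recovery(self):
        # species offsets with sd 0.5: REML recovers the realized variance
        rng = np.random.default_rng(12)
        nsp, nper = 50, 20
        off = rng.normal(0, 0.5, nsp)
        x = rng.normal(0, 1, nsp * nper)
        y = 0.3 + 1.0 * x + np.repeat(off, nper) + rng.normal(0, 0.3, nsp * nper)
        d = LogLogDataset(x, y, species=np.repeat([f"s{i}" for i in range(nsp)], nper))
        m = fit_random_intercept(d)
        realized = off.std(ddof=1)
        assert m.sigma_species == pytest.approx(realized, rel=0.15)

    def test_matches_independent_mixed_model_implementation(self):
        sm = pytest.importorskip("statsmodels.formula.api")
        import pandas as pd

        rng = np.random.default_rng(5)
        nsp, nper = 25, 10
        sp = np.repeat([f"s{i}" for i in range(nsp)], nper)
        off = rng.normal(0, 0.4, nsp)
        x = rng.normal(0, 1, nsp * nper)
        y = 0.5 + 1.1 * x + np.repeat(off, nper) + rng.normal(0, 0.35, nsp * nper)
        m = fit_random_intercept(LogLogDataset(x, y, species=np.array(sp)))
        ref = sm.mixedlm("y ~ x", pd.DataFrame(dict(x=x, y=y, sp=sp)),
                         groups="sp").fit(reml=True)
        assert m.intercept == pytest.approx(ref.params["Intercept"], abs=1e-5)
        assert m.slope == pytest.approx(ref.params["x"], abs=1e-5)
        assert m.sigma_species ** 2 == pytest.approx(ref.cov_re.iloc[0, 0], rel=1e-3)
        assert m.residual_sd ** 2 == pytest.approx(ref.scale, rel=1e-3)
        assert m.slope_se == pytest.approx(ref.bse["x"], rel=1e-2)

    def test_profile_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        nsp, nper = 30, 8
        off = rng.normal(0, 0.4, nsp)
        x = rng.normal(0, 1, nsp * nper)
        y = 1.0 * x + np.repeat(off, nper) + rng.normal(0, 0.3, nsp * nper)
        d = LogLogDataset(x, y, species=np.repeat([f"s{i}" for i in range(nsp)], nper))
        m = fit_random_intercept(d)
        lo, hi = profile_ci_sigma_species(d)
        assert lo < m.sigma_species < hi


class TestSelectModel:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(0)
        x, y = random_loglog(rng)
        f = fit_ols(LogLogDataset(x, y))
        assert select_model([f]) is f

    def test_minimum_aic_wins(self):
        rng = np.random.default_rng(0)
        x, y = random_loglog(rng)
        a = fit_ols(LogLogDataset(x, y))
        b = fit_ols(LogLogDataset(x, y))
        a.aic, b.aic = 100.0, 98.2
        assert select_model([a, b]) is b

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_no_group_effect_usually_selects_simpler_model(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 80
            g = np.array(["a", "b"] * (n // 2))
            x = rng.normal(0, 1, n)
            y = 0.2 + 1.0 * x + rng.normal(0, 0.3, n)  # no real group effect
            d = LogLogDataset(x, y, group=g)
            best = select_model([fit_ols(d), fit_ols(d, include_group=True)])
            wins += len(best.params) == 2
        assert wins > 20


# ------------------------------------------------------- Grubbs & CF

class TestGrubbs:
    def test_all_equal_nothing_removed(self):
        r = grubbs_filter(np.ones(6))
        assert r.removed_indices == []

    def test_single_gross_outlier_removed(self):
        r = grubbs_filter(np.array([1.0, 1, 1, 1, 10]), alpha=0.05)
        assert r.removed_indices == [4]
        assert r.statistics[0] == pytest.approx(1.7889, abs=1e-4)
        # critical value from the published t-quantile construction
        assert grubbs_critical_value(5, 0.05) == pytest.approx(1.715, abs=2e-3)

    def test_idempotent(self):
        rng = np.random.default_rng(21)
        v = rng.normal(0, 1, 60)
        v[:3] += 6.0
        first = grubbs_filter(v)
        second = grubbs_filter(v[first.kept_indices])
        assert second.removed_indices == []

    def test_false_positive_rate_near_alpha(self):
        removed = 0
        reps = 300
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            removed += grubbs_filter(rng.normal(0, 1, 100), alpha=0.05).n_removed > 0
        # fraction of clean samples losing ≥1 point ≈ alpha
        assert 0.01 < removed / reps < 0.12

    def test_ties_first_occurrence(self):
        v = np.array([0.0, 9.0, 0.0, 9.0, 0.0, 0.0, 0.1, -0.1])
        r = grubbs_filter(v)
        if r.removed_indices:
            assert r.removed_indices[0] == 1


class TestCorrectionFactor:
    def test_zero_sd(self):
        assert correction_factor(0.0) == 1.0

    def test_published_value_for_pooled_leaf_area_model(self):
        # ln-scale residual sd back-solved from the printed pooled CF
        assert correction_factor(0.3855) == pytest.approx(1.077, abs=1e-3)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            correction_factor(-0.1)

    def test_corrects_lognormal_back_transform_bias(self):
        rng = np.random.default_rng(17)
        n = 4000
        x = rng.normal(0, 1, n)
        y = 1.0 + 0.9 * x + rng.normal(0, 0.5, n)
        fit = fit_ols(LogLogDataset(x, y))
        naive = np.exp(fit.predict_ln(x))
        corrected = fit.cf * naive
        truth = np.exp(y)
        assert abs(corrected.mean() / truth.mean() - 1) < 0.05
        assert naive.mean() < truth.mean() * 0.95  # uncorrected is biased low
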