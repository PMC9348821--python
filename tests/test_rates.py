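"""Rate estimation: OLS oracle equivalence, windows, ANCOVA, rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dielstarch import (
    LightRegime,
    Perturbation,
    RateRegression,
    StarchModel,
    accumulation_rate,
    compare_slopes,
    early_dusk_rate_windows,
    fit_rate,
    mobilization_rate,
    required_rate_ratio,
    simulate_starch,
)
from dielstarch.rates import (
    DegenerateNormalizationError,
    InsufficientDataError,
)

from conftest import linear_night_series, series_from_points


def ols_oracle(t, y):
    """Closed-form normal-equations least squares (independent oracle)."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta  # (intercept, slope)


class TestFitRate:
    def test_collinear_points_exact_slope_zero_se(self):
        s = linear_night_series(dusk_starch=12, slope=-1)
        fit = fit_rate(s, (12, 24))
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.se_slope == pytest.approx(0.0, abs=1e-9)
        assert fit.ci95[0] <= fit.slope <= fit.ci95[1]

    def test_normalized_slope_is_fraction_of_dusk_starch(self):
        s = linear_night_series(dusk_starch=12, slope=-1)
        fit = fit_rate(s, (12, 24), normalize=True)
        assert fit.slope == pytest.approx(-1 / 12)

    def test_matches_closed_form_oracle_on_noisy_data(self, t24_12h):
        m = StarchModel(1.0, 24.0, noise_frac=0.08, n_reps=5, seed=3)
        s = simulate_starch(m, t24_12h)
        fit = fit_rate(s, (12, 24))
        sub = s.subset(12, 24).data
        b0, b1 = ols_oracle(sub["zt"], sub["value"])
        assert fit.slope == pytest.approx(b1, abs=1e-10)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)

    def test_too_few_time_points_raises(self):
        s = series_from_points([(12, "r1", 5), (14, "r1", 4)] * 2)
        with pytest.raises(InsufficientDataError):
            fit_rate(s, (12, 24))

    def test_zero_dusk_mean_degenerate_normalization(self):
        s = series_from_points(
            [(12, "r1", 0.0), (16, "r1", 0.0), (20, "r1", 0.0), (24, "r1", 0.0)]
        )
        with pytest.raises(DegenerateNormalizationError):
            fit_rate(s, (12, 24), normalize=True)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 12),
                st.floats(0.0, 50.0, allow_nan=False),
            ),
            min_size=6,
            max_size=30,
        ).filter(lambda pts: len({p[0] for p in pts}) >= 3)
    )
    def test_property_equals_least_squares_oracle(self, pts):
        t = np.array([p[0] for p in pts], float)
        y = np.array([p[1] for p in pts], float)
        est = RateRegression().fit(t, y)
        b0, b1 = ols_oracle(t, y)
        assert est.slope_ == pytest.approx(b1, abs=1e-8)
        assert est.intercept_ == pytest.approx(b0, abs=1e-8)

    def test_scaling_and_shift_invariances(self, t24_12h):
        m = StarchModel(1.0, 24.0, noise_frac=0.05, n_reps=4, seed=9)
        s = simulate_starch(m, t24_12h)
        sub = s.subset(12, 24).data
        t, y = sub["zt"].to_numpy(), sub["value"].to_numpy()
        base = RateRegression().fit(t, y)
        scaled = RateRegression().fit(t, 3.5 * y)
        assert scaled.slope_ == pytest.approx(3.5 * base.slope_)
        shifted = RateRegression().fit(t + 5.0, y)
        assert shifted.slope_ == pytest.approx(base.slope_)
        assert shifted.intercept_ == pytest.approx(
            base.intercept_ - 5.0 * base.slope_
        )


class TestWindows:
    def test_noiseless_accumulation_and_mobilization(self, noiseless_starch):
        assert accumulation_rate(noiseless_starch).slope == pytest.approx(1.0)
        assert mobilization_rate(noiseless_starch).slope == pytest.approx(-1.0)

    def test_photoperiod_response_ratio_recovered(self):
        """85% faster accumulation in a 6-h photoperiod is recovered in CI."""
        r12 = LightRegime(24, 12)
        r6 = LightRegime(24, 6)
        s12 = simulate_starch(StarchModel(1.0, 24.0, seed=1), r12)
        s6 = simulate_starch(StarchModel(1.85, 24.0, seed=2), r6)  # 85% faster
        f12, f6 = accumulation_rate(s12), accumulation_rate(s6)
        ratio_lo = f6.ci95[0] / f12.ci95[1]
        ratio_hi = f6.ci95[1] / f12.ci95[0]
        assert ratio_lo <= 1.85 <= ratio_hi

    def test_darkness_cap_matches_full_night_when_linear(self):
        """T28 night with E past the cap: capped and full windows agree."""
        r = LightRegime(28, 14)
        s = simulate_starch(
            StarchModel(1.0, 29.0, noise_frac=0.0, n_reps=2), r, sample_every_h=14 / 6
        )
        full = mobilization_rate(s)
        capped = mobilization_rate(s, cap_darkness_h=8.5)
        assert capped.slope == pytest.approx(full.slope, abs=1e-9)
        assert capped.n_points < full.n_points


class TestEarlyDusk:
    @staticmethod
    def _pair(treated_slope=-0.5):
        control = linear_night_series(dusk_starch=12, slope=-1.0)
        r_t = LightRegime(24, 12, perturbation=Perturbation("early_dusk", at_zt=8))
        pts = []
        for zt in np.arange(8, 24.1, 2.0):
            v = max(8.0 + treated_slope * (zt - 8.0), 0.0)
            pts += [(float(zt), "r1", v), (float(zt), "r2", v)]
        treated = series_from_points(pts, regime=r_t)
        return control, treated

    def test_halved_rate_recovered(self):
        control, treated = self._pair(-0.5)
        full, matched, initial = early_dusk_rate_windows(control, treated)
        assert initial.slope / full.slope == pytest.approx(0.5)
        # matched window: control points with content <= 8, i.e. ZT16-ZT24
        assert matched.window[0] == pytest.approx(16.0)

    def test_truncation_without_slowdown_gives_ratio_one(self):
        control, treated = self._pair(-1.0)
        full, _, initial = early_dusk_rate_windows(control, treated)
        assert initial.slope / full.slope == pytest.approx(1.0, abs=1e-6)

    def test_percent_decrease_recovered_from_noisy_scenario(self):
        rng_c = StarchModel(1.0, 24.0, noise_frac=0.03, n_reps=4, seed=21)
        control = simulate_starch(rng_c, LightRegime(24, 12))
        r_t = LightRegime(24, 12, perturbation=Perturbation("early_dusk", at_zt=8))
        slope_t = -0.85  # 15% slowdown vs control's -1
        pts = []
        rng = np.random.default_rng(22)
        for zt in np.arange(8, 24.1, 2.0):
            mu = max(8.0 + slope_t * (zt - 8.0), 0.0)
            for r in range(4):
                pts.append((float(zt), f"r{r}", max(mu + rng.normal(0, 0.24), 0)))
        treated = series_from_points(pts, regime=r_t)
        full, _, initial = early_dusk_rate_windows(control, treated)
        decrease = 1 - initial.slope / full.slope
        assert decrease == pytest.approx(0.15, abs=0.06)


class TestCompareSlopes:
    def test_identical_groups_zero_interaction(self, t24_12h):
        s = simulate_starch(StarchModel(1.0, 24.0, noise_frac=0.05, seed=4), t24_12h)
        res = compare_slopes(s, s, (12, 24))
        assert res.f_interaction == pytest.approx(0.0, abs=1e-8)

    def test_distinct_slopes_highly_significant(self):
        rng = np.random.default_rng(0)
        def noisy(slope):
            pts = []
            for zt in np.arange(12, 24.1, 2.0):
                for r in range(4):
                    pts.append(
                        (float(zt), f"r{r}", 13 + slope * (zt - 12) + rng.normal(0, 0.01))
                    )
            return series_from_points(pts)
        res = compare_slopes(noisy(-1.0), noisy(-0.5), (12, 24))
        assert res.p_interaction < 1e-6

    def test_type1_error_calibrated_under_h0(self):
        """Equal slopes, different intercepts: ~5% rejections, uniform p."""
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(400):
            pts_a, pts_b = [], []
            for zt in np.arange(12, 24.1, 3.0):
                for r in range(3):
                    pts_a.append((float(zt), f"r{r}", 12 - 0.5 * (zt - 12) + rng.normal(0, 0.5)))
                    pts_b.append((float(zt), f"r{r}", 14 - 0.5 * (zt - 12) + rng.normal(0, 0.5)))
            res = compare_slopes(
                series_from_points(pts_a), series_from_points(pts_b), (12, 24)
            )
            pvals.append(res.p_interaction)
        pvals = np.asarray(pvals)
        assert 0.02 <= np.mean(pvals < 0.05) <= 0.09
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestRequiredRateRatio:
    def test_early_dusk_arithmetic_from_results(self):
        assert required_rate_ratio(2 / 3, 12, 16) == pytest.approx(0.5)

    def test_identity_and_general_arithmetic(self):
        assert required_rate_ratio(1.0, 12, 12) == 1.0
        assert required_rate_ratio(0.5, 12, 18) == pytest.approx(1 / 3)

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(Exception):
            required_rate_ratio(0.5, 0, 12)
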