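"""Rates of starch accumulation and mobilization.

Rates are the slopes of ordinary least-squares fits of starch content
against ZT over the light period (accumulation) or the night
(mobilization), fitted to all biological replicates — never to
time-point means — so standard errors reflect replicate scatter.
95% CIs use the Student-t quantile on the slope's standard error.
Relative (dusk-normalized) rates divide every value by the mean dusk
starch of the series before fitting, giving fraction-of-dusk-starch h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator

from .core import DielSeries, ValidationError


class InsufficientDataError(ValueError):
    """Fewer than three sampled time points in the fit window."""


class DegenerateNormalizationError(ValueError):
    """Dusk mean is zero; relative rates are undefined."""


@dataclass(frozen=True)
class SlopeFit:
    """A fitted linear rate with its uncertainty and fit-window metadata."""

    slope: float
    intercept: float
    se_slope: float
    ci95: Tuple[float, float]
    n_points: int  # distinct sampled time points in the window
    n_obs: int  # replicate observations used
    window: Tuple[float, float]
    normalized: bool
    cov: Optional[np.ndarray] = None  # 2x2 covariance of (intercept, slope)

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.slope <= hi + 1e-12):
            raise ValidationError("ci95 must contain the slope")


class RateRegression(BaseEstimator):
    """OLS slope of value against time over a closed window.

    Parameters
    ----------
    window : (float, float) or None
        Closed ZT window; boundary samples included. None fits all data.
    normalize : bool
        Divide values by ``dusk_mean`` (supplied to :meth:`fit`) before
        fitting, yielding a relative rate in fraction h⁻¹.

    Attributes (after fit)
    ----------------------
    slope_, intercept_, se_slope_, se_intercept_, cov_, ci95_,
    n_points_, n_obs_
    """

    def __init__(self, window=None, normalize=False):
        self.window = window
        self.normalize = normalize

    def fit(self, t, y, dusk_mean: Optional[float] = None):
        t = np.asarray(t, float).ravel()
        y = np.asarray(y, float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have equal length")
        if self.window is not None:
            lo, hi = self.window
            keep = (t >= lo - 1e-9) & (t <= hi + 1e-9)
            t, y = t[keep], y[keep]
        n_points = np.unique(t).size
        if n_points < 3:
            raise InsufficientDataError(
                f"need >= 3 sampled time points in window, got {n_points}"
            )
        if self.normalize:
            if dusk_mean is None:
                raise ValueError("normalize=True requires dusk_mean")
            if dusk_mean == 0:
                raise DegenerateNormalizationError("mean dusk value is zero")
            y = y / dusk_mean
        X = sm.add_constant(t)
        res = sm.OLS(y, X).fit()
        self.intercept_, self.slope_ = res.params
        self.se_intercept_, self.se_slope_ = res.bse
        self.cov_ = np.asarray(res.cov_params())
        tcrit = stats.t.ppf(0.975, res.df_resid) if res.df_resid > 0 else np.inf
        half = tcrit * self.se_slope_
        if not np.isfinite(self.se_slope_) or self.se_slope_ == 0:
            half = 0.0
        self.ci95_ = (self.slope_ - half, self.slope_ + half)
        self.n_points_ = int(n_points)
        self.n_obs_ = int(t.size)
        self._window_used = (float(t.min()), float(t.max()))
        return self

    def predict(self, t):
        t = np.asarray(t, float)
        return self.intercept_ + self.slope_ * t

    def to_slope_fit(self) -> SlopeFit:
        return SlopeFit(
            slope=float(self.slope_),
            intercept=float(self.intercept_),
            se_slope=float(self.se_slope_),
            ci95=(float(self.ci95_[0]), float(self.ci95_[1])),
            n_points=self.n_points_,
            n_obs=self.n_obs_,
            window=self.window if self.window is not None else self._window_used,
            normalized=bool(self.normalize),
            cov=self.cov_,
        )


def dusk_mean(s: DielSeries) -> float:
    """Arithmetic mean of all dusk replicate values of the series."""
    vals = s.values_at(s.regime.dusk_zt)
    if vals.size == 0:
        raise ValidationError("no dusk sample present")
    return float(vals.mean())


def fit_rate(
    s: DielSeries, window: Tuple[float, float], normalize: bool = False
) -> SlopeFit:
    """OLS rate over the closed ``window`` on all replicate points."""
    est = RateRegression(window=window, normalize=normalize)
    dm = dusk_mean(s) if normalize else None
    est.fit(s.data["zt"], s.data["value"], dusk_mean=dm)
    return est.to_slope_fit()


def accumulation_rate(s: DielSeries, normalize: bool = False) -> SlopeFit:
    """Slope over all time points between dawn and dusk (both included)."""
    return fit_rate(s, (0.0, s.regime.dusk_zt), normalize=normalize)


def mobilization_rate(
    s: DielSeries,
    normalize: bool = False,
    cap_darkness_h: Optional[float] = None,
) -> SlopeFit:
    """Slope over time points between dusk and the next dawn.

    ``cap_darkness_h`` restricts the window to the first so-many hours of
    darkness (8.5 h in T-cycle comparisons, so T17/T24/T28 nights are
    compared over the same duration after dusk).
    """
    dusk = s.regime.dusk_zt
    end = s.regime.cycle_length_h
    if cap_darkness_h is not None:
        end = min(end, dusk + cap_darkness_h)
    return fit_rate(s, (dusk, end), normalize=normalize)


def required_rate_ratio(
    dusk_fraction: float, night_base_h: float, night_new_h: float
) -> float:
    """Required new/old mobilization-rate ratio under R = S/T.

    If dusk starch falls to ``dusk_fraction`` of its usual level and the
    night lengthens from ``night_base_h`` to ``night_new_h``, exhausting
    starch at the accustomed dawn requires the mobilization rate to change
    by the factor returned (e.g. 2/3 of the starch over a 16-h instead of
    12-h night → ratio 0.5, a 50% decrease).
    """
    if night_base_h <= 0 or night_new_h <= 0:
        raise ValidationError("night durations must be positive")
    return dusk_fraction * night_base_h / night_new_h


def early_dusk_rate_windows(
    control: DielSeries, treated: DielSeries
) -> Tuple[SlopeFit, SlopeFit, SlopeFit]:
    """Rate fits for the sudden-early-dusk comparison.

    Returns (control_full, control_matched, treated_initial):

    * control_full — control mobilization over the whole night;
    * control_matched — control restricted to time points whose mean
      starch is at or below the treated plants' content when they were
      darkened, matching the starch range of the treatment;
    * treated_initial — treated night rate excluding time points where
      mean starch has fallen below the control's dawn level (where the
      decline is no longer linear).

    Content cutoffs are resolved against time-point means; whole time
    points are kept or dropped.
    """
    pert = treated.regime.perturbation
    if pert is None or pert.kind != "early_dusk":
        raise ValidationError("treated series must carry an early_dusk perturbation")
    c_dusk = control.regime.dusk_zt
    t_dark = treated.regime.dusk_zt
    cycle = control.regime.cycle_length_h

    control_full = fit_rate(control, (c_dusk, cycle))

    darkening_content = float(treated.values_at(t_dark).mean())
    cg = control.data.groupby("zt")["value"].mean()
    night_zts = [z for z in cg.index if z >= c_dusk - 1e-9]
    matched_zts = [z for z in night_zts if cg[z] <= darkening_content + 1e-9]
    if len(matched_zts) < 3:
        raise InsufficientDataError(
            "matched control window has fewer than 3 time points"
        )
    control_matched = fit_rate(control, (min(matched_zts), max(matched_zts)))

    dawn_vals = control.values_at(cycle)
    if dawn_vals.size == 0:
        raise ValidationError("control series lacks a dawn (ZT=cycle_length) sample")
    dawn_mean = float(dawn_vals.mean())
    tg = treated.data.groupby("zt")["value"].mean()
    # contiguous run from darkening onward: stop at the first time point
    # whose mean has fallen to the control's dawn level (decline is no
    # longer linear beyond it; later noise blips must not re-extend it)
    initial_zts = []
    for z in sorted(tg.index):
        if z < t_dark - 1e-9:
            continue
        if tg[z] <= dawn_mean + 1e-9:
            break
        initial_zts.append(z)
    if len(initial_zts) < 3:
        raise InsufficientDataError(
            "treated initial window has fewer than 3 time points"
        )
    treated_initial = fit_rate(treated, (min(initial_zts), max(initial_zts)))
    return control_full, control_matched, treated_initial


@dataclass(frozen=True)
class SlopeComparison:
    """ANCOVA slope-difference test (group × time interaction, type III)."""

    f_interaction: float
    p_interaction: float
    df_num: float
    df_den: float
    degenerate: bool = False


def compare_slopes(
    a: DielSeries, b: DielSeries, window: Tuple[float, float]
) -> SlopeComparison:
    """Test whether two series have different rates over ``window``.

    Fits value ~ group + zt + group:zt on the pooled replicates with
    sum-to-zero group contrasts and reports the interaction term's
    type-III F and p.
    """
    frames = []
    for label, s in (("a", a), ("b", b)):
        sub = s.subset(*window).data
        frames.append(
            pd.DataFrame(
                {"zt": sub["zt"], "value": sub["value"], "group": label}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    model = smf.ols("value ~ C(group, Sum) * zt", data=df).fit()
    if model.ssr <= 1e-12 * max(1.0, float(np.sum(df["value"] ** 2))):
        return SlopeComparison(np.nan, np.nan, 1, model.df_resid, degenerate=True)
    table = sm.stats.anova_lm(model, typ=3)
    row = table.loc["C(group, Sum):zt"]
    return SlopeComparison(
        f_interaction=float(row["F"]),
        p_interaction=float(row["PR(>F)"]),
        df_num=float(row["df"]),
        df_den=float(model.df_resid),
    )
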