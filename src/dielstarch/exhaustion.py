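"""Starch-exhaustion-time estimation.

StEx ("time of starch exhaustion") is the ZT at which the night linear
fit of starch content reaches zero, found as the root of
f(ZT) = intercept + slope·ZT with a bracketed derivative-free root
finder, and reported in hours after the previous dawn.  Its SE comes
from first-order (delta-method) propagation of the x-intercept −b/m
through the slope/intercept covariance:

    var(−b/m) = var(b)/m² + b²·var(m)/m⁴ − 2·b·cov(b,m)/m³

StEx^app ("apparent StEx") extrapolates the *initial* mobilization rate:
nested fits over k = 3 … K consecutive time points anchored at dusk,
each restricted to the first ``max_darkness_h`` (default 8.5 h) of the
night, each extrapolated to zero; the estimate is the geometric mean of
the roots with a Student-t 95% CI formed on the log scale and
exponentiated.  With 2-h sampling and the 8.5-h cap this yields windows
of 3, 4 and 5 points (n = 3 fits).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .core import DielSeries, ValidationError
from .rates import RateRegression, SlopeFit, fit_rate

logger = logging.getLogger(__name__)


class NoExhaustionError(ValueError):
    """The fitted night slope is non-negative; no zero crossing exists."""


@dataclass(frozen=True)
class ExhaustionEstimate:
    """StEx or StEx^app, in hours after the previous dawn."""

    kind: str  # "StEx" | "StEx_app"
    hours_after_dawn: float
    se: Optional[float] = None  # StEx only
    ci95: Optional[Tuple[float, float]] = None  # StEx_app only
    n_fits: int = 1
    windows: Tuple[Tuple[float, float], ...] = ()
    degenerate: bool = False  # root earlier than dusk


def _root_of_fit(intercept: float, slope: float, dusk: float, cycle: float) -> float:
    """Zero of intercept + slope·ZT by bracketed Brent search."""
    if slope >= 0:
        raise NoExhaustionError(f"night slope {slope:.4g} is not negative")
    f = lambda zt: intercept + slope * zt
    lo, hi = 0.0, dusk + 3.0 * cycle
    if f(lo) < 0 or f(hi) > 0:  # pragma: no cover - negative slope brackets
        raise NoExhaustionError("root is not bracketed within three cycles of dusk")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def _stex_from_fit(fit: SlopeFit, dusk: float, cycle: float) -> ExhaustionEstimate:
    root = _root_of_fit(fit.intercept, fit.slope, dusk, cycle)
    b, m = fit.intercept, fit.slope
    if fit.cov is not None:
        var_b = fit.cov[0, 0]
        var_m = fit.cov[1, 1]
        cov_bm = fit.cov[0, 1]
        var_root = (
            var_b / m**2 + b**2 * var_m / m**4 - 2.0 * b * cov_bm / m**3
        )
        se = float(np.sqrt(max(var_root, 0.0)))
    else:
        se = None
    return ExhaustionEstimate(
        kind="StEx",
        hours_after_dawn=root,
        se=se,
        n_fits=1,
        windows=(fit.window,),
        degenerate=root < dusk - 1e-9,
    )


def stex(
    s: DielSeries, window: Optional[Tuple[float, float]] = None
) -> ExhaustionEstimate:
    """Single-extrapolation StEx from the night linear fit.

    ``window`` defaults to the whole night [dusk, cycle_length]; a root
    before dusk is flagged ``degenerate`` rather than raised.
    """
    dusk = s.regime.dusk_zt
    if window is None:
        window = (dusk, s.regime.cycle_length_h)
    fit = fit_rate(s, window)
    return _stex_from_fit(fit, dusk, s.regime.cycle_length_h)


def stex_app(s: DielSeries, max_darkness_h: float = 8.5) -> ExhaustionEstimate:
    """Nested-window StEx^app: geometric mean of dusk-anchored extrapolations.

    Windows always start at dusk and grow one time point at a time, from
    three points up to every sampled point within ``max_darkness_h`` of
    darkness.  Windows whose slope is non-negative are excluded with a
    warning; if all are excluded, a :class:`NoExhaustionError` is raised.
    """
    dusk = s.regime.dusk_zt
    cycle = s.regime.cycle_length_h
    cap = min(cycle, dusk + max_darkness_h)
    night_zts = [z for z in s.zts if dusk - 1e-9 <= z <= cap + 1e-9]
    if len(night_zts) < 3:
        raise ValidationError(
            "need >= 3 sampled time points between dusk and the darkness cap"
        )
    roots, windows = [], []
    for k in range(3, len(night_zts) + 1):
        win = (night_zts[0], night_zts[k - 1])
        fit = fit_rate(s, win)
        if fit.slope >= 0:
            warnings.warn(
                f"nested window {win} has non-negative slope; excluded",
                stacklevel=2,
            )
            continue
        roots.append(_root_of_fit(fit.intercept, fit.slope, dusk, cycle))
        windows.append(win)
    if not roots:
        raise NoExhaustionError("every nested window had a non-negative slope")
    roots = np.asarray(roots)
    log_roots = np.log(roots)
    gmean = float(np.exp(log_roots.mean()))
    # AM-GM: the geometric mean can never exceed the arithmetic mean
    assert gmean <= roots.mean() + 1e-9
    n = len(roots)
    if n > 1 and log_roots.std(ddof=1) > 0:
        se_log = log_roots.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (
            float(np.exp(log_roots.mean() - tcrit * se_log)),
            float(np.exp(log_roots.mean() + tcrit * se_log)),
        )
    else:
        ci = (gmean, gmean)
    return ExhaustionEstimate(
        kind="StEx_app",
        hours_after_dawn=gmean,
        ci95=ci,
        n_fits=n,
        windows=tuple(windows),
        degenerate=gmean < dusk - 1e-9,
    )


def stex_shift(a: ExhaustionEstimate, b: ExhaustionEstimate) -> float:
    """Difference b − a in hours (e.g. StEx^app at T28 minus at T17)."""
    return float(b.hours_after_dawn - a.hours_after_dawn)


class ExhaustionExtrapolator(BaseEstimator):
    """Estimator wrapper: fit a night series, expose ``hours_after_dawn_``
    and uncertainty attributes.

    method="single" reproduces StEx; method="nested" StEx^app.
    """

    def __init__(self, method: str = "single", max_darkness_h: float = 8.5):
        self.method = method
        self.max_darkness_h = max_darkness_h

    def fit(self, series: DielSeries):
        if self.method == "single":
            est = stex(series)
        elif self.method == "nested":
            est = stex_app(series, max_darkness_h=self.max_darkness_h)
        else:
            raise ValueError("method must be 'single' or 'nested'")
        self.estimate_ = est
        self.hours_after_dawn_ = est.hours_after_dawn
        self.se_ = est.se
        self.ci95_ = est.ci95
        self.n_fits_ = est.n_fits
        return self
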