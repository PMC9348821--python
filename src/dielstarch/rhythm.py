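"""Peak time and amplitude of oscillating transcript time series.

Peak time is the average peak location of curves fitted to bootstrapped
time series: replicates are resampled within each time point, a
polynomial (degree 2–6) and a smoothing spline (degrees of freedom
4 … min(10, #ZTs − 1)) are fitted to each draw, each model selected by
minimum small-sample-corrected AIC (AICc), and the fitted curve's global
maximum located (50 draws per method by default).  The reported peak is
the circular mean of the per-draw peaks with a bootstrap percentile 95%
CI on the circular residuals.  Series are unwrapped into a window
starting in the late night (ZT18 for a 24-h cycle) so peaks near dawn
are interior to the fit window.

Amplitude is max − min of the time-point mean levels over one full
cycle, with Gaussian error propagation of the two SEMs:
SE = sqrt(SEM_max² + SEM_min²), CI = ± t·SE.

Draws in which the selected curve is monotone carry no peak; if more
than half of all draws are monotone the series is reported unscorable
(weak oscillations prevent reliable definition of peak time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline
from sklearn.base import BaseEstimator

from .core import DielSeries, ValidationError


@dataclass
class RhythmFeature:
    """Peak ZT and/or amplitude of an oscillating series."""

    peak_zt: Optional[float] = None  # circular, hours in [0, cycle)
    peak_ci95: Optional[Tuple[float, float]] = None
    amplitude: Optional[float] = None
    amplitude_se: Optional[float] = None
    amplitude_ci95: Optional[Tuple[float, float]] = None
    scorable: bool = True
    n_draws_used: int = 0
    method_detail: Optional[dict] = None


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0 or rss <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _curve_peak(grid: np.ndarray, fitted: np.ndarray) -> Optional[float]:
    """Location of the global maximum; None when the curve is monotone."""
    d = np.diff(fitted)
    tol = 1e-12 * max(1.0, float(np.abs(fitted).max()))
    if np.all(d >= -tol) or np.all(d <= tol):
        return None
    return float(grid[np.argmax(fitted)])


def _fit_best_polynomial(x, y, grid):
    n = x.size
    best, best_aicc = None, np.inf
    for degree in range(2, 7):
        k = degree + 2  # coefficients + residual variance
        if n - k - 1 <= 0:
            continue
        coeffs = np.polyfit(x, y, degree)
        rss = float(np.sum((np.polyval(coeffs, x) - y) ** 2))
        a = _aicc(rss, n, k)
        if a < best_aicc - 1e-12:  # ties break toward fewer parameters
            best, best_aicc = coeffs, a
    if best is None:
        return None
    return np.polyval(best, grid)


def _fit_best_spline(x, y, grid, n_distinct):
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    uniq = np.unique(xs)
    best, best_aicc = None, np.inf
    for df in range(4, min(10, n_distinct - 1) + 1):
        n_interior = df - 4
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            knots = np.quantile(uniq, qs)
            knots = knots[(knots > xs[0]) & (knots < xs[-1])]
        else:
            knots = np.array([])
        try:
            spl = LSQUnivariateSpline(xs, ys, knots, k=3)
        except Exception:
            continue
        rss = float(np.sum((spl(xs) - ys) ** 2))
        a = _aicc(rss, xs.size, df + 1)
        if a < best_aicc - 1e-12:
            best, best_aicc = spl, a
    if best is None:
        return None
    return best(grid)


def _circular_mean(values: np.ndarray, cycle: float) -> float:
    ang = 2.0 * np.pi * values / cycle
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean_ang * cycle / (2.0 * np.pi)) % cycle)


class PeakEstimator(BaseEstimator):
    """Bootstrap peak-time estimator over polynomial and spline fits.

    Parameters
    ----------
    n_boot_per_method : bootstrap draws per curve family (default 50).
    unwrap_start : ZT at which the unwrapped fit window opens; default
        0.75·cycle_length (ZT18 in a 24-h cycle) so dawn-adjacent peaks
        sit mid-window.
    seed : RNG seed.
    """

    def __init__(self, n_boot_per_method: int = 50, unwrap_start=None, seed: int = 0):
        self.n_boot_per_method = n_boot_per_method
        self.unwrap_start = unwrap_start
        self.seed = seed

    def fit(self, series: DielSeries):
        cycle = series.regime.cycle_length_h
        start = (
            self.unwrap_start
            if self.unwrap_start is not None
            else 0.75 * cycle
        )
        zt = series.data["zt"].to_numpy(float)
        val = series.data["value"].to_numpy(float)
        # unwrap: late-night points keep their ZT, earlier points shift +T;
        # ZT0 and ZT=T are the same circular instant and pool together
        unwrapped = np.where(zt >= start - 1e-9, zt, zt + cycle)
        unwrapped = np.round(unwrapped, 9)
        uniq = np.unique(unwrapped)
        if uniq.size < 5:
            raise ValidationError("need >= 5 distinct sampled time points")
        groups = [val[unwrapped == u] for u in uniq]
        if any(g.size < 2 for g in groups):
            raise ValidationError("need >= 2 replicates at every time point")
        grid = np.arange(uniq[0], uniq[-1] + 1e-9, 0.05)
        rng = np.random.default_rng(self.seed)
        peaks, n_monotone, n_total = [], 0, 0
        for method in ("polynomial", "spline"):
            for _ in range(self.n_boot_per_method):
                ys = np.concatenate(
                    [g[rng.integers(0, g.size, g.size)] for g in groups]
                )
                xs = np.concatenate(
                    [np.full(g.size, u) for g, u in zip(groups, uniq)]
                )
                if method == "polynomial":
                    fitted = _fit_best_polynomial(xs, ys, grid)
                else:
                    fitted = _fit_best_spline(xs, ys, grid, uniq.size)
                n_total += 1
                if fitted is None:
                    n_monotone += 1
                    continue
                peak = _curve_peak(grid, fitted)
                if peak is None:
                    n_monotone += 1
                    continue
                peaks.append(peak % cycle)
        detail = {
            "n_boot_per_method": self.n_boot_per_method,
            "methods": ["polynomial", "spline"],
            "n_monotone": n_monotone,
        }
        if n_monotone > 0.5 * n_total:
            self.feature_ = RhythmFeature(
                scorable=False, n_draws_used=len(peaks), method_detail=detail
            )
            self.scorable_ = False
            self.peak_zt_ = None
            return self
        peaks = np.asarray(peaks)
        center = _circular_mean(peaks, cycle)
        resid = (peaks - center + cycle / 2.0) % cycle - cycle / 2.0
        lo, hi = np.percentile(resid, [2.5, 97.5])
        self.peak_zt_ = center
        self.peak_ci95_ = (center + float(lo), center + float(hi))
        self.scorable_ = True
        self.feature_ = RhythmFeature(
            peak_zt=center,
            peak_ci95=self.peak_ci95_,
            scorable=True,
            n_draws_used=len(peaks),
            method_detail=detail,
        )
        return self


def peak_time(
    s: DielSeries, n_boot_per_method: int = 50, seed: int = 0, unwrap_start=None
) -> RhythmFeature:
    """Bootstrapped peak ZT of an oscillating series (see module docs)."""
    est = PeakEstimator(
        n_boot_per_method=n_boot_per_method, unwrap_start=unwrap_start, seed=seed
    ).fit(s)
    return est.feature_


class AmplitudeEstimator(BaseEstimator):
    """Max − min of time-point means with Gaussian error propagation."""

    def fit(self, series: DielSeries):
        g = series.data.groupby("zt")["value"]
        means = g.mean()
        if means.size < 2:
            raise ValidationError("need >= 2 time points for an amplitude")
        sems = g.sem(ddof=1)
        counts = g.count()
        zt_max, zt_min = means.idxmax(), means.idxmin()
        amp = float(means[zt_max] - means[zt_min])
        se = float(np.sqrt(sems[zt_max] ** 2 + sems[zt_min] ** 2))
        df = int(counts[zt_max] + counts[zt_min] - 2)
        half = stats.t.ppf(0.975, df) * se if df > 0 else np.inf
        self.amplitude_ = amp
        self.se_ = se
        self.ci95_ = (amp - half, amp + half)
        self.feature_ = RhythmFeature(
            amplitude=amp, amplitude_se=se, amplitude_ci95=self.ci95_
        )
        return self


def amplitude(s: DielSeries) -> RhythmFeature:
    """Oscillation amplitude over one full cycle (max − min of means)."""
    return AmplitudeEstimator().fit(s).feature_
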