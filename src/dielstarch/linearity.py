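"""Ad hoc score for nonlinearity of night-time starch mobilization.

A chord is drawn between the dusk and dawn mean starch contents; at each
interior time point the residue is (observed mean − chord prediction)
normalized on the chord prediction, and the score is the mean of these
normalized residues.  Zero means linear mobilization; negative means
starch is mobilized too fast early in the night (content runs below the
chord); positive means too slow.  The 95% CI is a nonparametric
bootstrap: replicates are resampled within each time point — endpoints
included, so the chord is re-anchored on every draw — and the percentile
interval of the resampled scores is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core import DielSeries, ValidationError
from .statsutil import tukey_letters


@dataclass(frozen=True)
class NonlinearityResult:
    score: float
    ci95: Optional[Tuple[float, float]]
    n_interior_points: int
    per_point_residues: Tuple[float, ...]

    def __post_init__(self):
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo - 1e-9 <= self.score <= hi + 1e-9):
                raise ValidationError("ci95 must contain the score")


def _chord_score(
    zts: np.ndarray,
    means: np.ndarray,
    dusk_zt: float,
    dawn_zt: float,
    include_endpoints: bool,
) -> Tuple[float, np.ndarray]:
    dusk_mean = means[np.argmin(np.abs(zts - dusk_zt))]
    dawn_mean = means[np.argmin(np.abs(zts - dawn_zt))]
    slope = (dawn_mean - dusk_mean) / (dawn_zt - dusk_zt)
    residues = []
    for zt, obs in zip(zts, means):
        interior = dusk_zt + 1e-9 < zt < dawn_zt - 1e-9
        if not interior and not include_endpoints:
            continue
        pred = dusk_mean + slope * (zt - dusk_zt)
        if pred <= 0:
            if interior:
                warnings.warn(
                    f"chord prediction non-positive at ZT{zt:g}; point excluded",
                    stacklevel=3,
                )
            continue
        residues.append((obs - pred) / pred)
    residues = np.asarray(residues)
    if residues.size == 0:
        raise ValidationError("no usable interior time point for the score")
    return float(residues.mean()), residues


def nonlinearity(
    s: DielSeries,
    n_boot: int = 1000,
    seed: int = 0,
    include_endpoints: bool = True,
) -> NonlinearityResult:
    """Nonlinearity score of the night decay with a bootstrap 95% CI.

    Residues are averaged across all night time points, endpoints
    included: the dusk/dawn residues are identically zero in the point
    estimate (the chord is anchored on them), so including them rescales
    the interior mean by (n−2)/n.  Set ``include_endpoints=False`` to
    average interior residues only.  ``n_boot=0`` skips the CI.
    """
    dusk_zt = s.regime.dusk_zt
    dawn_zt = s.regime.cycle_length_h
    night = s.subset(dusk_zt, dawn_zt)
    groups = {
        zt: night.data.loc[night.data["zt"] == zt, "value"].to_numpy(float)
        for zt in night.zts
    }
    zts = np.array(sorted(groups))
    if not np.any(np.abs(zts - dusk_zt) < 1e-9) or not np.any(
        np.abs(zts - dawn_zt) < 1e-9
    ):
        raise ValidationError("dusk and dawn reference samples are required")
    means = np.array([groups[zt].mean() for zt in zts])
    d_mean = means[np.argmin(np.abs(zts - dusk_zt))]
    a_mean = means[np.argmin(np.abs(zts - dawn_zt))]
    if not (d_mean > a_mean >= 0):
        raise ValidationError(
            f"need dusk mean > dawn mean >= 0; got {d_mean:g}, {a_mean:g}"
        )
    n_interior = int(np.sum((zts > dusk_zt + 1e-9) & (zts < dawn_zt - 1e-9)))
    if n_interior < 1:
        raise ValidationError("need at least one interior time point")
    score, residues = _chord_score(zts, means, dusk_zt, dawn_zt, include_endpoints)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        arrays = [groups[zt] for zt in zts]
        for i in range(n_boot):
            boot_means = np.array(
                [a[rng.integers(0, a.size, a.size)].mean() for a in arrays]
            )
            try:
                draws[i], _ = _chord_score(
                    zts, boot_means, dusk_zt, dawn_zt, include_endpoints
                )
            except ValidationError:
                draws[i] = np.nan
        lo, hi = np.nanpercentile(draws, [2.5, 97.5])
        ci = (min(float(lo), score), max(float(hi), score))
    return NonlinearityResult(
        score=score,
        ci95=ci,
        n_interior_points=n_interior,
        per_point_residues=tuple(residues),
    )


class NonlinearityScorer(BaseEstimator):
    """Estimator form of :func:`nonlinearity` with fitted attributes
    ``score_``, ``ci95_``, ``residues_``."""

    def __init__(self, n_boot: int = 1000, seed: int = 0, include_endpoints=True):
        self.n_boot = n_boot
        self.seed = seed
        self.include_endpoints = include_endpoints

    def fit(self, series: DielSeries):
        res = nonlinearity(
            series,
            n_boot=self.n_boot,
            seed=self.seed,
            include_endpoints=self.include_endpoints,
        )
        self.result_ = res
        self.score_ = res.score
        self.ci95_ = res.ci95
        self.residues_ = res.per_point_residues
        return self


@dataclass(frozen=True)
class NonlinearityComparison:
    f: float
    p: float
    letters: dict
    scores: dict


def _per_replicate_scores(
    s: DielSeries, include_endpoints: bool
) -> np.ndarray:
    """Nonlinearity score of each replicate's own night trajectory."""
    dusk_zt, dawn_zt = s.regime.dusk_zt, s.regime.cycle_length_h
    night = s.subset(dusk_zt, dawn_zt)
    wide = night.data.pivot_table(
        index="replicate", columns="zt", values="value", aggfunc="mean"
    )
    zts = np.asarray(wide.columns, float)
    out = []
    for _, row in wide.iterrows():
        vals = row.to_numpy(float)
        ok = ~np.isnan(vals)
        if not (
            np.any(np.abs(zts[ok] - dusk_zt) < 1e-9)
            and np.any(np.abs(zts[ok] - dawn_zt) < 1e-9)
        ):
            continue
        try:
            d, _ = _chord_score(zts[ok], vals[ok], dusk_zt, dawn_zt, include_endpoints)
        except ValidationError:
            continue
        out.append(d)
    return np.asarray(out)


def compare_nonlinearity(
    groups: Sequence[DielSeries],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    include_endpoints: bool = True,
) -> NonlinearityComparison:
    """One-way ANOVA + Tukey HSD letters across groups' nonlinearity scores.

    The ANOVA unit is the per-replicate-profile score: each biological
    replicate's own night trajectory yields one score, so group sizes
    reflect the true replication.  Groups sharing a letter have
    statistically indistinguishable nonlinearity at ``alpha``.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    all_scores, all_labels, scores = [], [], {}
    for label, s in zip(labels, groups):
        scores[label] = nonlinearity(s, n_boot=0, include_endpoints=include_endpoints).score
        rep_scores = _per_replicate_scores(s, include_endpoints)
        if rep_scores.size < 2:
            raise ValidationError(
                f"group {label!r} has fewer than 2 complete replicate profiles"
            )
        all_scores.extend(rep_scores)
        all_labels.extend([label] * rep_scores.size)
    draws = np.asarray(all_scores)
    labs = np.asarray(all_labels)
    if np.ptp(draws) == 0:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*[draws[labs == l] for l in labels])
    letters = tukey_letters(draws, labs, alpha=alpha)
    return NonlinearityComparison(f=float(f), p=float(p), letters=letters, scores=scores)
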