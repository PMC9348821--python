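"""Dawn/dusk alignment scoring of transcript profiles across photoperiods.

For each transcript, mean ± SEM profiles from different photoperiod
treatments are re-anchored to dawn or to dusk and compared on a shared
offset grid.  Two scores are computed per anchor:

* DIST — the Euclidean distance between treatment profiles
  (averaged over treatment pairs when there are more than two);
* NORM — the Euclidean distance divided by its first-order propagated
  error, err = sqrt(Σ_j (a_j − b_j)²·(sem_aj² + sem_bj²)) / dist.

Scores are min–max scaled to [0, 1] across an analysis run (0 = best,
1 = worst alignment observed).  A transcript whose expression tracks
time-since-dawn gives a smaller dawn-anchored than dusk-anchored DIST.
A replicate-level two-way ANOVA (photoperiod × offset, type II sums of
squares) tests whether two photoperiod series differ significantly
under a given anchoring.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AlignedProfile, DielSeries, ValidationError, mean_profile
from .statsutil import anova_twoway


@dataclass
class AlignmentScore:
    transcript: str
    anchor: str
    dist_raw: float
    norm_raw: float
    dist_scaled: Optional[float] = None
    norm_scaled: Optional[float] = None
    discriminates: Optional[bool] = None


def _shared_grid(a: AlignedProfile, b: AlignedProfile) -> np.ndarray:
    lo = max(a.offsets.min(), b.offsets.min())
    hi = min(a.offsets.max(), b.offsets.max())
    if hi <= lo:
        raise ValidationError("profiles share no offset range")
    step = min(np.diff(a.offsets).min(), np.diff(b.offsets).min())
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    grid = grid[grid <= hi + 1e-9]
    if grid.size < 3:
        raise ValidationError("fewer than 3 shared offsets after gridding")
    return grid


def pairwise_dist(a: AlignedProfile, b: AlignedProfile) -> Tuple[float, float]:
    """Euclidean distance between two profiles and its error-normalized form.

    Profiles are linearly interpolated onto the intersection of their
    offset ranges at the finest common step.  Returns (dist, norm) where
    norm = dist / propagated error; norm is 0 for identical profiles and
    +inf (with a warning) when the propagated error vanishes while the
    distance does not.
    """
    grid = _shared_grid(a, b)
    am = np.interp(grid, a.offsets, a.means)
    bm = np.interp(grid, b.offsets, b.means)
    a_sem = np.interp(grid, a.offsets, np.nan_to_num(a.sems))
    b_sem = np.interp(grid, b.offsets, np.nan_to_num(b.sems))
    diff = am - bm
    dist = float(np.sqrt(np.sum(diff**2)))
    if dist == 0:
        return 0.0, 0.0
    prop_err = float(np.sqrt(np.sum(diff**2 * (a_sem**2 + b_sem**2))) / dist)
    if prop_err == 0:
        warnings.warn("zero propagated error with nonzero distance", stacklevel=2)
        return dist, np.inf
    return dist, dist / prop_err


def alignment_scores(
    series_by_treatment: Sequence[DielSeries],
    anchor: str,
    transcript: Optional[str] = None,
) -> AlignmentScore:
    """Raw DIST/NORM for one transcript: mean over all treatment pairs."""
    if len(series_by_treatment) < 2:
        raise ValidationError("need at least two treatments")
    profiles = [mean_profile(s, anchor=anchor) for s in series_by_treatment]
    dists, norms = [], []
    for a, b in itertools.combinations(profiles, 2):
        d, n = pairwise_dist(a, b)
        dists.append(d)
        norms.append(n)
    name = transcript or series_by_treatment[0].variable
    return AlignmentScore(
        transcript=name,
        anchor=anchor,
        dist_raw=float(np.mean(dists)),
        norm_raw=float(np.mean(norms)),
    )


def scale_scores(scores: Sequence[AlignmentScore]) -> pd.DataFrame:
    """Min–max scale DIST and NORM to [0,1] across the run, per score type.

    0 marks the best (smallest) and 1 the worst alignment observed in
    the set; a constant score column scales to 0.
    """
    df = pd.DataFrame(
        {
            "transcript": [s.transcript for s in scores],
            "anchor": [s.anchor for s in scores],
            "dist_raw": [s.dist_raw for s in scores],
            "norm_raw": [s.norm_raw for s in scores],
        }
    )
    for col in ("dist_raw", "norm_raw"):
        v = df[col].to_numpy(float)
        finite = v[np.isfinite(v)]
        lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
        scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
        df[col.replace("_raw", "_scaled")] = np.clip(scaled, 0.0, 1.0)
    for s, (_, row) in zip(scores, df.iterrows()):
        s.dist_scaled = float(row["dist_scaled"])
        s.norm_scaled = float(row["norm_scaled"])
    return df


@dataclass
class AlignmentAnova:
    p_photoperiod: float
    p_interaction: float
    aligned: bool  # neither photoperiod term significant
    table: pd.DataFrame = field(repr=False, default=None)


def _replicate_offsets(s: DielSeries, anchor: str) -> np.ndarray:
    zt = s.data["zt"].to_numpy(float)
    if anchor == "dawn":
        return np.round(zt, 9)
    p = s.regime.photoperiod_h
    night = s.regime.cycle_length_h - p
    return np.round(np.where(zt >= p, zt - p, zt + night), 9)


def alignment_anova(
    a: DielSeries, b: DielSeries, anchor: str, alpha: float = 0.05
) -> AlignmentAnova:
    """Two-way ANOVA (photoperiod × offset, type II) on replicate values.

    Restricted to offsets sampled in both series; "aligned" means
    neither the photoperiod main effect nor its interaction with time is
    significant at ``alpha``.
    """
    frames = []
    for label, s in (("a", a), ("b", b)):
        off = _replicate_offsets(s, anchor)
        frames.append(
            pd.DataFrame(
                {
                    "value": s.data["value"].to_numpy(float),
                    "offset": off,
                    "photoperiod": label,
                }
            )
        )
    shared = sorted(set(frames[0]["offset"]) & set(frames[1]["offset"]))
    if len(shared) < 2:
        raise ValidationError("fewer than 2 shared offsets")
    df = pd.concat(frames, ignore_index=True)
    df = df[df["offset"].isin(shared)]
    counts = df.groupby(["photoperiod", "offset"]).size()
    if counts.size < 2 * len(shared):
        warnings.warn("empty cells in the photoperiod × offset design", stacklevel=2)
    table = anova_twoway(df, "value", "photoperiod", "offset", typ=2)
    p_main = float(table.loc["C(photoperiod)", "PR(>F)"])
    p_int = float(table.loc["C(photoperiod):C(offset)", "PR(>F)"])
    return AlignmentAnova(
        p_photoperiod=p_main,
        p_interaction=p_int,
        aligned=(p_main > alpha) and (p_int > alpha),
        table=table,
    )


def alignment_table(
    series_by_transcript: Dict[str, Sequence[DielSeries]],
    alpha: float = 0.05,
    anova_pair: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Full alignment analysis: raw and scaled DIST/NORM per transcript and
    anchor, plus the dawn/dusk ANOVA discrimination flag.

    ``anova_pair`` picks the two treatments compared by ANOVA (default:
    first and last, e.g. the 6-h and 18-h photoperiods).
    """
    scores = []
    anova_rows = {}
    for name, series_list in series_by_transcript.items():
        i, j = anova_pair if anova_pair is not None else (0, len(series_list) - 1)
        for anchor in ("dawn", "dusk"):
            scores.append(alignment_scores(series_list, anchor, transcript=name))
            try:
                res = alignment_anova(series_list[i], series_list[j], anchor, alpha=alpha)
                anova_rows[(name, anchor)] = res.p_photoperiod
            except ValidationError as exc:
                warnings.warn(f"ANOVA skipped for {name}/{anchor}: {exc}", stacklevel=2)
                anova_rows[(name, anchor)] = np.nan
    df = scale_scores(scores)
    df["p_photoperiod"] = [
        anova_rows[(t, a)] for t, a in zip(df["transcript"], df["anchor"])
    ]
    disc = {}
    for name in series_by_transcript:
        pd_dawn = anova_rows[(name, "dawn")]
        pd_dusk = anova_rows[(name, "dusk")]
        disc[name] = (pd_dawn > alpha) != (pd_dusk > alpha)
    df["discriminates"] = [disc[t] for t in df["transcript"]]
    return df
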