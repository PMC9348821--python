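"""Shared statistical primitives: nonparametric bootstrap CIs, per-time-point
and two-way ANOVA, Tukey HSD compact letter displays, significance stars.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    lo: float
    hi: float
    n_boot: int
    seed: int
    method: str = "percentile"
    degenerate: bool = False  # some group had a single observation


def bootstrap_ci(
    groups,
    statistic: Callable[..., float],
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI, resampling with replacement within groups.

    ``groups`` is a single array or a sequence of arrays; ``statistic``
    receives the resampled array(s) positionally and returns a scalar.
    """
    if isinstance(groups, np.ndarray) or (
        len(groups) and np.isscalar(groups[0])
    ):
        groups = [np.asarray(groups, float)]
    else:
        groups = [np.asarray(g, float) for g in groups]
    rng = np.random.default_rng(seed)
    estimate = float(statistic(*groups))
    degenerate = any(g.size == 1 for g in groups)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        resampled = [g[rng.integers(0, g.size, g.size)] for g in groups]
        draws[i] = statistic(*resampled)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return BootstrapCI(
        estimate=estimate,
        lo=float(lo),
        hi=float(hi),
        n_boot=n_boot,
        seed=seed,
        degenerate=degenerate,
    )


def anova_timepoint(*groups) -> Tuple[float, float]:
    """One-way ANOVA F and p across replicate groups at one time point.

    Groups that are all exactly equal (zero within- and between-group
    variance) short-circuit to (0, 1) instead of a 0/0 F ratio.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def anova_twoway(
    df: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    typ: int = 2,
) -> pd.DataFrame:
    """Two-way ANOVA table (type II by default) with interaction."""
    model = smf.ols(
        f"{response} ~ C({factor_a}) * C({factor_b})", data=df
    ).fit()
    return sm.stats.anova_lm(model, typ=typ)


def tukey_letters(
    values: Sequence[float], labels: Sequence, alpha: float = 0.05
) -> Mapping:
    """Tukey HSD post-hoc comparison summarized as a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``
    (Tukey–Kramer adjustment for unbalanced groups).  Letters are
    assigned from maximal cliques of the not-significantly-different
    graph, ordered by descending group mean.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pooled_sd = np.concatenate(
        [values[labels == n] - values[labels == n].mean() for n in names]
    ).std(ddof=len(names))
    if pooled_sd == 0:
        # all groups internally constant: distinct iff means differ
        nsd = {
            (a, b): values[labels == a].mean() == values[labels == b].mean()
            for a, b in itertools.combinations(names, 2)
        }
    else:
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        nsd = {}
        for (a, b), reject in zip(
            itertools.combinations(sorted(names, key=str), 2), res.reject
        ):
            nsd[(a, b)] = not bool(reject)
    def similar(a, b):
        if a == b:
            return True
        return nsd.get((a, b), nsd.get((b, a), False))

    # maximal cliques of the NSD graph (group counts are small)
    cliques = []
    for size in range(len(names), 0, -1):
        for combo in itertools.combinations(names, size):
            if all(similar(a, b) for a, b in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    order = {n: -values[labels == n].mean() for n in names}
    cliques.sort(key=lambda c: min(order[n] for n in c))
    letters = {n: "" for n in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for n in clique:
            letters[n] += letter
    return letters


def p_stars(p: float) -> str:
    """Significance stars: 0 '***' 0.001 '**' 0.01 '*' 0.05."""
    if not np.isfinite(p):
        return "NA"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""
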