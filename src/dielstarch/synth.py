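"""Synthetic diel time-series generator.

Emulates the experimental design the analyses assume: piecewise-linear
starch accumulation from dawn to dusk, night-time mobilization paced to a
target exhaustion time with optional curvature, and transcript
oscillations shaped as raised-cosine bumps with specified peak ZT,
amplitude and damping.  Replicates carry additive Gaussian noise; all
randomness flows through explicit integer seeds.

The starch mean trajectory is

    S(t) = a·t                                    0 ≤ t ≤ P
    S(t) = S_dusk · (1 − (t−P)/(E−P))^γ           P < t < E
    S(t) = 0                                      t ≥ E

with S_dusk = a·P, accumulation rate ``a``, photoperiod ``P``, exhaustion
time ``E`` (hours after dawn) and curvature γ (γ=1 exactly linear decay;
γ>1 fast-early mobilization, γ<1 slow-early).  Replicate noise is
N(0, (noise_frac·S_dusk)²), clipped at zero — starch cannot be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    DielSeries,
    LightRegime,
    UNIT_METABOLITE,
    UNIT_TRANSCRIPT,
    ValidationError,
)


@dataclass(frozen=True)
class StarchModel:
    """Parameters of the piecewise starch trajectory.

    accum_rate: a, µmol gFW⁻¹ h⁻¹; exhaustion_zt: E, hours after dawn;
    curvature: γ > 0; noise_frac: replicate SD as a fraction of dusk
    starch; n_reps: biological replicates per time point.
    """

    accum_rate: float
    exhaustion_zt: float
    curvature: float = 1.0
    noise_frac: float = 0.05
    n_reps: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.accum_rate <= 0:
            raise ValidationError("accum_rate must be positive")
        if self.curvature <= 0:
            raise ValidationError("curvature must be positive")
        if self.noise_frac < 0:
            raise ValidationError("noise_frac must be non-negative")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


@dataclass(frozen=True)
class TranscriptModel:
    """Raised-cosine transcript oscillation on the log2 scale.

    The noiseless mean is ``baseline + damping·amplitude·g(d)`` where
    d is the circular ZT distance to ``peak_zt`` and
    g(d) = (1 + cos(π·d/peak_width))/2 for d < peak_width, else 0 —
    a sharp bump of full width 2·peak_width with g(0)=1.
    """

    baseline: float
    amplitude: float
    peak_zt: float
    peak_width: float
    damping: float = 1.0
    noise_sd: float = 0.0
    n_reps: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.peak_width <= 0:
            raise ValidationError("peak_width must be positive")
        if not (0 < self.damping <= 1):
            raise ValidationError("damping must be in (0, 1]")


def _sample_grid(regime: LightRegime, sample_every_h: float) -> np.ndarray:
    n = int(round(regime.cycle_length_h / sample_every_h))
    grid = np.arange(n + 1) * sample_every_h
    if grid[-1] < regime.cycle_length_h - 1e-9:
        grid = np.append(grid, regime.cycle_length_h)
    return grid


def starch_mean(m: StarchModel, regime: LightRegime, t) -> np.ndarray:
    """Noiseless starch trajectory at times ``t`` (hours after dawn)."""
    t = np.asarray(t, float)
    p = regime.dusk_zt
    e = m.exhaustion_zt
    if e <= p:
        raise ValidationError("exhaustion_zt must lie after dusk")
    s_dusk = m.accum_rate * p
    day = m.accum_rate * t
    frac = np.clip(1.0 - (t - p) / (e - p), 0.0, None)
    night = s_dusk * frac**m.curvature
    return np.where(t <= p, day, night)


def simulate_starch(
    m: StarchModel, regime: LightRegime, sample_every_h: float = 2.0
) -> DielSeries:
    """Simulate replicate starch measurements over one full cycle.

    The grid must contain the dusk time point exactly: downstream fits
    anchor on the dusk sample.
    """
    grid = _sample_grid(regime, sample_every_h)
    p = regime.dusk_zt
    if not np.any(np.abs(grid - p) < 1e-9):
        raise ValidationError(
            f"sampling grid (every {sample_every_h} h) misses dusk at ZT{p}"
        )
    mean = starch_mean(m, regime, grid)
    s_dusk = m.accum_rate * p
    rng = np.random.default_rng(m.seed)
    rows = []
    for zt, mu in zip(grid, mean):
        draws = mu + rng.normal(0.0, m.noise_frac * s_dusk, size=m.n_reps)
        draws = np.clip(draws, 0.0, None)
        for r, v in enumerate(draws, start=1):
            rows.append((zt, f"r{r}", v))
    return DielSeries(
        genotype="synthetic",
        regime=regime,
        variable="starch",
        unit=UNIT_METABOLITE,
        data=pd.DataFrame(rows, columns=["zt", "replicate", "value"]),
    )


def _circular_distance(t, peak, cycle):
    d = np.abs(np.asarray(t, float) - peak) % cycle
    return np.minimum(d, cycle - d)


def transcript_mean(m: TranscriptModel, regime: LightRegime, t) -> np.ndarray:
    d = _circular_distance(t, m.peak_zt, regime.cycle_length_h)
    g = np.where(d < m.peak_width, 0.5 * (1.0 + np.cos(np.pi * d / m.peak_width)), 0.0)
    return m.baseline + m.damping * m.amplitude * g


def simulate_transcript(
    m: TranscriptModel,
    regime: LightRegime,
    sample_every_h: float = 2.0,
    gene: str = "GENE",
) -> DielSeries:
    """Simulate replicate transcript abundances (log2 scale) over one cycle."""
    grid = _sample_grid(regime, sample_every_h)
    mean = transcript_mean(m, regime, grid)
    rng = np.random.default_rng(m.seed)
    rows = []
    for zt, mu in zip(grid, mean):
        draws = mu + rng.normal(0.0, m.noise_sd, size=m.n_reps)
        for r, v in enumerate(draws, start=1):
            rows.append((zt, f"r{r}", v))
    return DielSeries(
        genotype="synthetic",
        regime=regime,
        variable=f"transcript:{gene}",
        unit=UNIT_TRANSCRIPT,
        data=pd.DataFrame(rows, columns=["zt", "replicate", "value"]),
    )


def apply_perturbation(base: StarchModel, regime: LightRegime) -> StarchModel:
    """Translate the regime's harvest-day perturbation into model terms.

    low_light_day scales the accumulation rate by the irradiance ratio
    (photosynthesis roughly proportional to light input); early_dusk
    truncates the light phase, so dusk starch becomes a·at_zt — whether
    the night rate compensates (moving E) is the caller's choice and the
    exhaustion target is left untouched here.
    """
    pert = regime.perturbation
    if pert is None:
        return base
    if pert.kind == "low_light_day":
        ratio = pert.new_irradiance / regime.irradiance_umol
        return replace(base, accum_rate=base.accum_rate * ratio)
    if pert.kind == "early_dusk":
        # truncation is carried by regime.dusk_zt; the model is unchanged
        return base
    if pert.kind == "extended_night":
        return base
    raise ValidationError(f"unknown perturbation {pert.kind!r}")
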