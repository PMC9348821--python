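"""Domain types and tidy-table I/O for diel (light/dark-cycle) time series.

Conventions
-----------
Time is Zeitgeber time (ZT): decimal hours elapsed since the most recent
dawn (lights-on).  Dawn is ZT0, dusk is ZT ``photoperiod_h``.  A dawn
sample of the following cycle may be recorded at ZT ``cycle_length_h``.
Metabolite contents are in µmol Glc-equivalents g⁻¹ FW; transcript
abundances in log2(copies × 2.5e7 g⁻¹ FW).

Tables are long/tidy TSV with the columns in :data:`TABLE_COLUMNS` and
``NA`` as the missing-value marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column schema of the tidy exchange tables.
TABLE_COLUMNS = [
    "experiment_id",
    "genotype",
    "cycle_length_h",
    "photoperiod_h",
    "irradiance",
    "perturbation",
    "zt",
    "variable",
    "unit",
    "replicate",
    "value",
]

METABOLITE_VARIABLES = {"starch", "glucose", "fructose", "sucrose"}

UNIT_METABOLITE = "umol_gFW"
UNIT_TRANSCRIPT = "log2_copies_per_2.5e7_gFW"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


@dataclass(frozen=True)
class Perturbation:
    """A within-day perturbation of the light regime on the harvest day.

    kind: one of ``early_dusk`` (lights off early, at ``at_zt`` hours),
    ``low_light_day`` (irradiance dropped to ``new_irradiance`` from dawn),
    or ``extended_night`` (lights stay off past the expected dawn).
    """

    kind: str
    at_zt: Optional[float] = None
    new_irradiance: Optional[float] = None

    _KINDS = ("early_dusk", "low_light_day", "extended_night")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "early_dusk" and self.at_zt is None:
            raise ValidationError("early_dusk requires at_zt")
        if self.kind == "low_light_day" and self.new_irradiance is None:
            raise ValidationError("low_light_day requires new_irradiance")

    def encode(self) -> str:
        if self.kind == "early_dusk":
            return f"early_dusk@{self.at_zt:g}"
        if self.kind == "low_light_day":
            return f"low_light@{self.new_irradiance:g}"
        return "extended_night"

    @staticmethod
    def decode(text: str) -> Optional["Perturbation"]:
        if text in ("", "none", "NA") or pd.isna(text):
            return None
        if text.startswith("early_dusk@"):
            return Perturbation("early_dusk", at_zt=float(text.split("@", 1)[1]))
        if text.startswith("low_light@"):
            return Perturbation(
                "low_light_day", new_irradiance=float(text.split("@", 1)[1])
            )
        if text == "extended_night":
            return Perturbation("extended_night")
        raise ValidationError(f"cannot parse perturbation {text!r}")


@dataclass(frozen=True)
class LightRegime:
    """External light/dark cycle: total length, photoperiod, irradiance.

    ``cycle_length_h`` is the T-cycle duration (17, 24, 28 ...);
    ``photoperiod_h`` the light phase; dusk falls at ZT ``photoperiod_h``.
    """

    cycle_length_h: float
    photoperiod_h: float
    irradiance_umol: float = 160.0
    perturbation: Optional[Perturbation] = None

    def __post_init__(self):
        if not (0 < self.photoperiod_h < self.cycle_length_h):
            raise ValidationError(
                "photoperiod must be within (0, cycle_length): "
                f"got {self.photoperiod_h} of {self.cycle_length_h}"
            )
        if (
            self.perturbation is not None
            and self.perturbation.kind == "early_dusk"
            and self.perturbation.at_zt >= self.photoperiod_h
        ):
            raise ValidationError("early dusk must precede the scheduled dusk")

    @property
    def dusk_zt(self) -> float:
        """ZT of lights-off, accounting for an early-dusk perturbation."""
        if self.perturbation is not None and self.perturbation.kind == "early_dusk":
            return float(self.perturbation.at_zt)
        return float(self.photoperiod_h)

    @property
    def night_length_h(self) -> float:
        return float(self.cycle_length_h) - self.dusk_zt


@dataclass
class DielSeries:
    """Replicate measurements of one variable for one genotype × regime.

    ``data`` is a DataFrame with columns ``zt``, ``replicate``, ``value``;
    one row per biological replicate per sampled ZT.
    """

    genotype: str
    regime: LightRegime
    variable: str
    unit: str
    data: pd.DataFrame
    experiment_id: str = "exp"

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing = {"zt", "replicate", "value"} - set(df.columns)
        if missing:
            raise SchemaError(f"series data missing columns {sorted(missing)}")
        df = df.reset_index(drop=True)
        zt = df["zt"].to_numpy(float)
        if np.any(zt < -1e-9) or np.any(zt > self.regime.cycle_length_h + 1e-9):
            raise ValidationError(
                f"zt values must lie in [0, {self.regime.cycle_length_h}]"
            )
        if self.variable in METABOLITE_VARIABLES:
            bad = np.flatnonzero(df["value"].to_numpy(float) < 0)
            if bad.size:
                raise ValidationError(
                    f"negative metabolite value at row {bad[0]} "
                    f"({self.variable}, zt={zt[bad[0]]})"
                )
        self.data = df

    @property
    def zts(self) -> np.ndarray:
        """Sorted unique sampled ZTs."""
        return np.unique(self.data["zt"].to_numpy(float))

    def values_at(self, zt: float, atol: float = 1e-9) -> np.ndarray:
        t = self.data["zt"].to_numpy(float)
        return self.data.loc[np.abs(t - zt) <= atol, "value"].to_numpy(float)

    def subset(self, zt_start: float, zt_end: float) -> "DielSeries":
        """Closed-window subset: boundary samples are included."""
        t = self.data["zt"].to_numpy(float)
        keep = (t >= zt_start - 1e-9) & (t <= zt_end + 1e-9)
        return replace(self, data=self.data.loc[keep].reset_index(drop=True))

    def key(self) -> tuple:
        r = self.regime
        pert = r.perturbation.encode() if r.perturbation else "none"
        return (
            self.experiment_id,
            self.genotype,
            r.cycle_length_h,
            r.photoperiod_h,
            r.irradiance_umol,
            pert,
            self.variable,
        )


@dataclass
class AlignedProfile:
    """Mean ± SEM profile re-indexed to hours after dawn or dusk."""

    anchor: str  # "dawn" | "dusk"
    offsets: np.ndarray
    means: np.ndarray
    sems: np.ndarray

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, float)
        self.means = np.asarray(self.means, float)
        self.sems = np.asarray(self.sems, float)
        if not (len(self.offsets) == len(self.means) == len(self.sems)):
            raise ValidationError("offsets, means, sems must have equal length")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValidationError("offsets must be strictly increasing")


def _regime_from_row(row: pd.Series) -> LightRegime:
    return LightRegime(
        cycle_length_h=float(row["cycle_length_h"]),
        photoperiod_h=float(row["photoperiod_h"]),
        irradiance_umol=float(row["irradiance"]),
        perturbation=Perturbation.decode(str(row["perturbation"])),
    )


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"input table is missing required column(s): {missing}")
    return df


def read_series(path) -> list[DielSeries]:
    """Read a tidy TSV into one :class:`DielSeries` per
    (experiment, genotype, regime, variable) group.

    Rows whose ``value`` is NA are dropped; the count is logged.
    """
    df = read_table(path)
    n_na = int(df["value"].isna().sum())
    if n_na:
        logger.warning("dropping %d NA value row(s) from %s", n_na, path)
        df = df.dropna(subset=["value"])
    group_cols = [
        "experiment_id",
        "genotype",
        "cycle_length_h",
        "photoperiod_h",
        "irradiance",
        "perturbation",
        "variable",
    ]
    df = df.fillna({"perturbation": "none"})
    out: list[DielSeries] = []
    for key, grp in df.groupby(group_cols, sort=False):
        row = grp.iloc[0]
        series = DielSeries(
            genotype=str(row["genotype"]),
            regime=_regime_from_row(row),
            variable=str(row["variable"]),
            unit=str(row["unit"]),
            data=grp[["zt", "replicate", "value"]],
            experiment_id=str(row["experiment_id"]),
        )
        out.append(series)
    return out


def series_to_table(series: Iterable[DielSeries]) -> pd.DataFrame:
    frames = []
    for s in series:
        r = s.regime
        d = s.data.copy()
        d.insert(0, "experiment_id", s.experiment_id)
        d.insert(1, "genotype", s.genotype)
        d.insert(2, "cycle_length_h", r.cycle_length_h)
        d.insert(3, "photoperiod_h", r.photoperiod_h)
        d.insert(4, "irradiance", r.irradiance_umol)
        d.insert(5, "perturbation", r.perturbation.encode() if r.perturbation else "none")
        d["variable"] = s.variable
        d["unit"] = s.unit
        frames.append(d[TABLE_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_series(series: Iterable[DielSeries], path) -> None:
    """Write series as a tidy TSV (header line, ``NA`` missing marker)."""
    series_to_table(series).to_csv(path, sep="\t", index=False, na_rep="NA")


def mean_profile(s: DielSeries, anchor: str = "dawn") -> AlignedProfile:
    """Per-time-point mean ± SEM, re-anchored to dawn or dusk.

    Dusk anchoring is a pure relabelling: ZT ≥ photoperiod maps to
    ``zt - photoperiod`` (hours into the night) and pre-dusk points are
    rotated to ``zt + night_length`` so they follow in the same cycle.
    A time point with a single replicate gets SEM = NaN, never 0.
    """
    if anchor not in ("dawn", "dusk"):
        raise ValueError("anchor must be 'dawn' or 'dusk'")
    zt = s.data["zt"].to_numpy(float)
    if anchor == "dawn":
        offset = zt
    else:
        p = s.regime.photoperiod_h
        night = s.regime.cycle_length_h - p
        # ZT0 (dawn) and ZT=cycle_length (next dawn) pool at the same offset
        offset = np.where(zt >= p, zt - p, zt + night)
    df = s.data.assign(_offset=np.round(offset, 9))
    g = df.groupby("_offset")["value"]
    offsets = np.array(sorted(g.groups))
    means = g.mean().loc[offsets].to_numpy(float)
    sems = g.sem(ddof=1).loc[offsets].to_numpy(float)
    counts = g.count().loc[offsets].to_numpy()
    sems = np.where(counts >= 2, sems, np.nan)
    return AlignedProfile(anchor=anchor, offsets=offsets, means=means, sems=sems)
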