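"""End-to-end orchestration: simulate a scenario, run every analysis stage,
write tidy TSV tables plus a machine-readable JSON summary.

A scenario is a YAML/dict description of genotypes × light regimes:

    seed: 1
    sample_every_h: 2
    regimes:
      - {cycle_length_h: 24, photoperiod_h: 12, irradiance: 160}
      - {cycle_length_h: 24, photoperiod_h: 6, irradiance: 160}
    genotypes:
      - name: wt
        starch: {accum_rate: 1.0, exhaustion_zt: 24.0, curvature: 1.0,
                 noise_frac: 0.05, n_reps: 4}
        transcripts:
          - {gene: DAWN1, baseline: 10, amplitude: 3, peak_zt: 2,
             peak_width: 6, damping: 1.0, noise_sd: 0.3, anchor: dawn}

A transcript with ``anchor: dusk`` peaks at ``photoperiod + peak_zt`` in
every regime (dusk-tracking); the default dawn anchor keeps ``peak_zt``
fixed in ZT across regimes.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DielSeries, LightRegime, Perturbation, write_series
from .exhaustion import NoExhaustionError, stex, stex_app
from .linearity import nonlinearity
from .rates import accumulation_rate, mobilization_rate
from .rhythm import amplitude, peak_time
from .alignment import alignment_table
from .synth import StarchModel, TranscriptModel, apply_perturbation, simulate_starch, simulate_transcript

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scenario: dict
    outdir: Path
    seed: int = 0
    cap_darkness_h: float = 8.5
    n_boot: int = 1000
    alpha: float = 0.05
    stages: tuple = ("rates", "stex", "linearity", "peaks", "align")


def _regime_from_cfg(cfg: dict) -> LightRegime:
    pert = cfg.get("perturbation")
    return LightRegime(
        cycle_length_h=float(cfg["cycle_length_h"]),
        photoperiod_h=float(cfg["photoperiod_h"]),
        irradiance_umol=float(cfg.get("irradiance", 160.0)),
        perturbation=Perturbation.decode(pert) if pert else None,
    )


def _regime_label(r: LightRegime) -> str:
    label = f"T{r.cycle_length_h:g}_P{r.photoperiod_h:g}_I{r.irradiance_umol:g}"
    if r.perturbation:
        label += "_" + r.perturbation.encode()
    return label


def simulate_scenario(scenario: dict, seed: int) -> list[DielSeries]:
    """Generate every (genotype × regime × variable) series of a scenario.

    Per-series seeds are drawn from a SeedSequence spawned off ``seed``,
    so runs are reproducible and series mutually independent.
    """
    if not scenario.get("genotypes") or not scenario.get("regimes"):
        raise ValueError("scenario must define non-empty genotypes and regimes")
    ss = np.random.SeedSequence(seed)
    out = []
    counter = 0
    for gcfg in scenario["genotypes"]:
        for rcfg in scenario["regimes"]:
            regime = _regime_from_cfg(rcfg)
            step = float(rcfg.get("sample_every_h", scenario.get("sample_every_h", 2.0)))
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            counter += 1
            if "starch" in gcfg:
                scfg = dict(gcfg["starch"])
                model = StarchModel(seed=child_seed, **scfg)
                model = apply_perturbation(model, regime)
                s = simulate_starch(model, regime, sample_every_h=step)
                s.genotype = gcfg["name"]
                out.append(s)
            if not rcfg.get("simulate_transcripts", True):
                continue
            for tcfg in gcfg.get("transcripts", []):
                tcfg = dict(tcfg)
                gene = tcfg.pop("gene")
                anchor = tcfg.pop("anchor", "dawn")
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                if anchor == "dusk":
                    tcfg["peak_zt"] = (
                        regime.photoperiod_h + tcfg["peak_zt"]
                    ) % regime.cycle_length_h
                model = TranscriptModel(seed=child_seed, **tcfg)
                t = simulate_transcript(model, regime, sample_every_h=step, gene=gene)
                t.genotype = gcfg["name"]
                out.append(t)
    return out


def _starch_series(series: list[DielSeries]) -> list[DielSeries]:
    return [s for s in series if s.variable == "starch"]


def _transcript_series(series: list[DielSeries]) -> list[DielSeries]:
    return [s for s in series if s.variable.startswith("transcript:")]


def rates_table(series: list[DielSeries], cap_darkness_h=None) -> pd.DataFrame:
    rows = []
    for s in _starch_series(series):
        for phase, fn in (("accumulation", accumulation_rate), ("mobilization", mobilization_rate)):
            for normalize in (False, True):
                kwargs = {"normalize": normalize}
                if phase == "mobilization" and cap_darkness_h is not None:
                    kwargs["cap_darkness_h"] = cap_darkness_h
                fit = fn(s, **kwargs)
                rows.append(
                    {
                        "genotype": s.genotype,
                        "regime": _regime_label(s.regime),
                        "phase": phase,
                        "normalized": normalize,
                        "slope": fit.slope,
                        "se": fit.se_slope,
                        "ci_lo": fit.ci95[0],
                        "ci_hi": fit.ci95[1],
                        "n_obs": fit.n_obs,
                    }
                )
    return pd.DataFrame(rows)


def stex_table(series: list[DielSeries], cap_darkness_h: float = 8.5) -> pd.DataFrame:
    rows = []
    for s in _starch_series(series):
        row = {"genotype": s.genotype, "regime": _regime_label(s.regime)}
        try:
            est = stex(s)
            row.update(stex_h=est.hours_after_dawn, stex_se=est.se)
        except NoExhaustionError:
            row.update(stex_h=np.nan, stex_se=np.nan)
        try:
            app = stex_app(s, max_darkness_h=cap_darkness_h)
            row.update(
                stex_app_h=app.hours_after_dawn,
                stex_app_lo=app.ci95[0],
                stex_app_hi=app.ci95[1],
                n_fits=app.n_fits,
            )
        except (NoExhaustionError, ValueError):
            row.update(stex_app_h=np.nan, stex_app_lo=np.nan, stex_app_hi=np.nan, n_fits=0)
        rows.append(row)
    return pd.DataFrame(rows)


def linearity_table(series: list[DielSeries], n_boot: int, seed: int) -> pd.DataFrame:
    rows = []
    for s in _starch_series(series):
        res = nonlinearity(s, n_boot=n_boot, seed=seed)
        lo, hi = res.ci95 if res.ci95 else (np.nan, np.nan)
        rows.append(
            {
                "genotype": s.genotype,
                "regime": _regime_label(s.regime),
                "score": res.score,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_interior": res.n_interior_points,
                "n_boot": n_boot,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def peaks_table(series: list[DielSeries], seed: int) -> pd.DataFrame:
    rows = []
    for s in _transcript_series(series):
        feat = peak_time(s, seed=seed)
        amp = amplitude(s)
        rows.append(
            {
                "gene": s.variable.split(":", 1)[1],
                "genotype": s.genotype,
                "regime": _regime_label(s.regime),
                "peak_zt": feat.peak_zt if feat.scorable else np.nan,
                "peak_lo": feat.peak_ci95[0] if feat.scorable else np.nan,
                "peak_hi": feat.peak_ci95[1] if feat.scorable else np.nan,
                "scorable": feat.scorable,
                "amplitude": amp.amplitude,
                "amp_lo": amp.amplitude_ci95[0],
                "amp_hi": amp.amplitude_ci95[1],
            }
        )
    return pd.DataFrame(rows)


def align_table(series: list[DielSeries], alpha: float) -> Optional[pd.DataFrame]:
    by_key: dict = {}
    for s in _transcript_series(series):
        gene = s.variable.split(":", 1)[1]
        by_key.setdefault((s.genotype, gene), []).append(s)
    multi = {
        f"{g}:{gene}": lst for (g, gene), lst in by_key.items() if len(lst) >= 2
    }
    if not multi:
        return None
    return alignment_table(multi, alpha=alpha)


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate the scenario and run every enabled stage.

    Writes data.tsv, per-stage TSVs, summary.json and MANIFEST to
    ``cfg.outdir``; returns the summary dict.  Deterministic given cfg.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "schema_version": 1,
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stages": {},
    }
    manifest = ["data.tsv"]
    failed = None
    series = simulate_scenario(cfg.scenario, cfg.seed)
    write_series(series, outdir / "data.tsv")
    stage_fns = {
        "rates": lambda: rates_table(series, cap_darkness_h=None),
        "stex": lambda: stex_table(series, cap_darkness_h=cfg.cap_darkness_h),
        "linearity": lambda: linearity_table(series, cfg.n_boot, cfg.seed),
        "peaks": lambda: peaks_table(series, cfg.seed),
        "align": lambda: align_table(series, cfg.alpha),
    }
    for stage in cfg.stages:
        try:
            table = stage_fns[stage]()
        except Exception as exc:  # keep partial outputs, note failure point
            failed = (stage, repr(exc))
            logger.error("stage %s failed: %r", stage, exc)
            break
        if table is None or len(table) == 0:
            summary["stages"][stage] = {"rows": 0}
            continue
        path = outdir / f"{stage}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="NA")
        manifest.append(path.name)
        summary["stages"][stage] = {
            "rows": int(len(table)),
            "file": path.name,
        }
    summary["failed_stage"] = failed
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.append("summary.json")
    lines = list(manifest)
    if failed:
        lines.append(f"FAILED at stage: {failed[0]} ({failed[1]})")
    (outdir / "MANIFEST").write_text("\n".join(lines) + "\n")
    if failed:
        raise RuntimeError(f"pipeline failed at stage {failed[0]}: {failed[1]}")
    return summary


def load_scenario(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
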