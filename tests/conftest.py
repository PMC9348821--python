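import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dielstarch import DielSeries, LightRegime, StarchModel, simulate_starch

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def t24_12h() -> LightRegime:
    """Standard 12-h light / 12-h dark 24-h cycle at 160 µmol m⁻² s⁻¹."""
    return LightRegime(cycle_length_h=24, photoperiod_h=12, irradiance_umol=160)


@pytest.fixture
def noiseless_starch(t24_12h) -> DielSeries:
    """Exactly piecewise-linear starch: a=1, E=24, γ=1, two replicates."""
    m = StarchModel(
        accum_rate=1.0, exhaustion_zt=24.0, curvature=1.0,
        noise_frac=0.0, n_reps=2, seed=0,
    )
    return simulate_starch(m, t24_12h, sample_every_h=2.0)


def series_from_points(points, regime=None, variable="starch", genotype="g"):
    """Build a DielSeries from (zt, replicate, value) tuples."""
    regime = regime or LightRegime(24, 12)
    unit = "umol_gFW" if variable == "starch" else "log2_copies_per_2.5e7_gFW"
    return DielSeries(
        genotype=genotype,
        regime=regime,
        variable=variable,
        unit=unit,
        data=pd.DataFrame(points, columns=["zt", "replicate", "value"]),
    )


def linear_night_series(dusk_starch=12.0, slope=-1.0, regime=None, n_reps=2,
                        zt_start=None, zt_end=None, step=2.0):
    """Deterministic night decay with exact replicate duplicates."""
    regime = regime or LightRegime(24, 12)
    zt_start = regime.photoperiod_h if zt_start is None else zt_start
    zt_end = regime.cycle_length_h if zt_end is None else zt_end
    pts = []
    for zt in np.arange(zt_start, zt_end + 1e-9, step):
        v = max(dusk_starch + slope * (zt - regime.photoperiod_h), 0.0)
        for r in range(n_reps):
            pts.append((float(zt), f"r{r}", v))
    return series_from_points(pts, regime=regime)
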