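# dielstarch

Analysis of diel starch turnover and circadian transcript rhythms in
plant light/dark-cycle experiments.

In many plants, starch accumulated during the day is mobilized at night
at a nearly constant rate paced so that reserves run out close to the
next dawn — consistent with a division rule *R = S/T* (mobilization
rate = starch at dusk / time to the anticipated dawn). Quantifying that
pacing from replicated time series of starch content and clock
transcript abundance requires a small set of specialized estimators,
which this package provides as a tested, reusable library with a
command-line pipeline:

* **Turnover rates** — starch accumulation (dawn→dusk) and mobilization
  (dusk→dawn) as OLS slopes on replicate data, absolute or normalized
  to mean dusk starch, with t-based 95% CIs and ANCOVA (type III)
  slope comparison between genotypes; windows cappable at the first
  8.5 h of darkness for fair T-cycle comparisons.
* **Starch exhaustion time** — StEx (root of the night linear fit,
  delta-method SE) and StEx^app (geometric mean of nested dusk-anchored
  extrapolations of the initial rate, log-scale t CI).
* **Nonlinearity score** — mean normalized residue of night starch from
  the dusk→dawn chord (negative = fast-early mobilization), with a
  nonparametric bootstrap CI and Tukey-letter group comparison.
* **Rhythm features** — transcript peak ZT by bootstrapped AICc-selected
  polynomial and spline fits (circular mean, percentile CI, honest
  "unscorable" outcome for weak oscillations) and amplitude
  (max − min of means, Gaussian error propagation).
* **Dawn/dusk alignment** — DIST (Euclidean distance between treatment
  profiles on a shared offset grid) and NORM (DIST / propagated error),
  min–max scaled, plus a two-way ANOVA desynchronization test.
* **Synthetic data** — a generator reproducing the experimental designs
  (piecewise-linear starch with curvature knob γ, raised-cosine
  transcript bumps, 6/12/18-h photoperiods, T17/T24/T28 cycles,
  early-dusk and low-light perturbations, replicate Gaussian noise), so
  every stage is testable without external data.

The estimators follow scikit-learn conventions (`RateRegression`,
`ExhaustionExtrapolator`, `NonlinearityScorer`, `PeakEstimator`, … with
`fit` and trailing-underscore attributes); module-level functions
(`fit_rate`, `stex`, `nonlinearity`, `peak_time`, …) wrap them for
`DielSeries` inputs. See `docs/methods.md` for the statistical details.

## Worked example

Simulate the bundled scenario (wild type vs. a fast-early clock mutant
across five light regimes) and run every analysis stage:

```sh
dielstarch run examples/scenario.yaml -o out --seed 1 --n-boot 300
```

`out/stex.tsv` begins:

```
genotype   regime         stex_h  stex_se  stex_app_h  n_fits
wildtype   T24_P12_I160   24.11   0.25     25.41       3
wildtype   T24_P6_I160    24.06   0.21     25.45       3
```

The wild type, simulated to exhaust starch at the anticipated dawn
(E = 24 h), is estimated to run out 24.1 ± 0.25 h after dawn from the
single night fit, independent of photoperiod; StEx^app extrapolates the
initial rate from three nested dusk-anchored windows. In
`out/linearity.tsv` the wild type scores 0.02 (CI −0.06…0.12, spanning
zero: linear mobilization) while the mutant, simulated with curvature
γ = 1.3, scores negative (fast-early). `out/peaks.tsv` recovers the
dawn-tracking transcript near ZT2 in both photoperiods and the
dusk-tracking one at ZT13.2 (12-h days) versus ZT7.0 (6-h days), with
the mutant's amplitudes damped roughly 2.5-fold; and in `out/align.tsv`
the dawn-tracking transcript's scaled DIST is far smaller dawn-anchored
(0.02) than dusk-anchored (1.00), the dusk-tracking one the reverse.

The same stages are available piecewise (`simulate`, `rates`, `stex`,
`linearity`, `peaks`, `align`, `stats`) on any tidy TSV with columns
`experiment_id genotype cycle_length_h photoperiod_h irradiance
perturbation zt variable unit replicate value` (tab-separated, `NA`
for missing).

As a library:

```python
from dielstarch import LightRegime, StarchModel, simulate_starch, stex

series = simulate_starch(
    StarchModel(accum_rate=1.0, exhaustion_zt=24.0, noise_frac=0.05, seed=1),
    LightRegime(cycle_length_h=24, photoperiod_h=12),
)
print(stex(series).hours_after_dawn)   # 24.09 — hours after dawn
```

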