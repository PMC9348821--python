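# Methods

This note documents the statistical procedures the package implements,
the assumptions behind them, the synthetic-data generator used to
validate them, and the numerical choices made where the design was
genuinely open.

## Time conventions

All times are Zeitgeber time (ZT): decimal hours since the most recent
dawn (lights-on). Dawn is ZT0 and dusk is ZT *P*, where *P* is the
photoperiod in hours; the external cycle has total length *T* (the
"T-cycle": T17 = 8.5 h light/8.5 h dark, T24, T28). A dawn sample of the
following cycle may be recorded at ZT *T*; when profiles are re-anchored
it pools with the ZT0 sample, which is the same circular instant. A
sudden early dusk moves lights-off to an earlier ZT; the effective dusk
(`LightRegime.dusk_zt`) then precedes the scheduled one.

## Rates of starch accumulation and mobilization

Rates are slopes of ordinary least-squares fits of starch content
against ZT, fitted to **all biological replicates** (never to time-point
means), over the closed window dawn→dusk (accumulation) or dusk→dawn
(mobilization); the dusk sample belongs to both windows. 95% CIs use
the Student-t quantile with n − 2 degrees of freedom on the slope SE.
Relative rates divide every observation by the arithmetic mean of the
dusk replicate values of that series before fitting (units: fraction of
dusk starch per hour). In T-cycle comparisons the mobilization window is
capped at the first 8.5 h of darkness — the full T17 night — so nights
of different lengths are compared over the same duration after dusk.

Between-group rate differences are tested by ANCOVA: value ~ group +
ZT + group:ZT on the pooled replicates with sum-to-zero group contrasts,
reporting the interaction term's type-III F and p (statsmodels). An
intercept-difference term is always included.

For the sudden-early-dusk comparison three windows are fitted: the
control's whole night; the control restricted to time points whose mean
content is at or below the treated plants' content at darkening (so both
fits span the same starch range); and the treated night restricted to
the contiguous run of time points, from darkening onward, whose mean
content remains above the control's dawn mean — the decline is no longer
linear beyond that, and the run is deliberately not re-extended by
late-night noise excursions above the threshold. Cutoffs are resolved
against time-point means and whole time points are kept or dropped.

`required_rate_ratio` encodes the division-rule arithmetic R = S/T
(starch at dusk divided by time to the anticipated dawn): if dusk starch
falls to a fraction *f* of normal and the night lengthens from
*n₀* to *n₁* hours, exhausting starch on time requires the mobilization
rate to change by the factor *f·n₀/n₁* (e.g. 2/3 of the starch over a
16-h rather than 12-h night → 0.5, a 50% decrease).

## Starch exhaustion time (StEx and StEx^app)

**StEx** is the ZT at which the night linear fit reaches zero starch,
found as the root of f(ZT) = b + m·ZT with bracketed Brent search on
[ZT0, dusk + 3T] — a derivative-free method; the bracket is generous
because only the x-intercept of a line is sought. Its SE is first-order
(delta-method) propagation of −b/m through the OLS slope/intercept
covariance:

    var(−b/m) = var(b)/m² + b²·var(m)/m⁴ − 2·b·cov(b,m)/m³.

A non-negative night slope raises a no-exhaustion error; a root earlier
than dusk is flagged degenerate rather than raised.

**StEx^app** captures the *initial* mobilization rate: nested fits over
k = 3 … K consecutive time points, always anchored at dusk (never
sliding), restricted to dusk plus the first 8.5 h of darkness; each fit
is extrapolated to zero and the estimate is the geometric mean of the
roots. With 2-h sampling and the 8.5-h cap the windows hold 3, 4 and 5
points (n = 3 fits); with coarser sampling whatever windows satisfy
k ≥ 3 are used and `n_fits` records how many. The 95% CI is a Student-t
interval on the mean of log roots, exponentiated — the log scale is the
natural one for a geometric mean; the raw-scale alternative was
considered and rejected for consistency with the aggregation. Windows
with non-negative slope are excluded with a warning. The AM–GM
inequality (geometric ≤ arithmetic mean of the roots) is asserted on
every call as an internal sanity check.

## Nonlinearity score

A chord is interpolated between the dusk and dawn mean starch contents.
At each night time point the residue is (observed mean − chord
prediction)/chord prediction, and the score is the mean residue across
all night time points — endpoints included; their residues are
identically zero in the point estimate, so the score equals the interior
mean scaled by (n−2)/n. `include_endpoints=False` averages interior
residues only. Zero means linear mobilization, negative fast-early,
positive slow-early. The 95% CI is a nonparametric bootstrap
(default 1000 draws, percentile interval): replicates are resampled
within each time point, endpoints included, so the chord is re-anchored
on every draw. Time points whose chord prediction is non-positive are
excluded with a warning.

Group comparison uses one-way ANOVA with Tukey HSD compact-letter
display. The observation unit is the per-replicate-profile score (each
replicate's own trajectory scored against its own chord): bootstrap
draws are not independent observations and would inflate n, splitting
identical conditions into different letter groups.

## Transcript peak time and amplitude

Peak time is estimated from bootstrapped time series: replicates are
resampled within each time point; polynomials of degree 2–6 and cubic
least-squares splines over a degrees-of-freedom grid 4 … min(10,
#ZTs − 1) are fitted; each family's model is selected by minimum AICc
(AIC + 2k(k+1)/(n−k−1), n = replicate observations in the draw, ties
toward fewer parameters); and the fitted curve's global maximum is
located on a 0.05-h grid (a stationary maximum, or the window boundary).
Fifty draws per curve family is the default. The reported peak is the
circular mean of the per-draw peaks; the 95% CI is the percentile
interval of the circular residuals about that mean. Series are unwrapped
into a window opening in the late night (ZT18 for a 24-h cycle, 0.75·T
generally) so peaks near dawn are interior to the window. A draw whose
selected curve is monotone across the window carries no peak; if more
than half of all draws are monotone the series is reported unscorable —
the honest outcome for weak or heavily damped oscillations.

Amplitude is max − min of the time-point mean levels over one full
cycle (17/24/28 h as appropriate), with Gaussian error propagation:
SE = √(SEM_max² + SEM_min²), CI = ± t·SE with the two time points'
pooled degrees of freedom.

## Dawn/dusk alignment (DIST and NORM)

Mean ± SEM profiles from different photoperiod treatments are
re-anchored to dawn (offsets = ZT) or dusk (offsets = ZT − P for night
points; pre-dusk points rotate to ZT + (T − P)) and linearly
interpolated onto the intersection of their offset ranges at the finest
common sampling step (treatments with different photoperiods have
different native dusk-aligned offsets; the gridding makes them
comparable). For each treatment pair:

* DIST = √Σ_j (a_j − b_j)², the Euclidean distance on the shared grid;
* NORM = DIST / err, where err = √Σ_j (a_j − b_j)²(sem_aj² + sem_bj²) / DIST
  is the first-order Gaussian propagation of the distance through the
  per-offset SEMs (verified against a numeric-Jacobian oracle in the
  test suite).

With more than two treatments the arithmetic mean over pairs is
reported. Within an analysis run each score type is min–max scaled to
[0, 1] (0 = best, 1 = worst alignment observed); the scaling is
order-preserving by construction. The alternative NORM reading — a
quadrature sum of SEMs without distance weighting — changes only the
relative magnitudes, not the dawn/dusk ordering, on the generator's
designs.

Whether two photoperiod series are significantly desynchronized under a
given anchoring is tested by a replicate-level two-way ANOVA
(photoperiod × offset as categorical factors on the offsets sampled in
both series, type II sums of squares). A series pair counts as aligned
when neither the photoperiod main effect nor its interaction with time
is significant at α = 0.05: a pure phase shift moves the interaction,
not the main effect.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not plant physiology:

* **Starch**: S(t) = a·t up to dusk; S_dusk·(1 − (t−P)/(E−P))^γ at
  night; 0 beyond E. Defaults a = 1 µmol gFW⁻¹ h⁻¹, E = 24 h, γ = 1,
  2-h sampling, 4 replicates, additive Gaussian noise with SD = 5% of
  dusk starch, clipped at zero. γ is the single nonlinearity knob:
  γ > 1 gives fast-early decay (negative score), γ < 1 slow-early
  (positive score). Noise is additive and scaled to dusk starch so
  late-night scatter does not vanish; the measurements themselves never
  state a noise model, so the 5% level is a calibration choice.
* **Transcripts**: baseline + damping·A·g(d), with g a raised-cosine
  bump of half-width w in the circular ZT distance d to the peak
  (g(0) = 1, g(d ≥ w) = 0) — clock transcripts have sharp peaks, and
  the bump gives controllable width where a sinusoid would not; noise
  is additive Gaussian on the log2 scale.
* **Perturbations**: a low-light day scales the accumulation rate by
  the irradiance ratio; an early dusk truncates the light phase (dusk
  starch a·at_zt) and leaves the night policy to the caller;
  fixed seeds give bit-identical series.

What the generator does **not** emulate: growth/dilution of contents,
day-to-day carry-over, correlated errors between metabolites measured
on the same extract, non-Gaussian assay error, or any mechanistic
clock–starch coupling. Passing recovery tests therefore demonstrates
that the estimators recover the parameters of data with this structure
at realistic noise, not that real measurements satisfy the structure.

One measurable artifact of the zero-clipping deserves note: at time
points whose true content is near zero (dawn, when E = T) clipping
inflates the observed mean by ≈ 0.4·σ. This raises the dawn chord
anchor and biases the γ = 1 nonlinearity score slightly negative
(≈ −0.02 at the default noise level) and the fitted night slope
slightly shallow, delaying mean StEx by ≈ +0.15 h. Both biases shrink
with the noise fraction and vanish without clipping.

## Problem sizes

Stochastic validation uses 100 generator seeds for starch parameter
recovery, 15–25 seeds per condition for peak/amplitude recovery, and
300 simulations for type-I-error calibrations — sizes at which the
Monte-Carlo error of the checked summaries is comfortably below the
tolerances asserted, while the whole suite stays quick on one CPU.

## Known limitations

* The nested StEx^app windows assume the initial decline is linear over
  at least three time points; strongly curved nights make the estimate
  window-dependent by design (that is what the score quantifies).
* No changepoint detection for the late-night slowdown; windowing is
  the only handling.
* Plant age is carried as metadata only and never enters a computation.
* ANOVAs are plain fixed-effects OLS; no mixed models, and per-time-point
  tests are not corrected for multiple testing.
* The publisher-format spreadsheet layouts of real experiments are not
  parsed; data must be provided in the package's tidy TSV schema.
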