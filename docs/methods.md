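# Methods

This note documents the models, numerical choices and limitations of the
`circafeed` pipeline in enough detail to reproduce or audit any stage.

## Data model and conventions

The central object is the per-animal hourly intake series: a
`(n_days, 24)` matrix in grams with an explicit boolean missingness
mask. Hour bin `h` covers `[h, h+1)` hours post-midnight; day boundaries
fall at 00:00; day numbers count from arrival at the farm. All modules
share these conventions. Intake is held in grams throughout; unit
conversion happens only at I/O.

## Synthetic cohorts (`synth`)

The generator emulates one fattening round on a commercial farm: by
default 10 pens of 11 pigs monitored for 83 days, with daily intake
rising roughly 2.5-fold as the animals grow (linear multiplicative ramp
1.0 → 2.5; configurable or replaceable by any day → factor function).

Each animal carries a diurnal profile: 24 hourly eating probabilities
`p_eat`, 24 conditional mean intakes `mu_intake` (g), a pattern kind and
a consistency scalar in [0, 1]. Hourly intake is drawn by the hurdle
mechanism the downstream model assumes: eat ~ Bernoulli(p), and given
eating, intake ~ Gamma with mean `trend(day) · offsets · mu` and shape 4
(configurable; shape 4 gives a coefficient of variation of 0.5, a
realistic within-hour spread). Day-to-day inconsistency has three
seeded components, all scaled by `1 − consistency`: a day-level
propensity shift on the logit scale (sd 1.2), a day-level mean-preserving
intake factor on the log scale (sd 0.35), and a circular phase shift of
the whole profile in whole hours (sd 5 h). The phase component is what
destroys the 24 h rhythm for inconsistent animals; the logit/log
components perturb level without touching timing. Pen and pig
multiplicative offsets (log-sd 0.05 / 0.10) create the grouping
structure the variance-component stage estimates. Whole days go missing
with probability `missing_day_prob`.

Canonical profiles: *alternans* (small 09:00 peak, larger 16:30 peak —
7.5 h apart so the model class below can resolve both), *single peak*
(afternoon), *night feeder* (22:00–04:00), and *flat* (uniform p and mu;
with low consistency this animal's hours are i.i.d., i.e. white-noise
feeding). The peak separation matters: with peaks only 6 h apart the
6-df cyclic spline cannot represent the valley between them, and no fit
of this model class recovers the two-peak truth.

Visit records are generated by splitting each non-zero hour into 1–3
visits with dyadic weights (1; ½+½; ¼+¼+½), which keeps the float sum of
visit intakes exactly equal to the hourly value, so visit → hourly
aggregation round-trips bit-exactly. Error injection corrupts visits
with mutually exclusive classes (negative intake, implausible feeding
rate ~400 g/min, 2 h visit) drawn from one uniform variate per visit, so
the corrupted fraction is exactly binomial with the summed rates.

The feature-panel simulator (`simulate_feature_panel`) draws
`y = period mean + pen + pig + AR(1) residual` directly at programmed
variance components, for validating the mixed-model stage in isolation.

## Cleaning and aggregation (`ingest`)

The per-visit rules are parameterised because the thresholds used in
practice differ between feeder dialects: negative intake beyond `tol`
(default 0 g); feeding rate above `rate_max` (default 150 g/min, well
above sustained intake rates reported for finishing pigs); duration
above `dur_max` (default 3600 s) or zero-duration visits with positive
intake; overlapping same-animal visits (the later visit is removed).
Each removed visit is attributed to the first rule that caught it, so
rule tallies partition the removals. A final sweep removes **all**
visits of any pig-day whose removed fraction exceeds `day_frac_max`
(default 0.25) — partial removals would bias hourly sums. Unparseable
rows are quarantined and counted, never silently dropped.

Aggregation sums visit intakes into hour bins; a visit spanning an hour
boundary is split proportionally to the time spent in each bin (the
unbiased assignment; any fixed-endpoint rule biases mass toward one
bin). Hours on removed pig-days are missing; hours without visits on
retained days are zero — the zeros are data.

Welfare filters mask days ±3 (inclusive) around a high-disease-score
day, days strictly before the first health observation, and days
strictly after the first slaughter departure. The filter is idempotent.

## Stationarising (`detrend`)

Wavelet significance testing needs approximately constant mean and
variance. Three steps, per animal:

1. **LOESS de-trending** — locally linear regression with tricube
   weights, span 0.75 (fraction of points), fitted on the true hourly
   time index with missing points as gaps, no robustness iterations;
   residuals = observed − fit. A constant or slowly rising trend leaves
   residuals with mean ≈ 0 at every age.
2. **Amplitude correction** — consecutive 7-day blocks aligned to the
   animal's first day; each block divided by its own de-trended range
   (max − min over non-missing points). Blocks with range below 1e-9
   pass through unscaled and are flagged. After correction every valid
   block has range exactly 1, and the step is invariant to global
   rescaling of the input.
3. **Zero fill** — missing points set to 0, recorded in a fill mask so
   downstream calls can refuse to interpret filled windows. Zeros are
   preferred over imputation to avoid inventing structure.

## Wavelet analysis (`wavelet`)

Analytic Morlet wavelet, central frequency ω₀ = 6 (the standard
admissibility-respecting choice; Fourier period ≈ 1.033 × scale).
Periods are log₂-spaced with 20 voices per octave over 8–48 h, which
guarantees at least one grid row inside the 23.5–24.5 h call band. The
transform is computed in the frequency domain with zero padding to a
power of two at least `n + 8·max_scale`, which pushes circular
wraparound below ~1e-9 of wavelet amplitude; a brute-force O(n²)
time-domain convolution of the same wavelet is kept as an independent
validation path and agrees to < 1e-6 relative error outside the cone of
influence. Power is |W|² normalised by the series variance, hence
invariant to input scaling. The cone of influence marks points within
one e-folding time (√2 · scale) of either edge; power there is
edge-contaminated.

Significance: `n_sim` (default 1000) Gaussian white-noise series of the
same length, each normalised by its own sample variance and transformed
identically; pointwise p = (1 + #{surrogate power ≥ observed}) /
(n_sim + 1) — a valid finite-sample p-value that cannot be zero. Under
white-noise input observed and surrogates are exchangeable, so the
p-values are exactly calibrated; the calibration check feeds white
noise directly into this stage (LOESS pre-filtering would distort the
null spectrum and make the check test the wrong thing).

A day is **evaluable** if none of its 24 points was zero-filled;
evaluable days are called circadian when the median p over (band rows ×
24 points) is below α = 0.05. Days whose band points touch the cone of
influence are flagged `coi_contaminated` but still called. Rhythm
summaries report the proportion of circadian days per animal per month
(consecutive 28-day blocks from the first recorded day — "month" has no
canonical boundary for a fattening phase, so a fixed 4-week block is
used) and per 14-day period, the latter suppressed below 7 evaluable
days.

## Hurdle GAM (`hurdle_gam`)

Hourly intake mixes a point mass at zero with a positive amount, i.e. a
zero-adjusted gamma. Because the binary and positive likelihood factors
share no parameters, the model is fitted as two independent parts whose
log-likelihoods add:

- **Probability part** — eat indicator ~ binomial GLM, logit link.
- **Intake part** — positive intakes ~ gamma GLM, log link, with a
  separate gamma shape per period estimated by maximum likelihood given
  the fitted means (Brent root of the digamma score), iterated three
  times with variance weights; the total gamma log-likelihood is
  evaluated exactly.

Both parts share one design: intercept, a cubic B-spline in day (df 3,
from 4 knots), and a centred cyclic cubic spline in hour (df 6, from 8
knots on [0, 24)), fitted separately per retained 14-day period in the
full model, shared across periods in the `single_diurnal` reduction, and
absent in the `trend_only` reduction. The hour covariate is the bin
midpoint h + 0.5. Splines are **unpenalised** regression splines of
fixed dimension: likelihood-ratio comparisons between the nested
variants are then standard χ² tests with integer degrees of freedom,
which is what makes the LR size calibrate at its nominal level (a
penalised fit with data-driven smoothing has no clean reference
distribution). Periods with fewer than 7 available days are excluded
before fitting. An animal that eats in every hour (or none) gets a
constant-probability fallback with an add-half estimator instead of a
separating GLM fit.

Predicted intake is π·μ by construction, exactly. The de-trended
prediction used for features evaluates the surface with the day-spline
columns replaced by their mean over the period's observed days, removing
the trend contribution so curves are comparable across periods.

Calibration caveats: the LR size check must generate from an exactly
period-constant profile (consistency = 1). With day-to-day jitter the
generating process contains day-level random effects the model does not,
and the full model absorbs their period-specific realisations — the LR
then rejects well above nominal (~18% observed). Separately, the χ²
reference requires adequate cell counts: profiles with near-zero night
eating probabilities (~0.08, i.e. about one eating event per 14-day
period cell) make the test anticonservative (~10% at nominal 5%), which
is the familiar sparse-cell failure of likelihood asymptotics, not a
defect of the implementation. The calibration study therefore uses the
moderate-probability cosine profile (p_eat within [0.3, 0.75]), where
the empirical size is ~6-7% — a small residual finite-sample inflation
shared equally by the binomial and gamma parts.

## Features (`features`)

All features are read off the de-trended predicted-intake curve f and
the probability fit on a 0.1 h grid (sub-6-minute timing resolution,
stable for these smooth bases):

- **n_peaks** — local maxima of f on the circular grid, ignoring maxima
  whose topographic prominence is below 5% of the curve range
  (unpenalised spline bases ripple at the few-percent level, and those
  ripples are not feeding peaks; `prominence_frac=0` restores the pure
  derivative-sign-change rule, plateaus counting once).
- **peak_time_h / peak_height** — argmax and max of f.
- **peak_width** — mean drop in f half an hour before and after the
  peak (cyclic indexing); for a local parabola H − a(t−t*)² this equals
  a/4 exactly. Larger = narrower.
- **lowest_intake** — min of f.
- **night_prop** — trapezoidal integral of f over 21:00–24:00 plus
  0:00–5:00, divided by the whole-day integral (a bin-sum mode
  reproduces hour-binned conventions; both give 8/24 for a uniform
  curve).
- **min/max_prob_eat** — extremes of the fitted eating probability over
  the full period surface (hour × observed day), approximating
  day-to-day consistency. Taking extremes over the full surface rather
  than the hour curve alone is a deliberate choice; the hour-only
  alternative differs little for smooth trends.

Scale equivariance and rotation behaviour are property-tested: scaling f
scales the three intake features and leaves timing/counts/night share
unchanged; circularly shifting f shifts only the peak time (mod 24).

## Statistics (`stats`)

Transforms (square root for the low extremes, log for peak height and
width, 24 − √x for peak timing, identity otherwise) are applied per
feature before modelling; the constant 24 is the hour-scale maximum and
is configurable. Residual normality is gated by Shapiro–Wilk W ≥ 0.9 on
the mixed-model conditional residuals.

The mixed model per feature is `value = period (fixed) + pen + pig
(random intercepts) + ε`, with AR(1) correlation between an animal's
residuals at consecutive periods; a gap of Δ periods carries correlation
ρ^Δ. Pens are independent, so the REML objective factorises into pen
blocks (55×55 at full design), evaluated by Cholesky with a relative
ridge of 1e-8 for boundary stability, and minimised by L-BFGS-B over
(log σ²_pen, log σ²_pig, log σ²_e, artanh ρ). Recovery at the programmed
components (1.0 / 0.25 / 0.75, ρ = 0.3, 10 pens × 11 pigs × 5 periods)
is unbiased to within Monte-Carlo error.

The period effect is a Wald χ² on the period fixed-effect block (an LR
variant would need refitting by ML; Wald is the default and the two
agree asymptotically). If significant at 0.05, all pairwise period
contrasts are adjusted with the studentized-range distribution
(Tukey-style) and summarised as a compact letter display built from
maximal windows of mutually non-significant groups in mean order —
exact when non-significance is contiguous in that order, the usual case
for monotone age trends.

ICCs divide each random component by the total σ²_pen + σ²_pig + σ²_e,
the residual entering through the diagonal of the AR(1) covariance
(which is σ²_e regardless of ρ). Labels: weak < 0.4 ≤ moderate < 0.6 ≤
strong, applied to |value|.

Spearman matrices use pairwise-complete observations and average ranks
for ties; constant columns yield NaN and are flagged. No multiplicity
correction is applied across the per-feature period tests, matching
standard practice for this descriptive design.

## Validation design and what it shows

Ground truth is only available synthetically, so every end-to-end check
runs on simulated cohorts at fixed seeds: transform agreement with a
brute-force oracle; surrogate-p calibration on white noise (pooled
fraction below 0.05 ≈ 5%, day-call rate well under 10%); separation of
programmed-rhythm vs white-noise animals; hurdle curve recovery within
10% of profile amplitude; LR size ≈ 5% and power > 80%; ICC recovery
within ±0.1; exact cleaning of a labelled toy table; and a programmed
night-feeding / no-rhythm cohort reproducing a strong negative Spearman
correlation between night intake share and circadian-day proportion.
`scripts/acceptance.py` recomputes all of these from scratch at a given
seed. Problem sizes (20 noise animals × 1000 surrogates, 100 null
animals for LR size, 200 ICC replicates, 10+10 association animals at
300 surrogates each) were chosen to keep Monte-Carlo error comfortably
inside the stated bands on a single CPU. The null LR rejection rate is
a binomial proportion over 100 animals (sd ≈ 2 points), so individual
runs scatter around the nominal 5%.

What passing these tests does **not** show: real EFS data contain
correlated competition effects between penmates, diurnal temperature and
lighting covariates, drifting load-cell calibration and meal-structure
autocorrelation within hours, none of which the generator emulates. The
pipeline's statistical guarantees (calibration, recovery) are guarantees
about its own model classes, not about biological truth on any given
farm.

## Known limitations

- Surrogates are white noise only; an AR(1) (red-noise) null would be
  stricter for series with short-range autocorrelation.
- The wavelet call band inherits the period grid; with 20 voices per
  octave the 23.5–24.5 h band typically contains one to two rows.
- The mixed model assumes Gaussian features after transform; strongly
  discrete features (peak counts) are excluded from modelling.
- Fits are strictly per animal; no partial pooling across animals.
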