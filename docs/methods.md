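# Methods

This note documents the models and numerical choices behind the package,
what the synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal model

A triggered recording is modelled as

    a(t) = g(t) + s(t) + e(t)

where `g` is a slow flight-movement trend (typically one peak and trough as
the insect banks through the sensor), `s` is the wingbeat oscillation — a
fundamental f0 with decaying harmonics, amplitude-modulated by the flight
envelope — and `e` is stationary background noise. Amplitudes are in
arbitrary amplitude units (AAU): raw b-bit integers divided by 0.5·2^b, so
recordings at different bit depths are directly comparable and full-scale
maps to ±1.

## Trimming and the temporal-outlier fence

The flight is located as the span of samples with |a(t)| above a fixed
background threshold of 0.0061 AAU. Because background noise occasionally
crosses the threshold far from the flight, supra-threshold *indices* are
treated as a sample on the time axis: indices beyond 3×IQR from the
quartiles of that index set (linear-interpolation quantiles, the common
"type 7" rule) are discarded before taking the [min, max] span — the
whiskers of a boxplot on time. Trimmed flights shorter than 128 samples
(12.8 ms at 10 kHz, under two wingbeat periods) are excluded from feature
extraction; exclusion is a counted outcome, not an error. The threshold is
deliberately not adaptive: it is a property of the sensor's noise floor,
not of the flight.

## Background filtering

The only stated constraint on the filter is an STFT with a Hanning window,
so the filter is a pluggable strategy. The default estimates a *broadband*
noise floor — the median across frequency bins of each bin's median frame
magnitude — and subtracts it from all frame magnitudes (clipped at zero,
phases kept) before 50%-overlap-add resynthesis with a 128-sample window.
A per-bin median floor (classical spectral subtraction) is available as an
option but is not the default because a stationary wingbeat harmonic is
constant in its bin across frames: its own median would cancel it. The
broadband floor cannot remove a sustained tone, only level noise. Output
length equals input length, and since every frame magnitude is reduced the
filter never increases total power.

## Trend estimation

The trend is a penalized cubic B-spline smooth of amplitude on the sample
index (rescaled to [0, 1] for conditioning only), with basis dimension
k = max(10, floor(n/50)) for n trimmed samples, capped at n − 1 for
degenerate inputs. The penalty is the second difference of the spline
coefficients; the smoothing parameter λ is chosen by generalized
cross-validation (GCV) over a 60-point logarithmic grid, evaluated cheaply
through the Demmler–Reinsch reparameterization (one k×k
eigendecomposition for the whole path). The decomposition a = g + ã is
exact by construction.

**The λ-selection rule matters.** At k = n/50 and 10 kHz the basis can
partially represent oscillations up to ~100 Hz, and for a low-noise
signal the GCV profile over λ is bimodal: a minimum where only the trend
is fitted and a second, often deeper, basin where the spline starts to
track the wingbeat tone itself. A global GCV minimizer therefore absorbs
slow wingbeats into the "trend". The selector walks the grid from heavy
smoothing downward and stops at the first local minimum — the
trend-fitted optimum — with a secondary stop (once GCV has dropped ≥20%
below its heavy-smoothing asymptote and the per-step improvement falls
under 1%) for noiseless signals whose profile drifts monotonically. This
mirrors how gradient-based GAM optimizers initialized at heavy smoothing
behave, and the test suite checks the result against mgcv on a trend-like
fixture and verifies that ≥90% of an injected 90–150 Hz tone's power
survives detrending while the trend itself is recovered with r > 0.99.

## Features

The 52 features follow a fixed schema (`wingbeat.features.FEATURE_SCHEMA`):
25 on the trimmed, filtered signal, 26 on its detrended counterpart
(suffix `_g`, including the trend's own peak-to-trough range), plus the
fundamental frequency. Storage transformations — natural log for the
energy-type statistics, amplitude index, trend range and fundamental;
square root for the dominant frequency; none for entropies, band indices
and harmonic positions — are applied at storage time because both the
ANOVA and the classifier operate on the transformed scale; raw values are
recoverable via `invert_transform`. Undefined computations (log of a zero
range, entropy of a zero envelope, bands above Nyquist, no qualifying ACF
peak) yield missing values, never sentinels.

Details worth knowing:

- Envelope and spectral stages run on the signal zero-padded to 8192
  samples; longer inputs are used as-is (padding is simply skipped), and
  the mean spectrum then uses as many full 128-sample frames as fit.
- The mean magnitude spectrum uses non-overlapping Hanning frames;
  frequency resolution is sample_rate/128 (≈78 Hz at 10 kHz). Species-level
  Hz precision comes from the autocorrelation estimator, not the spectrum.
- Entropies are Shannon evenness on unit-sum normalizations with
  0·log 0 := 0; the acoustic entropy is the product H_t·H_f and all three
  lie in [0, 1].
- Harmonic peaks are strict local maxima ranked by height, ties broken
  toward lower frequency, with no lower frequency limit; the dominant
  frequency is the tallest peak strictly above 50 Hz (excluding slow body
  oscillations), so the two can differ.
- The fundamental is 1/T with T the lag of the first autocorrelation peak
  at least 10 samples from zero, peaks at least 10 samples apart. Peak
  search is restricted to positive ACF values: the modulus of a tone's ACF
  has a maximum at the *half* period (the negated trough), which would
  double every estimate. Peaks must reach a normalized height of 0.3 —
  below that the ACF of noise-like input at the retained lengths can
  produce spurious peaks — and the estimate must fall in 20–2000 Hz;
  otherwise the feature is missing.

## Balanced random forest

Each of 1000 trees is grown on a bootstrap containing a fixed, configured
number of draws (with replacement) from every class, so the rarest species
contributes as reliably as the commonest; 10 variables are tried per
split. Class probabilities are vote fractions across trees, and OOB
estimates use only trees for which the observation was out of bag. The
study-tuned per-class sizes (75/75/120/50/120/300 with imputation,
60/60/96/40/96/240 without, for the six species) ship as presets; for other
corpora `scaled_sample_sizes` rescales those ratios to the observed class
counts — the presets encode the *fraction* of each class a tree sees, which
is what transfers across corpus sizes. Missing values are imputed with
training-set medians (validation rows included — never their own medians).

Permutation importance permutes each feature within each tree's OOB rows
and records the per-class accuracy decrease, averaged over trees; the
overall mean decrease in accuracy is defined as the unweighted mean of the
per-class values. Gini importance averages each tree's unnormalized
impurity decreases. The leave-one-species-out protocol retrains without
one species (same hyper-parameters; no re-tuning) and reports how its
recordings distribute over the remaining classes together with the
maximal class probability — the operating characteristic for species the
sensor has never seen.

## Feature subsets

Sets 1–4 are derived from the schema (all 52; the 25 raw; the 27
detrended; the 20 harmonic peaks) so a schema change cannot desynchronize
them. Set 5 extends the harmonics with the frequency-spectrum indices
(band indices, spectral and acoustic entropies, dominant and fundamental
frequencies; 35 members). Sets 6–8 are data-driven: features are
standardized, distances are 1 − r (pairwise-complete Pearson correlation),
complete-linkage clustering is cut at k = 3, 5, 14, and each cluster is
represented by its member closest to the cluster centroid in standardized
observation space (ties alphabetical). Constant features are excluded with
a warning. Standardization precedes correlation, so the clustering is
scale-invariant by construction.

## Per-feature inference

Each transformed feature is fitted by OLS as
`feature ~ temperature + humidity + species`; a Type II ANOVA gives the F
for dropping each term while retaining the others, making the species test
order-invariant and covariate-adjusted. Rows with missing values are
dropped per feature, so degrees of freedom vary across features. P-values
are reported raw (a Holm option exists but is off by default, matching the
convention of reporting per-feature tests). Adjusted species means are
model predictions at sample-mean covariates, back-transformed (exp for
logged features — the geometric mean under no covariate effect; square for
square-rooted ones); medians are computed from back-transformed
observations.

## The synthetic generator

`simulate_recording` draws, per flight: a duration (normal, clipped below
at 0.02 s and above at 90% of the 0.6 s buffer; mean 0.17 s), an onset
uniform in the buffer, a fundamental (species mean + 1 Hz/°C × (T − 20),
species SD), per-flight loudness/timbre/manoeuvre jitter (lognormal
amplitude and trend factors, jittered harmonic decay), uniform random
harmonic phases, a raised-cosine envelope (15% ramps capped at 10 ms), a
one-cycle sinusoidal banking trend, Gaussian noise at 0.0015 AAU RMS
(≈ a quarter of the trim threshold), and 16-bit quantization. Temperature
and humidity are uniform over lab ranges (15–25 °C, 40–80 %RH). The study
templates use the six species' reported wingbeat means (104–139 Hz, SD 8),
the published 3323:848:274:186:161:113 class-imbalance ratios scaled to
desk size, and a 2% rate of clipped partial transits; the `separable`
preset (fundamentals 10 Hz apart, SD 3, no nuisance jitter) is the
controlled corpus used for classifier acceptance.

What the generator does **not** emulate: stroke kinematics, stridulation
or wing-body contact, frequency drift within a flight, sensor transfer
functions, non-stationary background noise, or any correlation structure
between features beyond what the signal model induces. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes
— frequencies, trends, flight bounds, class structure — not that real
corpora will classify at the same accuracy.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: corpora
of a few hundred 0.6 s recordings at 10 kHz, forests of 100–1000 trees —
sizes at which every quantity is stable under the fixed seeds used.
Tolerances follow the sources of error they bound: wingbeat recovery is
checked against the integer-lag quantization bound (< 2 Hz median at
10 kHz), entropies against closed forms at 1e−9, the trim rule against a
brute-force oracle exactly, and stochastic quantities (chance-level OOB
error, type-I rates) against binomial noise at the simulated n.

## Known limitations

- Flights of only a couple of wingbeat periods can yield octave errors:
  finite-window cross terms between harmonics create a spurious positive
  ACF peak at the half period. The first-peak rule keeps them; they appear
  as outliers in the fundamental-frequency feature (and inflate means more
  than medians).
- The 78 Hz spectral resolution makes harmonic-peak features coarse at
  10 kHz; they are bin centres, not interpolated peaks.
- The broadband background filter levels stationary noise only; tonal
  interference (mains hum) would survive and should be notched upstream.
- `scaled_sample_sizes` assumes the study's class-imbalance structure when
  rescaling the presets; for corpora with very different imbalance the
  per-class sizes should be re-tuned to balance class-specific error
  rates, which this package treats as given rather than re-deriving.
- Recordings at sample rates far above ~13.6 kHz exceed the 8192-sample
  padding target after trimming; the pipeline then analyses the unpadded
  signal, which changes the frame count entering the mean spectrum.
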