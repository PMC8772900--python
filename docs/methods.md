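# Methods

`fhrva` implements a complete analysis route for fetal heart rate
variability (FHRV): preprocessing of CTG-style FHR traces, extraction of
19 linear and nonlinear features, blockwise dimension reduction to 8
interpretable components, and regression of the per-record acceleration
count with a feed-forward neural network against a multiple linear
regression baseline.  Because clinical CTG corpora are rarely
distributable, the package ships a synthetic-data generator with full
ground truth; this note records the model choices, defaults and known
limitations.

## Signal model and synthetic data

A record is an evenly sampled FHR trace in beats per minute,

    FHR(t) = baseline + drift(t) + v(t) + a(t)  (+ artifacts)

* **Sampling rate** 4 Hz, the typical effective rate of commercial CTG
  monitors after interpolation of the Doppler autocorrelation output.
* **Baseline** per record ~ N(140, 10) bpm clipped to [112, 168];
  duration defaults to 30 min (the route requires at least 20 min).
* **Drift** (the true *floatingline*) is the sum of two slow sinusoids
  with random phase: amplitude 4 bpm at the configured drift period
  (default 600 s) plus half that amplitude at 2.7x the period.
* **Variability** v(t) is the sum of three independent band-limited
  Gaussian processes synthesized in the Fourier domain, with exact
  band confinement and calibrated variances (bpm^2) in the standard
  fetal bands: VLF 0-0.003 Hz (default power 1.0), LF 0.003-0.2 Hz
  (6.0), HF 0.2-1 Hz (1.5).  The defaults give a residual SD of ~3 bpm
  and a sympatho-vagal balance LF/HF of ~4, typical of healthy
  antepartum traces.
* **Accelerations** a(t) are raised-cosine-edged plateaus: 5-s cosine
  ramps around a plateau of the configured duration (default 20 s) at a
  peak drawn uniformly in [1.5, 1.9] x the configured amplitude
  (default 15 bpm).  The plateau construction ensures each event
  satisfies the clinical 15 bpm / 15 s criterion with enough margin
  that the automated counter recovers the injected count exactly even
  with ~3 bpm of variability riding on the event.  Events are placed
  uniformly with >= 10 s separation.
* **Counts.** The per-record number of accelerations follows a negative
  binomial truncated to [0, 30] whose (mu, k) are solved at run time so
  the truncated mean and SD are 8.5 and 5.4 — the corpus-level
  statistics the route is calibrated to (range 0-30, median 8, mode 9).
  Gestational week (uniform 28-42) weakly modulates the expected rate
  (+3% per week around week 35), so week carries a little predictive
  signal, as it does clinically.  The week trend is a modeling choice;
  no per-week reference statistics exist to calibrate it against.
* **Artifacts**: spike outliers (uniform in 25-45 or 225-250 bpm,
  default 0.5% of samples) and signal-loss gaps encoded as NaN (default
  three 2-s gaps).

**Corpus heterogeneity.** `generate_corpus` draws three lognormal
per-record factors: an overall variability scale (sigma 0.65,
multiplying all band powers), an LF/HF balance factor (sigma 0.8,
scaling LF up and HF down), and a slow-band factor (sigma 0.6, scaling
VLF power and drift amplitude).  These spreads are what make the
extracted features reproduce the blockwise correlation structure the
reduction step expects: the scale factor ties the time-domain block and
the Poincare descriptors together, the balance factor drives the
sympatho-vagal ratio, the percentage features and the roughness-type
nonlinear indices (SampEn, HFD, symbolic variability), and the slow
factor decouples VLF/total power from the rest.  With these defaults a
187-record corpus retains (1, 3, 2) components per block in every one
of the seeded replicates we ran.

**Feature-level generators.** Two additional generators sample at the
feature level rather than the signal level. `synthetic_feature_table`
draws 17-feature vectors from per-block Gaussian factor models whose
loading pattern follows the reference structure (one time factor;
VLF/total-power, LF/HF and SVB frequency factors; variability and
complexity nonlinear factors).  A factor carried by a single feature
has a population eigenvalue of ~1, sitting exactly on the Kaiser
retention threshold, so the tertiary frequency factor (SVB, with an HF
counterweight) is given slightly more mass than a literal reading of
the reference correlations would imply; this lifts its population
eigenvalue to ~1.3 and makes retention deterministic in practice at
n = 187.  Additive identities (total power as a band sum, percentages
summing to 100) are *not* enforced in this fixture — it reproduces
correlation structure only.  `synthetic_reduced_dataset` draws the
8-column reduced representation directly and builds a count response
with a linear part dominated by the time and VLF/total-power
components, a product interaction between the two nonlinear components
whose strength grows with gestational week (30% of full strength at
week 28, 100% at week 41), and a quadratic term in the time component.
The interaction produces the qualitative behaviour the models section
tests: a nonlinear regressor outperforms the linear baseline, and
response-surface curvature in the nonlinear plane grows with week.

What the generator deliberately does **not** emulate: decelerations,
uterine activity, fetal behavioural states, autocorrelated artifact
bursts, and any pathological trace morphology.  Tests passing on this
synthetic corpus therefore demonstrate correctness of the pipeline's
computations and calibration of its study conditions — not clinical
performance on real CTG data.

## Preprocessing

* **Outliers**: samples outside 50-220 bpm, or jumps > 25 bpm between
  consecutive valid in-range samples (the later sample is flagged).
  These are standard CTG plausibility limits.
* **Gap repair**: runs of flagged-or-missing samples up to 3 s are
  linearly interpolated between flanking valid samples; longer runs and
  edge-touching runs stay missing and are excluded from the analysis
  span (the longest contiguous valid segment is analyzed).
* **Inclusion gate**: signal loss <= 30% of the record, outliers < 5%,
  duration >= 20 min, and no visual-artifact flag (an operator-supplied
  boolean; no automatic detector is claimed).
* **Floatingline**: the smooth curve following slow heart-rate
  alterations.  Its contract: passband gain >= 0.9 at periods >= 60 s,
  gain <= 0.1 at periods <= 10 s, and transient excursions (such as
  accelerations) excluded so they stay in the residual.  The
  implementation detects acceleration candidates as samples > 10 bpm
  above a 60-s running median, bridges them by interpolation (the
  detection is iterated twice so dense acceleration sequences that bias
  the first median are still caught, and the mask is dilated by 5 s),
  then smooths with a 10-s running median followed by a zero-phase
  4th-order Butterworth low-pass at 0.025 Hz.  A 60-s median in the
  *smoothing* path would annihilate 60-s-period components and break
  the passband contract, which is why the long median serves detection
  only.  The FHRV signal is the elementwise difference FHR minus
  floatingline.
* **Floatingline error budget.** Any estimator honouring the passband
  contract absorbs the VLF part of the variability noise (all of its
  power lies below 1/60 Hz), so the deviation from the generator's true
  floatingline is bounded below by the VLF noise RMS (~1 bpm at the
  default VLF power) regardless of estimator quality.  The tracking
  test therefore uses a drift-dominated configuration (drift amplitude
  8 bpm, vlf 0 / lf 1.5 / hf 1.0 bpm^2), where the estimate stays
  within 10% of the drift amplitude.
* **Acceleration counter**: maximal intervals with residual >= 15 bpm,
  merged when separated by < 5 s, counted when >= 15 s long.  This is a
  reproducible stand-in for visual acceleration assessment; on
  artifact-free synthetic records it recovers the injected count
  exactly.

## Features (19)

Two global: gestational week; mean FHR over the clean analysis span.

Time domain (on the FHRV / clean FHR): STV, the mean of per-window
sample SDs over consecutive non-overlapping 30-s windows (trailing
partial window discarded); SDev, the sample SD of the whole FHRV; PPA,
max minus min of the clean FHR.  All SDs use the n-1 denominator.

Frequency domain: the PSD of the FHRV is an averaged short-time
periodogram (Welch): 300-s Hann segments, 50% overlap, per-segment mean
removal, one-sided density.  The 300-s segment is the best compromise
available on 20-min records for the VLF band edge at 0.003 Hz; VLF
estimates on such records remain poorly resolved (one resolution cell)
and should be interpreted accordingly.  Band powers integrate the
density by the trapezoid rule with the band edges added by linear
interpolation (so a band narrower than the grid spacing is not lost);
bands are VLF 0-0.003, LF 0.003-0.2, HF 0.2-1 Hz.  Total power is the
exact sum of the three band powers; %VLF/%LF/%HF are relative to it;
SVB = LF/HF (undefined, with a warning, when HF is zero).

Nonlinear (on the FHRV unless noted):

* **SampEn**: m = 2, tolerance r = 0.2 x SD of the series, Chebyshev
  distance, self-matches excluded, n - m templates at both lengths;
  pair counting uses a k-d tree and is verified against an O(n^2)
  oracle.  Undefined (with a warning) when no template pair matches.
* **SD1/SD2**: lag-1 Poincare dispersion, SD1^2 = var(diff)/2,
  SD2^2 = 2 var - SD1^2 (sample variances); the sum-of-squares identity
  SD1^2 + SD2^2 = 2 var holds by construction, and a negative SD2
  radicand (numerically possible) is clipped to zero with a warning.
* **HFD**: Higuchi's curve-length slope with k_max = 8 (a common
  default for records of a few thousand samples), clipped to [1, 2]
  with a warning outside.  A constant series has dimension 1 by
  convention.
* **VIRR / VIFHR**: symbolic dynamic analysis.  The series is
  quantized into 6 uniform levels spanning mean +/- 3 SD (values
  outside clipped to edge bins; a zero-variance series maps to the
  middle bin), overlapping words of 3 symbols are formed, and the
  variability index is the Shannon entropy of the word distribution
  normalized by ln(min(6^3, number of words)), so VI is 0 for a single
  repeated word and 1 at maximal diversity, and is invariant under any
  relabeling of the alphabet.  VIFHR is computed on the FHRV; VIRR on
  the increments of RR = 60000/FHR ms — true beat times are not
  recoverable from CTG-style data, so RR is derived from the evenly
  sampled rate.  The published symbolic-dynamics VI this stands in for
  is defined in work we could not reproduce exactly; results that hinge
  on its fine detail should be read qualitatively.

## Blockwise PCA

PCA runs separately in the three feature families — time {STV, SDev,
PPA}, frequency {VLF, LF, HF, TotalPower, SVB, %VLF, %LF, %HF},
nonlinear {SampEn, SD1, SD2, HFD, VIRR, VIFHR} — on the **correlation**
matrix, since the features carry heterogeneous units.  Components with
eigenvalue > 1 are retained (Kaiser rule, which is also where the
eigenvalue spectrum's elbow sits for these blocks; the dominant
component is always kept, covering the single-feature edge case whose
eigenvalue is exactly 1).  With two or more retained components the
loadings are varimax-rotated (Kaiser row normalization, tolerance 1e-6,
at most 100 sweeps) and the scores rotated accordingly; components are
re-ordered by explained variance after rotation and signed so the
largest-loading feature loads positively.

The reduced representation keeps week and mean FHR unchanged and
expects retained counts (1, 3, 2); anything else raises an error naming
the offending block, because the component naming below would be
undefined.  Components are named by their Pearson correlations with
defining feature sets — frequency: {VLF, TotalPower} -> LIN_VLF_power,
{LF, HF} -> LIN_LF_HF, {SVB} -> LIN_SVB; nonlinear: {SD1, SD2, VIRR,
VIFHR} -> NL_variability, {SampEn, HFD} -> NL_complexity — using an
optimal one-to-one assignment on mean absolute correlation, which is
sign-invariant and resolves ties in favour of the larger total.
Component columns are standardized to mean 0, SD 1 over the corpus.

## Models

Records are split 70:15:15 into training/validation/test by a seeded
permutation with largest-remainder rounding (n = 187 gives 131/28/28).

**ANN.** One hidden layer of tanh units (1-10, selected on the grid by
validation R^2), identity output.  Training is adam backpropagation
(full passes, learning rate 0.01, L2 penalty 1e-4) with early stopping
on the validation RMSE (patience 50, best checkpoint kept), at most
1000 epochs and 5 random restarts per hidden size by default.  Inputs
are z-scored with training-set statistics stored in the model; the
count targets are left raw.  The transfer functions and optimizer are
our choices — only the architecture (single hidden layer, 1-10 units)
is fixed by the route.  Prediction, feature importance and response
surfaces are computed from the extracted weights, so they are exactly
reproducible from a serialized model.  Per-input relevance is the
connection-weight contribution C_i = |sum_j a_ij b_j| (input->hidden
weights a, hidden->output weights b), reported raw and normalized to
sum 1.  Tests and the model-comparison check use reduced grids
(hidden sizes {6, 10}, 2-3 restarts, 600 epochs) — the selection
behaviour is identical, only the search is smaller.

**Metrics.** RMSE = sqrt(mean (y - yhat)^2); R^2 = 1 - SSE/SST with SST
about the observed mean (undefined for a zero-variance target); R is
the Pearson correlation of observed and predicted.  All three are
reported per subset and overall.

**MLRM.** Ordinary least squares of the count on the 8 reduced
predictors, with raw and standardized coefficients (the latter from
z-scored predictors and response; the intercept is reported raw),
two-sided p-values (significance threshold 0.05), 95% confidence
intervals, and the assumption diagnostics: Durbin-Watson on the
residual sequence, Tolerance = 1/VIF per predictor, normal P-P
coordinates of the standardized residuals, and standardized
residual-vs-fitted coordinates.  A rank-deficient design is rejected
with the collinear columns named.

**Response surfaces.** Predictions of the fitted network over a grid of
two inputs (default the two nonlinear components, spanning their
observed ranges, 25 points per axis), with the other components fixed
at their corpus medians and (week, mean FHR) stepped through
{30, 37, 41} x {110, 140, 170} bpm — nine surfaces probing how the
nonlinear dynamics' influence changes across gestation and baseline
rate.

## Pipeline and reproducibility

All stages run under one YAML-validated configuration (unknown keys
rejected) with a single global seed fanned out to per-stage seeds by a
counter-based SeedSequence derivation, so any stage can be rerun in
isolation and a rerun with the same configuration reproduces every
numeric table bitwise.  All artifacts are plain text: per-record CSV
traces (missing samples as empty fields), corpus metadata, YAML ground
truth, feature and reduced tables, and structured text reports for the
quality gate, the per-block PCA (correlation tables with highlight
markers and eigenvalue spectra) and the models.  Table readers parse
floats in round-trip mode so write-read-write is byte-identical.

Problem sizes used by the test suite were chosen to keep a full run in
about a minute of single-core compute: corpora of 10-30 records for
pipeline mechanics, 187 records (the reference corpus size) for
structure checks, 500 for the count-calibration check, and n = 400 with
a reduced hidden-size grid for the model-ordering check.

## Known limitations

* The floatingline cannot separate VLF variability from genuine
  baseline drift (they overlap spectrally); VLF features computed on
  the residual mostly reflect leakage and should be treated as
  low-information on 20-min records.
* The symbolic-dynamics VI and the floatingline filter are
  contract-faithful stand-ins for published methods whose exact
  definitions were not reproducible; both are documented above and
  tested against their stated properties, not against the original
  implementations.
* The nonlinear-feature grouping that emerges from the *signal-level*
  generator differs from the reference pattern (the amplitude scale
  drives SD1/SD2 while roughness drives SampEn, HFD and both VIs);
  retention counts and component naming are unaffected.
* Clinical headline values from the motivating study design (fitted
  R^2 values, exact loadings, inclusion ratios) depend on a
  request-only clinical dataset and are out of scope; the package
  reproduces the route and its calibration targets, not those numbers.
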