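# Methods

This note documents the models, estimators and design choices behind
`priorclarity`, what its synthetic-data generators do and do not
emulate, and the numerical conventions its results depend on.

## Perceptual model

The clarity model treats the listener as an ideal observer combining a
prior expectation about speech content with degraded sensory input.

**Sensory precision.** For each vocoder-channel level
`c ∈ {4, 8, 16}`, precision is the 4AFC identification accuracy
expressed as proportion above chance, `s_c = max(0, (acc_c − 0.25) /
0.75)`, dimensionless in `[0, 1]`. It is fixed per subject before any
fitting, so group differences in raw identification ability cannot
masquerade as differences in prior precision.

**Posterior precision.** The posterior multiplies sensory precision by
a weighted function of prior precision:

    P = s_c · (1 + w / σ²)

with `σ > 0` the prior standard deviation (arbitrary units) and `w` the
congruency weighting (`0.5` for a matching cue — the cue validity in
the paradigm — and `0` for mismatching or uninformative cues). This
form was chosen because it is (a) multiplicative, (b) reduces *exactly*
to `P = s_c` when the prior carries no weight, and (c) is monotone in
prior precision `1/σ²`. Freeing `w` and freeing `σ` are mathematically
interchangeable, so "excessively precise priors" and "inflexible
priors" describe the same fitted quantity.

**Clarity mapping.** Posterior precision at or below the perceptual
threshold `θ ≥ 0` maps to rating 1; above it, ratings rise linearly to
4 at the subject's maximum condition precision `P_ref` (subjects are
trained to use the full scale, which the per-subject anchor
implements):

    rating = 1                              if P ≤ θ
    rating = 1 + 3 (P − θ) / (P_ref − θ)    otherwise, clipped to [1, 4]

If every condition falls at or below threshold the mapping is
degenerate (an "all-unclear" subject) and is reported as an error
rather than silently returning all-ones.

**Fitting.** `(σ, θ)` — plus `w_match_16 ∈ [0, 1]` in the complex
variant — are fitted to the six condition-mean ratings by least
squares. Fitting condition means (n = 6) rather than single trials
keeps the AICc small-sample correction meaningful (k = 3 requires
n ≥ 5) and matches how condition-level fits are usually reported.
Global minimisation is emulated deterministically: 32 Latin-hypercube
starting points over bounded space (`σ ∈ [10⁻³, 10³]` searched on a
log₁₀ scale; `θ ∈ [0, 1]`), each refined with L-BFGS-B, best kept. A
vectorised grid evaluation of the RSS surface (`rss_surface`) serves as
an independent oracle; tests require the optimiser never to be beaten
by a 100×100 grid.

**Model comparison.** `AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`;
lower wins, ties break toward the simpler variant, and fits are refused
comparison unless they hash to the same observed data.

## Trial designs

- **Experiment 1**: 2 congruency × 3 channel levels, 108 trials per
  cell over six blocks (18 per cell per block); written cue → spoken
  word → clarity probe with 1050 ms intervals jittered uniformly ±50 ms
  (uniform is the minimal assumption for a "±50 ms" specification).
  324 spoken words are each heard twice — once matched, once
  mismatched — never twice under one congruency. The generator treats
  these per-condition counts and reuse caps as the binding constraints
  and reports realised word tallies in the schedule summary. Mismatch
  is modelled purely as "different word identity"; no phonological
  feature space is represented. `order_label` selects one of two fixed
  seed-derived trial orders, mirroring counterbalanced fixed random
  orders.
- **Experiment 2**: 90 4AFC identification trials; 30 response sets
  (target, offset neighbour, onset neighbour, unrelated) each presented
  once per channel level. Each set contributes its 2-neighbour and
  0-neighbour cases plus one of the two 1-neighbour cases; a cyclic
  rotation balances cases over channel levels so each level realises
  case counts (10, 5, 5, 10). The (channels, difficulty) slot sequence
  is fixed; the seed randomises only set-to-slot assignment.
- **Neutral replication**: one block, 3 congruency (match / mismatch /
  uninformative cue) × 3 channel levels × 18 trials.

## Synthetic behaviour

Subjects are parameterised by `(σ, θ)`, a rating noise SD, and an
identification ability. 4AFC accuracy follows a chance-floored
logistic,

    acc = 0.25 + 0.75 · logistic(ability + 1.0·log₂(c/4) − 0.5·n_neighbours),

whose slopes (1.0 per channel doubling, 0.5 per neighbour) were chosen
once to produce monotone channel and distractor effects of realistic
size for elderly listeners; single-trial ratings are the model's
condition mean plus Gaussian noise (default SD 0.3 rating units),
rounded half-up and clipped to {1..4}. The default cohort is 11
controls and 11 patients; prior SDs are log-normal with medians 1.0
(controls) vs 0.4 (patients) and log-SD 0.4, thresholds normal
0.10/0.07 ± 0.03, abilities 0.5/0.0 ± 0.3 — i.e. patients hold more
precise priors, marginally lower thresholds and slightly weaker
identification, the configuration the group statistics are meant to
detect.

What this generator does *not* emulate: sequential effects, lapses,
response bias, ordinal-scale distortions, or any phoneme-level
structure. A passing recovery suite therefore shows the estimator is
correct under the model's own assumptions at study-scale noise, not
that real raters obey Gaussian-round-clip noise (no single-trial noise
model is established for such data; ours is a stand-in).

Two sensory-precision tables are carried per simulated subject: the
*measured* table (from the simulated 90-trial identification block —
what an experimenter would have) and the *true* table (expected
accuracy under the generating parameters). Cohort pipelines use the
measured table; the headline recovery property conditions on the true
table to isolate rating noise, the quantity it is about.

## Neural statistics

All source-level analyses run on two-region (frontal / temporal)
per-trial arrays, 0–912 ms after spoken-word onset at 250 Hz
(228 samples).

- **Morlet power**: 7-cycle complex Morlet wavelets, 4–80 Hz in 2 Hz
  steps (39 bins), zero-mean and unit-energy, envelopes truncated at
  5 SD or the epoch length. Samples without full wavelet support are
  masked, never zero-padded into statistics. Baseline rescaling is
  `10·log₁₀(power / mean baseline power per band)` against a
  pre-written-word window.
- **Congruency-contrast latency (t80)**: the 12–24 Hz band mean of
  (mismatch − match) rescaled power, searched 0–1000 ms at 4 ms
  resolution with no smoothing; `t80` is the earliest sample at or
  above 80% of the peak (a relative tolerance of 10⁻⁹ guards exact
  analytic crossings against float rounding). The signed contrast is
  the default (matching cues suppress the response, making the
  contrast positive at effect); an absolute-value fallback is
  available by flag. Non-positive peaks yield an explicitly undefined
  latency.
- **Evoked subtraction** removes each condition's mean waveform so the
  spectral analyses see induced, approximately stationary activity.
- **Cross-spectra**: Slepian multitapers with ±4 Hz smoothing
  (`NW = T·W`, `K = max(1, ⌊2TW − 1⌋)` = 6 tapers for the 0.912 s
  window), per-trial Hermitian 2×2 matrices on the rFFT grid.
- **Imaginary coherence**: `|Im(S_xy / √(S_xx S_yy))|` from trial- and
  taper-averaged spectra — insensitive to zero-lag (volume-conducted)
  mixing, which the tests verify directly.
- **Spectral Granger causality**: bivariate VAR fitted by least squares
  pooled across trials (order by AIC up to 10, or fixed), stability
  checked via companion eigenvalues, then Geweke's frequency-domain
  decomposition into the two directed components. The parametric
  VAR/Geweke route was chosen over nonparametric spectral
  factorisation for transparency and testability against simulated
  ground truth; numeric parity with any particular toolbox is not a
  goal.
- **Permutation nulls**: 1000 trial-label shuffles by default; one
  region's trial order is permuted per replicate, the observed pairing
  is never included in the ensemble, and per-frequency 95th percentiles
  summarise the null. Fewer than 100 shuffles triggers a warning. For
  Granger nulls the VAR order is held at the observed-data order across
  permutations.
- **Relative influence**: each direction's Granger spectrum divided by
  its own across-frequency mean (output mean exactly 1), removing
  signal-to-noise scale differences before between-direction or
  between-subject comparison.
- **Directionality contrast**: per-frequency paired t statistics on the
  within-subject difference of normalised profiles, corrected across
  frequencies by suprathreshold-cluster mass (cluster-forming p = 0.05
  two-sided) against a max-cluster sign-flip permutation null. With one
  frequency this reduces to a paired t-test.

The coupled-source generator drives the receiver with a lagged,
band-limited copy of the driver's component (`strength` = fraction of
receiver variance from the driver; lag ≥ 1 sample, since zero-lag
coupling carries no imaginary coherence) plus independent noise. The
implanted-latency generator snaps the requested latency to the 4 ms
grid and aims the analogue 80% crossing half a sample early so its
small additive noise (10⁻³ of amplitude) cannot move the sampled
crossing; recovery is then exact to within half a sample.

## Group statistics

Rank-sum comparisons use midranks and, for n₁+n₂ ≤ 24, an exact null by
convolution over doubled midranks; two-sided p doubles the smaller
tail, capped at 1. Because the U convention differs between sources,
both `U` and its complement `n₁n₂ − U` are reported. The
normal-approximation mode applies tie correction and a 0.5 continuity
correction. Associations report Pearson and Spearman coefficients
together.

## Problem sizes and calibration checks

The test suite validates, among others: noiseless generate-and-refit to
RSS < 10⁻⁶; Spearman ≥ 0.9 recovery of the prior SD across 22 subjects
at 108 trials/condition and rating noise 0.3; ≥ 80% AICc preference for
the simple variant over 50 subjects it generated; implanted-latency
recovery within one sample over 50 implants; trial-shuffle null type-I
error within [0.03, 0.07] (200 replicates × 200 shuffles on 20-trial,
114-sample uncoupled data — exceedances pooled across frequencies, which
are mutually correlated); and exact-test calibration of the rank-sum
null (10⁴ rank-permutation replicates). These sizes were chosen to
estimate each quantity with comfortable margin while keeping the whole
suite fast on a single CPU.

## Known limitations

- The exact analytic form of the posterior-precision weighting and of
  the clarity normalisation is a package design choice satisfying the
  model's stated constraints; other monotone multiplicative forms would
  fit condition means comparably and would rescale `σ` units.
- Threshold (`θ`) is weakly identified from a single subject when
  sensory precision is itself estimated from 30 trials per level; the
  prior SD is the robust quantity.
- No source reconstruction, head modelling, sensor-level statistics or
  artefact handling: inputs are assumed to be extracted source time
  series.
- The VAR-based Granger estimator assumes within-window stationarity
  after evoked subtraction and a finite-order linear model.
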