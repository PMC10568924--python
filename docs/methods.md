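# Methods

`usvkit` re-implements, as a tested library, an adaptive-threshold
spectrogram detector for rat ultrasonic vocalisations (USVs), the
session-level behavioural variables built on its output, and the
mixed-model analysis of per-session call counts. A seeded synthetic-data
stage generates both ultrasonic audio with exact ground truth and
cohort-structured behavioural tables, so every downstream step can be
validated end to end without any external data.

## The detector

A mono recording (default 250 kHz sampling rate) is processed in 0.5 s
segments. Each segment is transformed with a 1024-sample Hann window at
90% overlap. The fractional hop (102.4 samples; frame *m* starts at sample
`round(m·102.4)`) gives exactly 1211 frames per 0.5 s segment, with
frequency bands of fs/1024 ≈ 244.1 Hz; band *b* covers the half-open
interval `[b·Δf, (b+1)·Δf)`. The 50-kHz profile restricts analysis to the
136 bands intersecting 35–68 kHz and computes, per frame, the mean μ_t and
sample SD σ_t of the amplitudes over the 126 bands in 37.44–68 kHz. A band
*exceeds* when its amplitude is strictly greater than μ_t + 2.1·σ_t; a
frame is *flagged* when at least 4 bands exceed. Flagged frames whose start
times lie within 40 ms of one another are grouped; groups of at least 16
flagged frames become candidate calls spanning the first flagged frame's
start to the last flagged frame's start plus one hop, and candidates
shorter than 6.6 ms are discarded. Because 16 contiguous frames span only
6.55 ms, the effective minimum for a contiguous group is 17 frames; the
grouping/duration conventions (gap measured between frame start times,
duration = (last − first + 1)·hop) are declared here and configurable. The
whole recording is tiled twice — pass offsets 0 and 0.25 s — so any call of
≤ 0.25 s lies wholly inside at least one analysis window of one pass;
detections from both passes are combined by interval union (overlapping or
abutting detections merge; duplicates collapse). A trailing partial
segment is processed whenever it still contains one full analysis window.

The 22-kHz profile changes the band range to 18–26 kHz (34 bands, used
both for detection and for the frame statistics), the SD multiplier to
1.3, and the flagged-band minimum to 2, inheriting the grouping and
duration parameters.

### Amplitude scale

The frame statistics are computed on dB-converted magnitudes,
`20·log10(|A|/2·10⁻⁵)` (the Avisoft-style pressure reference carried as
metadata; a floor of 10⁻³⁰ guards exact zeros). This choice matters. The
across-band distribution of *linear* STFT magnitudes of Gaussian noise is
Rayleigh, whose right tail puts ≈ 3% of bands above μ + 2.1σ — about four
of 126 bands per frame, so most noise-only frames would be flagged and
the detector would be unusable (we measured ~75% flagged frames on the
default tilted noise). On the dB scale the distribution is left-skewed
with a light right tail: the same rule flags ~0.04% of noise-only frames,
and noise alone produces no detections. The detector is exactly invariant
to any positive gain on either scale (a gain is an additive dB constant,
shifting mean and threshold together); `amplitude_scale="linear"` is
available for comparison experiments.

Known property: with the printed 22-kHz parameters (1.3 SD, ≥ 2 bands
over 34), even dB-scale statistics flag roughly half of noise-only frames
under the synthetic background, so the 22-kHz profile produces spurious
detections on noise. This is an intrinsic property of those parameters,
kept as printed; quantitative accuracy claims in this package are made
for the 50-kHz profile only, and 22-kHz per-session counts in the
simulated cohort come from the count generator, not from audio.

### Evaluation

Detections are matched one-to-one to ground-truth calls greedily by
descending temporal intersection-over-union (IoU), ties broken by onset
difference; a pair may match when IoU ≥ 0.3 or the onsets differ by at
most 5 ms. Recall = matched/truth, precision = matched/detected; with no
truth calls recall is 1 by convention, with no detections precision is 1
(no false alarms). The tolerances are strict at typical 20–100 ms call
durations and are configurable.

## Synthetic audio

The background is Gaussian noise whose amplitude spectrum falls off as
f^(−α) above 1 kHz (flat below, so the spectral shape does not depend on
recording length), α = 1 by default — a pink-like tilt resembling
ultrasonic recording noise floors; α = 0 (white) is available for stress
tests. Calls are phase-continuous FM tones with raised-cosine ramps
(≥ 2 ms, shortened to a quarter of very short calls): *flat* (constant
carrier), *sweep* (linear chirp), *trill* (sinusoidal FM, rates 40–90 Hz,
depths 2–6 kHz) within 35–68 kHz, and *long22* (0.3–2 s narrowband calls
at 18–26 kHz). Call durations for the 50-kHz class are uniform
15–120 ms; the default type mix is 40% flat / 30% sweep / 30% trill.

All calls carry seeded instantaneous-frequency jitter (SD drawn from
250–600 Hz, ~1 ms correlation time, clipped to the class band). This is a
deliberate realism feature: rodent phonation has cycle-to-cycle frequency
jitter, giving even nominally flat calls an instantaneous bandwidth of a
few hundred Hz. A mathematically pure tone is narrower than a single
244 Hz analysis band, excites only 2–3 rfft bins, and therefore can never
satisfy a ≥ 4-bands-per-frame criterion — it is not a realistic stand-in
for a biological call. `CallSpec` defaults to zero jitter so closed-form
examples (dominant bin of a tone, etc.) hold exactly.

SNR is defined in-band: RMS of the call waveform divided by the RMS of
the background restricted (by FFT masking) to the call class's detection
band, in dB. Benchmark amplitudes are calibrated from the in-band RMS of
a fixed reference noise realisation, so realized SNRs land within ~1 dB
of their targets; each truth annotation records the realized value.

The standard benchmark plan places 200 calls at SNR uniform in 15–30 dB
with a minimum inter-call gap of 80 ms. The gap exceeds the detector's
40 ms grouping window plus ~4 ms of analysis-window smearing per side:
calls closer than that are merged into a single detection *by
construction* of the published algorithm. That resolution limit is tested
separately (grouping property); the benchmark measures detection, not
temporal resolution. What a passing benchmark shows — and does not show —
about real recordings: synthetic backgrounds are stationary and calls are
clean FM tones; real tickling sessions contain broadband transients
(scratching, handling) and overlapping harmonics that this generator does
not emulate, so benchmark recall/precision bound the algorithm's
behaviour under its stated assumptions, not its field performance.

## Cohort simulation

The simulated cohort mirrors the study layout: batches A (17 rats, 10
test days), B (18 rats, 7 days), C (18 rats, 10 days) — 53 rats, 476
sessions — four litters per batch, treatments (control / kinematically
reduced / socially reduced play) balanced within batch, and a fixed
tickling-order position per rat.

* **Received pinnings** are Poisson with log-link predictor over
  treatment and batch (defaults: intercept 3.20 for control/batch A,
  −0.45 socially reduced, −0.82 batch C). Kinematically reduced rats
  receive exactly zero (their low-ceiling cage precludes being pinned),
  matching the structural zero that motivates excluding that group from
  the pinning model. Delivered pinnings use the same predictor with a
  positive shift (+0.35, log scale) for socially reduced rats, whose less
  playful partners rarely pin back — so their asymmetry score is shifted
  upward, following the study's verbal description. (The printed
  asymmetry-model coefficient table is internally inconsistent with the
  score's [−1, 1] bounds and is not used as generative truth.)
* **50-kHz counts per session** follow a Gaussian linear mixed model:
  intercept 136.27, day slope 3.09, order slope 4.31, treatment shifts
  −33.35 (social) and −8.59 (kinematic), batch shifts −25.56 (B) and
  −23.58 (C), with Normal rat (SD 51.6) and litter (SD 26.5) intercepts
  and residual SD 42. These SDs give rat repeatability
  σ²_rat/(σ²_rat+σ²_litter+σ²_res) = 0.519 and litter repeatability 0.137,
  and a marginal session SD of ~72, matching the study scale. Counts are
  floored at zero and rounded; `floor_at_zero=False` yields the exact
  Gaussian model for estimator validation (the truncation affects < 1% of
  sessions at the defaults and does not disturb coverage measurably).
* **22-kHz counts** are Poisson with log-link predictor (intercept −0.72,
  day 0.17, batch B 2.13, batch C −0.01) plus latent Normal rat (SD 0.48)
  and litter (SD 0.10) intercepts. The rat SD is calibrated so the
  latent-scale repeatability, with distribution-specific variance
  ln(1 + 1/λ̄), is ≈ 0.38 at the cohort's fixed effects.

The contact schedule alternates 15 s hover ("none") and 15 s tickle
blocks; each tickle block splits into a dorsal then a ventral sub-period
(default 50/50, configurable). A 120 s session yields 4 hover and 4
tickle blocks.

## Session metrics

Calls are assigned to contact periods by onset time with half-open
intervals `[start, end)` everywhere, so boundary calls are never double
counted and per-period counts sum exactly to the session count. The
emission rate per period type is total calls over summed duration
(seconds). The play asymmetry score is (delivered − received)/(delivered
+ received), in [−1, 1], antisymmetric under swapping the roles and
undefined (an explicit error) when both counts are zero.

## Statistical models

* Received pinnings: log-link Poisson GLM (treatment + batch;
  kinematically reduced group excluded as a structural zero).
* Asymmetry score: OLS with treatment and batch.
* 50-kHz counts: Gaussian LMM with rat and litter random intercepts (rat
  nested in litter; implemented via statsmodels MixedLM with the litter
  as grouping factor and the rat intercept as a variance component). The
  Gaussian-on-counts choice is kept deliberately — it is the model the
  analysis is defined with. ML is used when comparing fixed-effect
  structures, REML for reported coefficient tables.
* 22-kHz counts: log-link Poisson mixed model with rat and litter
  intercepts, fitted by Laplace-approximate maximum likelihood written in
  this package (penalized-IRLS joint mode, Nelder-Mead profile over the
  two variance components, and a final profile of the fixed effects
  through the Laplace objective, which matters near variance boundaries).
  The fitter agrees with lme4's `glmer` to ~10⁻⁴ on coefficients and
  ~3·10⁻⁴ on log-likelihood on a 476-session cohort; that cross-check is
  part of the test suite.
* Model selection: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k counting
  fixed effects plus variance components (including the residual variance
  for Gaussian families). The counting convention is configurable in the
  sense that k is stored on each fit and AICc is a pure function of
  (ℓ, k, n).
* Repeatability: R = σ²_term/(σ²_rat + σ²_litter + σ²_residual) for
  Gaussian fits; Poisson fits use the latent log scale with the
  distribution-specific variance ln(1 + 1/λ̄), λ̄ evaluated at the mean
  fixed predictor plus half the summed random variances. Confidence
  intervals come from a seeded parametric bootstrap (default 1000 draws;
  simulate from the fitted model, refit, take percentile limits).
* Marginal means: levels of the target factor are crossed with all levels
  of the other categorical terms (equal weights), numeric covariates at
  their observed means; means are averaged on the link scale,
  back-transformed for Poisson fits, with normal-approximation CIs and
  Tukey-adjusted (studentized-range) pairwise contrasts.
* Spearman correlation via average ranks, with an explicit error on
  constant input.

## Numerical choices and degenerate inputs

Segments shorter than one analysis window raise a typed error; empty flag
sequences and empty detection lists flow through as empty outputs. Exact
zeros in the spectrogram are floored before dB conversion, so silent
segments give constant frames, zero SD, and (by the strict inequality) no
flags. Merging uses a 1 ns tolerance for "abutting". Mixed-class merges
and undefined asymmetry raise. Singular mixed-model fits are reported via
a flag on the fit, never silently dropped; on deliberately tiny cohorts
the pipeline records a fit failure in its report instead of crashing.

## Problem sizes

Default test and acceptance runs use: the 200-call benchmark (~45 s of
audio at 250 kHz, detected in a few seconds), 200-replicate coverage
experiments for the Poisson GLM and the Gaussian LMM at the full
53-rat × 476-session cohort, 20-replicate repeatability recovery, and a
scaled-down full-synthetic pipeline (6 rats, 12–20 s sessions) whose
per-session detected counts are verified to equal the planted truth
exactly before any model is fitted.

## Known limitations

The detector reproduces the published parameters and declared conventions,
but the original script's exact onset/offset conventions are not public;
ours are documented above and configurable. The 22-kHz profile's
false-alarm behaviour on noise is documented rather than repaired, since
repairing it would change printed parameters. The synthetic cohort
reproduces the generating structure of the analysis, not the study's
actual data; reproduction of the published coefficient tables requires
the deposited per-session tables, which the package reads through
`run_reproduction` when provided under `data/deposited/`.
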