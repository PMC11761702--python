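# Methods

This note documents the models and procedures `reachmetrics` implements,
the conventions it fixes where the field leaves a choice open, and what
the synthetic generators do and do not emulate.

## Pose preprocessing

Pose tables follow the markerless-tracking CSV dialect (three header rows
scorer / bodyparts / coords, one x/y/likelihood triplet per body part)
with seven canonical points: digits 1–5, wrist, pellet. Coordinates are
pixels in the image frame (origin top-left, x rightward, y downward),
frames 0-based, at a default 309 frames/s.

- **Median filter.** Each coordinate series is run through a 5-sample
  (~15 ms) running median to remove single-frame tracker glitches. Edge
  policy: the window shrinks at the trial boundaries, preserving length.
  The window is configurable but must be odd.
- **Mirroring.** Left-pawed animals are flipped into the right-pawed
  frame (`x ↦ width − 1 − x`, 0-based pixels) so one template convention
  serves all animals. Mirroring is an involution and preserves
  inter-point distances.
- **Paw preference.** The paw used ≥ 6 of the first 10 shaping reaches.
  A 5–5 split returns `undetermined` rather than guessing; the rule only
  defines a preference at ≥ 6.

## Stereotypy by template matching

A *grab* is one reach-and-close event; trials contain several. The
canonical grab is a 50-sample × 10-coordinate template (5 digits ×
{x, y}; the pellet is tracked for bookkeeping but does not enter the
statistic) built per animal and session by averaging three grab windows.

- **Correlation.** At every frame whose 50-sample window fits inside the
  trial, the Pearson correlation between window and template is computed
  per coordinate and averaged across the 10 coordinates. The Pearson
  (normalised) form is used because the score must be a bounded
  correlation coefficient, invariant to uniform translation and positive
  scaling of the coordinate frame; raw dot-product cross-correlation has
  neither property. Zero-variance coordinates (flat tracking) contribute
  0 at that alignment and are logged.
- **Alignment.** Windows are centred: the score at frame f covers
  [f − 25, f + 25). Edge alignments are NaN, never zero-filled, so the
  "final grab" can never be an edge artifact.
- **Detection.** Local maxima above `min_score` (default 0.3) are kept
  greedily in descending score order with a `min_separation` exclusion
  zone (default 50 samples — one template length, since two grabs cannot
  overlap within a single reach cycle). Both thresholds are exposed in
  the API and CLI. The last surviving peak is the final grab; its score
  is the trial's stereotypy. Trials without a detected grab yield a
  missing score and are counted, not silently dropped.
- **Template-grab selection.** Which three grabs seed a session template
  is a genuinely open choice. The default is automatic and
  deterministic: a seed template is bootstrapped as the cross-trial
  average of windows at each trial's motion-energy peak, then from each
  of the first three trials with a grab detected against that seed, the
  highest-scoring grab is taken and the three windows averaged. The
  selection is logged per session. Any externally chosen grabs can be
  passed to `build_template` directly.

## MEP quantification

Sweeps are EMG recordings (mV, 10 kHz) around an epidural stimulation
train; `stim_onset` marks the first pulse.

- **Window mean.** Mean of |signal| over [onset + 10 ms, onset + 30 ms),
  half-open with inclusive start. Sweeps are assumed artifact-truncated
  upstream; optional blanking of an early post-pulse interval exists but
  is off by default.
- **Condition amplitude.** Median of the 20 per-trial window means
  (mean-of-middle-two for even counts), robust to occasional spontaneous
  motor-unit bursts. Statistics use the natural log of the median, so
  differences read as amplitude ratios; the base only rescales
  coefficients. A zero median is flagged rather than raised.
- **Motor threshold.** Smallest tested current with > noise-floor
  (0.05 mV) responses in ≥ ceil(0.9 n) of n trials (18 of 20); "above"
  is strict. No qualifying current returns an explicit no-threshold
  result. Exclusion criteria like "unreliable threshold" are flagged for
  the analyst, never auto-applied.
- **Recruitment curve.** Per-intensity amplitudes at 90/100/120/140/200%
  of threshold, sorted, with absent intensities flagged missing.

## Electric-field dosimetry

Four contacts on a 1 mm square planar lattice record potentials during
sinusoidal stimulation at 10/100/1000 Hz and 10/20/40 μA.

- **Demodulation.** Each channel's component at the stimulation
  frequency is a least-squares fit of sine + cosine + offset over an
  integer number of cycles (records shorter than one cycle are
  rejected). The complex phasors keep relative sign information between
  channels.
- **Field estimate.** Least-squares gradient fit of V = c − E·r over the
  four contacts, which on the unit square equals the mean of the two
  parallel pair differences divided by the 1 mm spacing in each
  direction. Sign convention E = −∇V; downstream analysis uses the
  magnitude, as dosimetry requires.
- **Gain.** Through-origin regression of |E| on current (zero current
  gives zero field physically); an ordinary-intercept slope is kept as a
  diagnostic. Gains are reported per frequency; calibration uses the
  gain at the caller's frequency — recording chains are typically
  calibrated for unit gain at 1000 Hz, so that is the default. DC gain
  is out of scope (electrode impedance dominates at 0 Hz).
- **Outliers.** Points are flagged when their residual from the robust
  through-origin line (median of per-point |E|/current ratios) exceeds
  3× the MAD of the residuals. The robust slope is used for *flagging*
  because a least-squares line is dragged toward a gross outlier and
  would implicate clean points; the reported gain remains the
  least-squares fit, optionally refitted after exclusion at the caller's
  request. A MAD of zero (perfect line) flags nothing beyond a
  magnitude-relative epsilon.
- **Calibration.** current = target / gain, e.g. a montage gain of
  0.0141 (V/m)/μA needs ≈ 142 μA for 2 V/m. Gain is always a measured
  input; no montage constant is hard-coded.

## Learning-curve mixed models

All longitudinal outcomes are fitted with linear mixed-effects models
(statsmodels `MixedLM`, REML) with a per-animal random intercept:

    y_id = β0 + β1·log(d) + β2·G_i + β3·G_i·log(d) + b_i + ε_id

with day d numbered from 1 and natural log (day 1 = 0, so β2 is the
day-1 group offset). Unbalanced tables (animals missing late days) are
handled by the likelihood. Wald t statistics are reported on residual
degrees of freedom (n_obs − n_fixed); single-df F statistics are t².
Different mixed-model software disagrees on denominator df — the
convention here is fixed and documented, and validation is by synthetic
recovery, not by df matching. The random-intercept structure is the
default; a random log-day slope is available behind a flag with a
likelihood-ratio comparison (`compare_random_slope`, ML-fitted, df = 2,
conservative at the boundary).

Model variants: successes (counts, fitted as Gaussian), success rate
(successes/attempts as a linear response — a pragmatic mirror of common
practice, not a binomial model; rows with zero attempts are dropped and
counted), per-trial stereotypy (optionally restricted to one
paw-preference subset — left- and right-pawed animals behave differently
and the 3-way interaction is deliberately avoided — and stratifiable by
trial success), and MEP log-amplitudes (side contrast, contra−ipsi
log-difference with tDCS × training factors, and a success + tDCS
model). No multiple-comparison correction is applied anywhere; every
summary prints that caveat, and any analysis beyond the single planned
interaction should be treated as exploratory.

## Synthetic generators

The generators define the conditions every test and the acceptance
script run under. All are deterministic per seed, with per-trial /
per-animal sub-streams derived via `SeedSequence` so growing a cohort
never perturbs earlier units.

- **Pose trials** (default 100 trials × 400 frames, 3 grabs/trial,
  ≥ 60-frame separation): a smooth reach–advance–close arc (raised-cosine
  profiles with per-digit lags, amplitudes ~150 px — the scale of a rat's
  reach in a 2032×1086 px frame) spliced into a resting baseline. Shape
  noise (Gaussian-smoothed, σ = 25 px — a couple of digit-widths, the
  scale of early-training reach variability) and a time warp (SD 8%) are
  scaled by (1 − stereotypy_level); per-frame tracking jitter of 1.5 px
  (matching typical tracker test error) is added everywhere. At
  stereotypy 1 with zero baseline noise the embedded grab equals the
  base waveform exactly — the identity the oracle tests rely on.
- **Learning tables** (default 24 animals, 10 days): Gaussian responses
  around the linear-in-log-day predictor (β0 = 5, β_day = 8,
  β_tdcs = 0, β_interaction = 2, animal SD 3, residual SD 4 — plausible
  single-pellet success counts rising from ~5 to ~25), rounded and
  floored at 0. The Gaussian generative model matches the fitted linear
  model by design; real success counts are integer-valued and
  heteroscedastic (binomial-like), which this generator does not
  emulate — passing recovery tests certifies the pipeline's estimator,
  not the count-data adequacy of a linear model. Rounding adds ±0.5
  quantisation noise; `round_counts=False` exposes the latent response
  for exact-recovery validation. Attempts add Poisson(15) unsuccessful
  reaches; paw preference is drawn with P(right) = 13/24.
- **MEP sweeps** (default 20 trials × 5 intensities): a positive
  half-cosine² burst filling the [10, 30) ms window under a sign
  alternating carrier, so the rectified window mean has the closed form
  amplitude × mean(envelope). Amplitudes follow a logistic recruitment
  (midpoint 115%, slope 0.06/%, max 1.2 mV) with lognormal trial jitter
  (SD 0.2) and a 0.01 mV noise floor. Real MEPs have variable latency
  and polyphasic shapes; the fixed envelope is what makes the analytic
  oracle possible.
- **Field recordings**: uniform-field potentials V = −E·r on the lattice
  with E = gain × current × sin(2πft), plus white noise (10 μV). The
  uniform-field assumption is exact by construction, so the estimator's
  residual is pure noise; real tissue adds gradients and electrode
  impedance effects the generator does not model. Default true gain
  (0.010, 0.010) (V/m)/μA — magnitude ≈ 0.0141, a realistic epicranial
  montage gain — puts the calibrated current for 2 V/m near 140 μA.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to give stable Monte-Carlo
statistics at interactive runtimes: 20 trials for the correlation
oracle, 100-trial cohorts per stereotypy level, 200 null cohorts for the
type-I error of the interaction test (the exact binomial 95% band at
α = 0.05 is [2.4%, 8.9%]), and 100 cohorts for CI coverage. Degenerate
inputs are handled explicitly rather than by exception where the science
requires it: zero-variance correlation coordinates → 0, zero MEP median
→ flagged NaN log, MAD = 0 outlier rule → epsilon threshold, singular
mixed-model fits (zero-variance data) → flagged `converged=False` while
fixed effects remain exact (any weighted least squares reproduces an
exactly linear response).

## Known limitations

- The stereotypy statistic is sensitive to the template-grab selection
  rule in low-quality sessions; the automatic rule is deterministic but
  not guaranteed optimal.
- The success-rate model treats a ratio as Gaussian; near 0 or 1 its
  residuals are necessarily non-normal.
- Reported df follow the residual-df convention and will not match
  software using Satterthwaite or Kenward-Roger approximations.
- The field estimate assumes a locally uniform field over the 1 mm
  lattice; curvature in the true potential biases the finite-difference
  gradient.
- No DC gain estimation, no finite-element head modelling, no video
  processing or pose estimation — the pipeline begins at tracked
  coordinates.
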