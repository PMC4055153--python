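# Methods

`alphavar` studies the trial-to-trial ("moment-to-moment") variability of
auditory alpha-band power in resting-state MEG. The scientific question it
operationalizes: is ongoing low-alpha (8–10 Hz) activity over temporal
cortex weaker *and less variable* in people with chronic tinnitus than in
matched controls, and does that variability shrink with tinnitus duration?
Because no public data accompany the reference design, the package pairs the
analysis pipeline with a synthetic-cohort generator whose planted parameters
are exactly the quantities the pipeline estimates.

## Analysis pipeline

1. **Line-noise removal.** Per channel and per 2 s window, the sine and
   cosine components at 50 Hz are least-squares estimated and subtracted.
   With an integer number of line cycles per window the removal is exact and
   orthogonal content is untouched (tested to 1e-10).
2. **Downsampling** to 600 Hz by polyphase resampling with a zero-phase FIR
   anti-alias filter; non-integer ratios (678.17 or 2034.51 → 600 Hz) use a
   rational approximation accurate to < 2 ppm.
3. **Segmentation** into consecutive, non-overlapping 2 s epochs (trailing
   partial epoch dropped).
4. **Artifact flagging.** An epoch is flagged iff any channel's peak-to-peak
   exceeds an absolute threshold or any channel's epoch-variance z-score
   (across epochs) exceeds a second threshold. The pipeline's default
   absolute threshold is adaptive: 6x a gap-robust ceiling (the largest
   per-epoch max-channel peak-to-peak not exceeding 8x its 75th percentile).
   Rationale: lognormal-envelope oscillations legitimately span an order of
   magnitude of epoch amplitude, so a plain quantile anchor either censors
   the physiological tail (biasing the CV downward) or is dragged up by the
   artifacts themselves; blink-scale transients sit well above the gap. The
   variance-z default (25) is deliberately far out for the same reason.
5. **Random selection** of exactly 90 clean epochs (180 s of data per
   subject), uniformly, from a seed derived by hashing (master seed,
   subject id) so results do not depend on subject processing order.
6. **Spectra.** Each selected epoch is Hann-tapered and Fourier-transformed
   on the 1–100 Hz grid in 0.5 Hz steps (199 bins; the native resolution of
   a 2 s epoch, so every grid frequency is an exact DFT bin). Power is the
   one-sided, taper-power-compensated density `2|X|^2 / (fs * sum(w^2))`;
   statistics use these raw values (normalized, relative power exists for
   presentation only — the CV is invariant to the choice either way).
7. **CV.** Per (sensor, frequency bin), the sample (n−1) standard deviation
   of power across the 90 epochs divided by its mean. Band/ROI values
   average the per-bin CV over the band's bins (half-open `[lo, hi)`, so the
   shared 10 Hz edge belongs to the upper band exactly once) and over each
   hemisphere's ROI sensors. The coarser alternative — CV of pre-averaged
   band power — is available as `cv_order="band_first"` for sensitivity
   analysis.
8. **ROI.** Per hemisphere, the k (default 4) temporal-tagged sensors with
   the most negative tinnitus-minus-control difference of epoch-averaged
   8–10 Hz power; ties break by sensor id. The ROI is frozen after this one
   definition and reused for every band and outcome.
9. **Statistics.** Group contrasts are linear mixed models (outcome ~ group,
   random intercept per subject) on the two hemisphere observations per
   subject, fitted by REML (statsmodels MixedLM). The group effect is
   reported as F = t_Wald^2 with denominator degrees of freedom
   n_subjects − 2 — the between-subject test, which in a balanced design
   equals the one-way ANOVA on per-subject hemisphere means (tested to
   1e-6) and yields df = (1, 40) at 21 + 21 subjects. The duration
   association is the hyperbolic model cv = b/duration + a, fitted by OLS in
   the regressor 1/duration (`fix_b=1` gives the literal one-parameter
   reading). The median split uses the sample median of duration, at-median
   subjects falling in the short-duration group, compared by Welch's
   unequal-variance t-test. Covariate checks are Pearson correlations. No
   multiple-testing correction is applied; all p-values are reported raw.

## Synthetic cohorts

Each subject's recording is built from:

* **Two narrowband alpha sources per hemisphere.** The low-alpha source is a
  pair of grid-aligned sinusoids 0.5 Hz apart straddling the subject's alpha
  peak (drawn in 8.8–9.2 Hz), sharing one slowly varying positive envelope.
  Grid alignment means every component completes an integer number of cycles
  per 2 s epoch, so a Hann-tapered spectrum confines the source's energy to
  exactly the four low-alpha bins: band statistics then measure the planted
  modulation, not bin alignment. A second, group-neutral upper-alpha source
  (10.8–11.2 Hz, half the amplitude, its own CV drawn identically in both
  groups) fills the 10–12 Hz band — without it the upper band would be
  noise-only and so implausibly stable across subjects that even harmless
  spectral leakage would register as a spurious "upper-alpha group effect".
* **Envelope.** log-amplitude follows a stationary Ornstein–Uhlenbeck
  process with a 5 s time constant (smooth between-epoch fluctuation at the
  2 s epoch scale), mixed from a shared and a hemisphere-specific component
  (weight 0.45, giving left/right envelope correlation ≈ 0.8). The positive
  envelope is then Gaussian-smoothed (sigma 0.25 s) so its modulation
  sidebands die off before 10 Hz; otherwise a strongly modulated 9 Hz
  carrier splatters measurable sideband power into the upper band.
* **Spatial projection.** Ear-centred gains; temporal-tagged sensors carry a
  strong, gently graded gain (1.0 → 0.7 by distance rank) so every ROI
  candidate is signal-dominated in-band, other sensors a Gaussian falloff.
* **Background.** Gaussian noise with one-sided PSD ∝ 1/f^χ (default χ = 1,
  flat below 1 Hz; synthesized exactly in the Fourier domain), a per-subject
  level factor (log-sd 0.2), a 50 Hz line component, and Poisson-placed
  blink-like transients (2 Hz Gabor, 0.5 s) whose amplitude is pinned to 8x
  the recording's realized peak-to-peak so they clear any plausible flagging
  threshold. In-band alpha-to-background ratios are deliberately generous
  (~300 at the best sensor): the generator is a controlled testbed, and a
  high SNR keeps the planted CV interpretable as the measured CV.

**CV calibration.** The planted, per-subject quantity `alpha_cv_target` is
the *measured* trial-to-trial CV. The textbook lognormal link
CV² = exp(s²) − 1 maps a target to the instantaneous log-envelope variance,
but the sample CV of 90 autocorrelated, heavy-tailed epoch powers sits well
below the population CV (by 10–20% at CV ≈ 2.5–4), and additive band noise
dilutes the sample CV more than the population noise-to-signal ratio ρ
suggests (the sample mean in the denominator is typically below the
population mean). The generator therefore inverts the expected *sample* CV
directly: a seeded Monte-Carlo table (one per cohort configuration, cached)
maps (log-envelope scale, ρ) to the expected sample CV of the measured band
cells — Hann-kernel transforms of the modulated component pair plus complex
noise, with OU autocorrelation, epoch integration and random selection of
the 90 analysed epochs from the artifact-free pool (the raw epoch count
minus the expected artifact count) included — and each subject's scale is
read off at its analytically known cell ρ values. Residual calibration error is ~1–2%, worst (~2%) at the
highest targets where artifact flagging occasionally censors genuine
envelope extremes.

**Cohort structure.** 21 subjects per group; controls copy age and sex from
their matched tinnitus subject. Tinnitus durations are log-normal with
median 3 years (the median-split point), log-sd 0.6, truncated to 1–25
years. Tinnitus CV targets follow cv = b/duration + a with default
(a, b) = (2.38, 1.0) plus N(0, 0.15²) jitter; control targets sit at the
tinnitus mean plus `group_cv_delta`, with the same jitter (a literally
jitter-free control group would have zero between-subject target variance
and an ill-conditioned null model). Tinnitus alpha amplitude is scaled by
sqrt(`group_power_ratio`). Distress and age are drawn to match the reference
demographics and are independent of CV by construction.

**Planted effect sizes.** The defaults `group_power_ratio = 0.2` and
`group_cv_delta = 1.05` were chosen by power analysis against the
generator's own measured between-subject noise so that the planted
standardized effects (~0.9–1.0) reproduce the reference design's reported
F ≈ 9–10 at n = 21 + 21. They are larger than a naive reading of a "power
reduction" because two noise sources are irreducible at these study
conditions: the envelope's 5 s correlation time leaves only ~20 effectively
independent epochs for a subject's mean power, and the sample CV of 90
heavy-tailed powers carries a per-subject standard error near 1.0. The
acceptance power study plants a slightly stronger condition
(ratio 0.15, delta 1.1, planned detection ≈ 90–95%).

## Problem sizes used by the test suite and acceptance script

Replicated studies run 200 cohorts each with a thinned frame: 10 sensors
(4 temporal per side), 250 Hz, 220 s → 110 epochs, 90 analysed. The
detection-power study runs at the study's n = 21 + 21 with the calibrated
planted contrasts; the duration-model recovery study runs 200 tinnitus
cohorts (n = 21) under the default study conditions (the recovery question
concerns the CV-duration law, not the group contrast); the null-calibration
study runs 8 + 8 cohorts with no planted effect. The acceptance script runs one full-length cohort
(300 s at 678.17 Hz, analysed at 600 Hz) on a 64-sensor array; these sizes
keep a desk-scale compute budget while leaving every statistical quantity
(df, epoch accounting, bands, ROI size) at its default.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the pipeline estimates:
narrowband temporal alpha over a 1/f background, lognormal-OU power
modulation with controlled mean and CV, group offsets, a hyperbolic
duration-CV law, matched demographics, line noise and blink artifacts. It
does not emulate real MEG physics: no head model or forward solution, no
sensor-noise correlations, no heartbeat/eye-movement physiology, no
between-region connectivity, and its alpha SNR is generous. Passing tests
therefore validate the pipeline's correctness and calibration — not claims
about real tinnitus cohorts.

## Numerical choices and degenerate inputs

* Seeds: one master seed; per-subject signal/selection seeds derived by
  BLAKE2 hashing of (seed, subject id, stage); all derived seeds < 2^31.
* The calibration Monte Carlo uses a fixed internal seed (it is a numerical
  method, not study randomness); identical configs give bit-identical
  cohorts.
* CV with zero mean power at any cell raises an error naming the cell;
  selection with too few clean epochs reports the exact shortfall; CV
  targets above the calibratable ceiling raise a calibration error, targets
  below the additive-noise floor clamp to zero modulation.
* Mixed-model fits run under suppressed convergence warnings; a singular or
  non-finite group effect raises an explicit convergence error.
* ROI ties break by sensor id; the band convention is half-open [lo, hi).

## Known limitations

* Sample-CV calibration is accurate to ~1–2%; at the very highest targets
  artifact flagging can censor genuine envelope extremes (~2% downward).
* The measured CV of a 90-epoch recording has a per-subject standard error
  of order 1.0 at CV ≈ 3; single-subject CVs are noisy by construction, and
  only cohort-level contrasts are meaningfully powered.
* The F-test's n − 2 denominator df is exact for the balanced two-hemisphere
  design only; unbalanced hemisphere data are rejected rather than
  approximated.
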