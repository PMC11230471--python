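# Methods

This note documents the models implemented in `striatophot`, the
assumptions behind them, the tunable parameters and their defaults, what
the synthetic generator does and does not emulate, and the numerical
choices that make the pipeline deterministic.

## Normalization model

Both normalization chains assume the demodulated sensor and UV isosbestic
channels share two nuisance processes: slow multiplicative photobleaching
with channel-specific kinetics, and motion/coupling artifacts that enter
both channels through (instantaneously) affine gain and offset. The
sensor channel additionally carries the biological signal, which the UV
channel — excited at the calcium-independent isosbestic wavelength — does
not.

**GCaMP chain.** The sliding-percentile baseline (window 5 s, rank 10)
tracks bleaching and other slow drift; dividing by it makes both channels
dimensionless and scale-free, so multiplying both raw channels by any
constant leaves the final ΔF/F unchanged (tested). The reference is
low-pass filtered at 3 Hz (2nd order Butterworth) before the affine fit;
filtering is applied forward–backward (zero phase), because the
downstream analyses are all offline timing statistics (time of peak,
pre-offset slope) and a causal filter's group delay would bias them. The
squared magnitude response of the zero-phase filter, |H(f)|² =
1/(1+(f/fc)⁴), is verified against pure tones to 2 %.

**Robust affine fit.** The reference→signal map is fit with RANSAC around
ordinary least squares. Defaults: each hypothesis is an OLS fit on a
random half of the samples (`min_samples=0.5`), the inlier band is 3
median absolute deviations of the global OLS residuals, 50 trials, fixed
seed. Large hypothesis subsets matter: with the textbook two-point
subsets the consensus slope is noise-dominated whenever inliers dominate
the data, and we measured 5–13 % slope bias on synthetic sessions — enough
to leave a visible artifact residue in ΔF/F. Half-sample subsets make
every candidate model OLS-stable while a contaminated subset still loses
the consensus vote, so gross outliers (e.g. ±100 detachment spikes on 5 %
of samples) are rejected and the injected affine map is recovered to
better than 1e-3.

**rDA3m chain.** The dopamine chain fits the affine map on the *raw*
channels and uses the fitted trace as F (ΔF/F = (F_raw − F)/F), with no
percentile baseline — deliberately, so sustained stimulation-driven
offsets appear in ΔF/F instead of being absorbed. Here stimulation epochs
are structural outliers with large offsets (up to ~15 % of the session),
so this chain keeps the minimal-subset RANSAC (`min_samples=2`, 1 MAD,
100 trials): two clean baseline samples pin the unstimulated relation and
the stimulated samples fall outside the tight inlier band. The two chains
therefore carry separate RANSAC configurations (`ransac` and
`ransac_rdam`), both exposed.

**QC gate.** Sessions are kept when max ΔF/F exceeds 1.5 % *and* the
Pearson correlation between the final ΔF/F and the transformed UV
reference stays below 0.6. The amplitude threshold is read as ΔF/F
expressed in percent (max(dff) > 0.015); the correlation is computed
between the two traces as they exist at the end of the chain. Both
operands and thresholds are config values, so the alternative readings
are one flag away. z-scoring uses the mean and SD of the entire session;
a zero-variance trace maps to zeros rather than NaN.

## Bout segmentation

All thresholds are strict (`>`), equality falls on the sub-threshold
side, and intervals are half-open `[onset, offset)` with durations counted
in samples — this pins every boundary decision. Treadmill: threshold
0.25 cm/s; sub-threshold runs shorter than 0.8 s are absorbed into
movement (they are not rest), which follows from treating "rest" as
requiring 0.8 s; movement periods shorter than 0.5 s or with mean
velocity below 0.5 cm/s are retained but flagged `excluded`, so
movement ∪ rest ∪ excluded partitions the session (tested) and downstream
alignment simply skips flagged bouts. Sub-threshold runs touching the
session edges count as rest regardless of length, so every analyzable
movement bout has a defined onset (crossing ending a rest) and offset
(crossing followed by rest). Velocity is rectified by default (the
encoder is signed; backward walking counts as movement); a config flag
switches to signed thresholding.

Open-field ambulation merges supra-threshold runs across gaps of at most
0.5 s (runs separated by more than 0.5 s stay separate) and keeps merged
runs longer than 0.5 s; immobility applies the same logic to runs of
activity change below 2 % per frame. The activity series is abstract
(percent pixel change at the video frame rate); the package does not
decode video, and a velocity-thresholded stand-in can be declared
explicitly (`is_velocity_proxy`), which is recorded in the output
metadata.

## Peri-event statistics

Traces are decimated to a 100 Hz grid (zero-phase FIR) before alignment;
1 kHz carries no information for ~1 s indicator kernels and the coarser
grid keeps trial × time matrices small. Rows are linear interpolations at
event + relative time; events whose window leaves the session are dropped
and counted. The time of maximum uses the closed window [−1, 1] s with
ties resolved to the earliest sample (a flat trace reports −1 s); the
offset slope is the OLS slope of the trial-mean trace on the half-open
window [−0.5, 0.5) s.

Stimulation amplitudes are signed as `window_mean − baseline`, so
suppression is negative and the onset peak positive — the orientation the
one-sample left-/right-tailed tests require; a literal
`baseline − window` orientation is available behind a config flag.
Locomotion analyses use z-scored activity, stimulation analyses raw ΔF/F.

## Statistics layer

One-sample, paired and unpaired t-tests with two-, left- and right-tailed
p-values; unpaired defaults to the equal-variance (Student) form with a
Welch flag. Zero-variance inputs do not raise: the result carries a
`degenerate` flag and the limit p-value (1 for a zero effect, 0 for a
nonzero effect in the tested tail). Type-I error of every kind/tail is
calibrated to 0.05 ± 0.01 over 10⁴ null replicates. Report tables give
per-group n, mean ± SEM or median with min–max, and stars at p < 0.05 /
0.01 / 0.001. Whether rows are sessions, mice or pooled trials is the
caller's choice; the table's `n` states what was aggregated. Two-way
ANOVA is out of the tested surface.

## Synthetic sessions

The generator writes down exactly the structure the pipeline assumes,
plus ground truth for every component, and is bit-reproducible from
`(params, seed)`:

* **Bleaching** — multiplicative double exponential per channel
  (defaults: signal 0.1·e^(−t/120 s) + 0.9·e^(−t/3600 s); reference with
  different constants), applied to everything the fiber collects.
* **Motion artifacts** — sparse positive bumps (Poisson events, default
  20/min, half-normal amplitudes of SD 4 a.u. on a 100 a.u. baseline,
  Gaussian-smoothed with σ = 0.3 s), entering both channels with
  channel-specific gain/offset and scaled by each channel's bleach
  factor. The bleach scaling reflects that motion modulates coupling
  efficiency of the *current* light level; without it the true
  channel-to-channel map drifts as the channels bleach apart and no
  constant affine fit can be exact. Positive-going bumps are used because
  long negative dips corrupt a 10th-percentile baseline in a
  channel-specific, non-affine way; brief dips of either sign are still
  handled by the referencing, but the default regime isolates the
  property under test. The bump width keeps the artifact inside the 3 Hz
  reference-filter passband, as real motion artifacts of sub-second
  timescale are.
* **Transients** — difference-of-exponentials kernel (rise 50 ms, decay
  1 s), Poisson event times at 0.4 Hz during movement and 0.05 Hz at
  rest, lognormal amplitude jitter around 3 % ΔF/F.
* **Offset coupling** — `patch_like`: a within-bout plateau plus a linear
  ramp starting 0.5 s before each bout offset, peaking 0.2 s after it,
  then decaying (τ = 0.3 s); `matrix_like`: a plateau that declines
  linearly over the 0.5 s before the offset, reaching baseline at the
  offset. These produce, respectively, post-offset peak times with
  positive pre-offset slopes, and pre-offset peak times with negative
  slopes.
* **Locomotion** — alternating rest/movement epochs (shifted-exponential
  durations, means 4 s, minimum 1.2 s) or a fixed schedule; trapezoidal
  velocity with 10 ms edges so the 0.25 cm/s crossing stays within one
  sample of the (grid-snapped) scheduled boundary; rest noise uniform
  ±0.08 cm/s, far below threshold, so fixed-schedule bouts are exactly
  recoverable. Ground truth records the realized bouts.
* **Stimulation sessions** — 2/5/15 s trials, 10 per duration,
  interleaved in seeded random order with gaps of at least 45 s (gap
  violations are a parameter error); the injected response approaches the
  suppression depth exponentially (τ_on = 0.5 s), relaxes back after
  offset (τ_off = 0.8 s), with optional Gaussian onset peak (+0.4 s,
  σ = 50 ms) and post-offset rebound (+5 s, σ = 1 s). The signal is the
  affine image of the clean reference modulated by (1 + response), so the
  injected response *is* the ground-truth ΔF/F.

What the generator does not emulate: hemodynamic contamination,
indicator nonlinearity and saturation, spike-to-fluorescence dynamics,
wavelength crosstalk, slow sensor rundown distinct from bleaching, and
real video. Passing tests therefore show the pipeline recovers the
stated structure under its own model assumptions — they do not certify
performance on pathologies outside that model.

## Validation studies and problem sizes

The studies in `scripts/acceptance.py` and the test suite use desk-scale
sizes chosen as follows: treadmill sessions 240 s and artifact-removal
sessions 600 s at a 100 Hz grid (artifact-removal sessions are longer
because the chance correlation between independent smooth processes
scales as 1/√(T·bandwidth) and at ≤ 120 s that floor alone exceeds the
0.1 criterion; real sessions of this kind run ~30 min); cohorts of 7
sessions per profile, 20 replicates; 20 stimulation sessions per
condition with the full 30-trial protocol at 100 Hz; 10⁴ null replicates
per t-test variant; percentile-oracle traces up to 10⁴ samples. The
full-rate 1 kHz path is exercised by the filter tests and works
unchanged; only session length and grid density are scaled.

## Known limitations

* The percentile baseline reacts to any structure that occupies the lower
  tail of a 5 s window (long negative artifacts, dense pauses in
  activity); this is a property of the published normalization itself,
  not of this implementation.
* The QC correlation operands and the amplitude-threshold unit follow one
  reading of the inclusion rule (final ΔF/F vs transformed reference;
  percent units); both are configurable.
* `segment_immobility` trusts the caller's activity series; no pixel
  processing is performed.
* Open-field tracking at video rate is handled by linear interpolation to
  the common time base before thresholding; sub-frame bout boundaries are
  therefore approximate at the frame scale.
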