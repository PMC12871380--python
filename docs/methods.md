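# Methods

## The measurement problem

Dual-modal release imaging records the same field of view through two
fluorescent dopamine sensors with very different affinities. The
high-affinity sensor (visible band, GRAB-type) is so sensitive that it
saturates at the low concentrations reached by volume transmission, so
it reports *that* release happened essentially everywhere in the field.
The low-affinity sensor (near-infrared nanosensor) responds linearly in
the relevant range, so its signal is confined to the high-concentration
neighbourhoods of actual release sites. The pipeline quantifies both
channels the same way and lets the contrast between them map release
hotspots.

## ΔF/F and preprocessing

All normalization is `ΔF/F = (F − F₀)/F₀`. Two baseline conventions are
used, matching the two experiment types:

- **pre-stimulus mean** (`dff_prestim`): F₀ is the mean of the
  `baseline_frames` frames immediately preceding the stimulus frame.
  Used for evoked-release movies.
- **trial median** (`dff_median`): F₀ is the median of the whole trial.
  Used for spontaneous-activity recordings, where there is no defined
  pre-stimulus epoch.

Both are invariant to multiplicative gain, which is what makes the
downstream SD-based criteria gain-invariant.

Slow decays (common in the first 30–60 s of nanosensor recordings) are
removed by fitting `a₁e^(−t/τ₁) + a₂e^(−t/τ₂) + c` by least squares and
subtracting only the decaying part, so the plateau level is preserved.
The model includes the constant term deliberately: fluorescence decays
to a plateau, not to zero, and subtracting a no-offset fit would destroy
the baseline. The fit is multi-started over τ pairs from {5, 20, 80} s
(τ bounded to [0.5 s, 10 × trace duration]) and the best RMSE start
wins; on total non-convergence the input is returned unchanged with
`rmse = ∞` and `converged = False` rather than raising, so batch
pipelines degrade gracefully. Whether a given trace *needs* detrending
is left to the caller via a flag — there is no reliable automatic
criterion for "exhibits a decay", and guessing would silently alter
data.

Low-pass filtering is a third-order Butterworth at 0.68 Hz by default,
applied forward–backward (`sosfiltfilt`). Zero-phase filtering is a
deliberate choice: causal filtering would delay wave peaks and bias
every triggered average. The forward–backward pass squares the
magnitude response, so the half-power point of the design becomes an
amplitude of exactly 0.5 at the cutoff — the tests assert this against
the analytic response. The default pipeline order is ΔF/F → detrend →
filter; the operations are independent functions, so callers can
reorder.

## Hotspot calling

The field is tiled with `grid_px × grid_px` squares (8 px default;
partial edge squares are dropped rather than padded, because
partially-filled squares would have different noise). A 152×152-px
analysis field therefore gives 19×19 = 361 squares. Per square, the
spatially averaged trace is normalized per stimulus repeat against that
repeat's pre-stimulus baseline and windowed to
`[stim − baseline_frames, stim + response_frames)`.

A square is **active** when the peak ΔF/F of the across-repeat mean
trace over the response window exceeds

    baseline mean + roi_threshold_sd × baseline SD,

where the baseline statistics are pooled over the *per-trial*
(unaveraged) baseline samples — the trace's baseline activity. This
split is the crux of the criterion's statistics:

- With a single trial, the activation probability of a pure-noise square
  is the closed form `1 − Φ(k)^W` (k the SD multiplier, W the response
  window length): ≈ 20.6% at k = 2, W = 10. A single-trial 2-SD rule is
  therefore a *mapping* statistic, not a detector.
- With R repeats, the mean trace's noise shrinks by √R while the
  threshold (single-trial SD) does not, so the effective threshold is
  k√R SDs: ≈ 0.3% false positives per square at R = 3. Repeat averaging,
  not the threshold, is what buys specificity.

Both regimes are asserted in the acceptance tests: the closed-form
false-positive rate on single-trial noise (within binomial 99% bounds
over 20 seeds), and ≥95% site sensitivity with ≤2% false-positive
squares on rendered three-repeat scenes, aggregated over 20 seeds.

Squares with exactly zero baseline SD (noiseless synthetic input) fall
back to `active ⇔ peak > baseline mean`. The response window default is
10 frames (≈ 6.8 s at 1.47 fps), wide enough to cover the evoked
transient; `baseline_frames` defaults to 15 (≈ 10 s).

Condition comparisons report active counts, the fractional reduction
`(pre − post)/pre` (undefined, not zero, when the pre count is zero) and
per-square peak differences. Sensor-amplitude comparisons are ordinary
least squares with R² plus the ratio of means, which carries the
orders-of-magnitude amplitude contrast between sensors.

## Events and triggered averages

Spontaneous events are strict local maxima of the z-scored trace
(whole-trace mean/SD — no sliding window, keeping detection affine
invariant) with z > 3, merged greedily in descending z order until all
survivors are ≥ 10 s apart; plateau ties resolve to the earliest frame
so detection is deterministic. Triggered averages use
`round(window_s × fps)` samples (60 s default) centered on the frame
*prior to* the event or puff frame; events whose window would leave the
trace are dropped and counted, never padded, since padding would bias
the mean. The response amplitude is `post_peak − pre_peak`, each peak
being the mean over `peak_win_s` (3 s; 0 disables smoothing) centered on
the maximum of the corresponding 10-s window, clipped to that window.

## Axial FWHM

z-stacks are reduced to a per-slice statistic (mean by default — a
uniform thin film fills the field; max available for bead-like
samples). Background is the mean of the lowest-decile slices —
appropriate for stacks with flat dark tails; heavy-tailed (Lorentzian)
profiles need a z range several times the FWHM for this estimate to be
unbiased. Half-max crossings are located by linear interpolation between
the bracketing samples walking outward from the peak; a profile whose
peak sits at the stack edge, or that never falls below half-max on one
side, raises an error naming the side.

## The simulator

The generator produces the statistical structure the analysis assumes,
with known ground truth.

**Release scenes.** Release sites occupy whole grid squares with peak
concentration 1 (normalized units). Each stimulus evokes
`c(t) = (1 − e^(−t/τ_rise))·e^(−t/τ_decay)` (τ_rise = 0.3 s,
τ_decay = 2 s), unit-peak normalized and summed over stimuli. Diffuse
"spillover" is an isotropic Gaussian blur (σ = 30 px) of the site map,
rescaled so its spatial maximum is `spill_gain` = 0.002 site-peak
units: large enough that the high-affinity sensor responds strongly at
every pixel, ~10× below the low-affinity channel's per-square noise SD.
Spillover as a single blurred field is the simplest surrogate for
diffusion that produces the everywhere-active saturating channel; it
has no kinetics of its own.

**Sensors.** `ΔF/F = dff_max·cⁿ/(Kdⁿ + cⁿ)`, then causal convolution
with a normalized mono-exponential reporter kernel (unit DC gain).
Defaults: high affinity Kd = 0.01, dff_max = 0.9, τ_off = 0.3 s; low
affinity Kd = 10, dff_max = 0.15, τ_off = 1 s (the near-infrared sensor
decays more slowly). These Kd values are working values chosen to place
the two sensors firmly on the saturated and linear limbs of the
dose–response curve — published affinities for the real sensors are not
encoded here. Fluorescence is `baseline_f·(1 + ΔF/F)` (baseline 100)
with additive Gaussian noise (SD 0.3 per pixel per frame); PMT movies at
these intensities are near-Gaussian and the activity criterion is
variance-based, so Poisson noise would change nothing structurally. At
these defaults the nominal per-square SNR of the low-affinity channel
(peak site ΔF/F over per-square noise SD, accounting for frame sampling
and the reporter kernel) is ≈ 20. An optional multiplicative
double-exponential bleach and a perturbation variant (seeded random
site survival with amplitude scaling) complete the scene model.

**Waves.** The calcium channel is a sum of Gaussian wave templates
(σ = 2 s) at frame-aligned, seeded, evenly spaced times; the
near-infrared channel carries a causal release transient per wave
(rise 2 s, decay 6 s, starting `lag_s` after the wave peak) scaled by
`coupling_scale`, plus independent noise and an optional initial decay
for detrending tests. The transient is causal — zero before its
trigger — because the pre/post peak-difference amplitude presumes no
signal in the pre-trigger window; a symmetric template would leak into
it and understate the coupling by construction.

**z-stacks.** Per-slice intensity follows a Gaussian
(FWHM = 2√(2 ln 2)·σ) or Lorentzian (FWHM = 2·HWHM) of requested width,
centered in the stack, with optional per-pixel noise.

All generators are bit-reproducible for a fixed seed.

## What the synthetic tests do and do not show

The simulator reproduces hotspot geometry, the two-affinity contrast,
stimulus kinetics, noise and bleaching — the features the estimators
consume. It does not model diffusion kinetics, vesicular release
stochasticity, sensor photophysics beyond a mono-exponential, motion,
or correlated (shot/row) noise. Passing tests therefore validate the
*estimators* under the assumed statistical structure; they do not
certify performance on tissue data, where baseline non-stationarity and
correlated noise can raise the effective false-positive rate of the
SD criterion.

## Problem sizes

The validation suite uses 152×152-px, 135-frame scenes (three stimulus
repeats) at 20 seeds for the recovery study; 19×19-px single-trial noise
movies with 500-frame baselines for the false-positive calibration (the
closed form assumes known baseline statistics, so the baseline window is
made long enough that estimation error is second-order); 50 random
traces for the event-detection guarantees; and 151-sample axial
profiles. These sizes make every distributional check well-resolved
while keeping the full suite around a quarter of a minute.
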