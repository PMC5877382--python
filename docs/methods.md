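# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from external
measurements.

## Conventions

Quaternions are stored scalar-first `(w, x, y, z)` with the Hamilton
product. A quaternion `q` maps body-frame vectors to the navigation
frame, `v_nav = q (0, v_body) q*`; passively it is the frame rotation
from global to body. Under this convention the kinematic equation driven
by the body rate is `q̇ = ½ q ⊗ (0, ω)`. Angular I/O is in degrees
(deg/s for rates), internal math in radians; displacement I/O is in mm,
acceleration in m/s². The navigation frame has z up (gravity-aligned)
and no absolute heading — there is deliberately no magnetometer anywhere
in the chain.

Every `QuatSignal` is normalized and made sign-continuous at
construction (`dot(q_k, q_{k-1}) ≥ 0`), because the finite-difference
angular-velocity recovery is meaningless across a `q → −q` jump.

## Orientation (complementary AHRS)

Per sample: first-order gyro integration with renormalization, then a
tilt-only correction that rotates the estimate toward the
accelerometer-implied gravity direction about a horizontal axis by a
fraction `accel_gain` of the tilt error. Yaw is never corrected; heading
drift is accepted and removed downstream by per-stride axis estimation.
The integration uses the first-order Euler form (the exponential-map
integrator would be more accurate per step but the first-order form is
the documented baseline, and at 200 Hz the difference is far below the
other error sources).

`accel_gain` defaults to 1e-4 per sample at 200 Hz. This sets an
equilibrium trade-off: a constant horizontal gyro bias `b` produces a
steady tilt error of `b / (gain · fs)`. At the default gain the filter
therefore assumes a startup-calibrated gyroscope (residual bias
~0.01–0.02 deg/s, giving <1° tilt error); with larger biases the gain
must be raised accordingly. Samples with `|acc| < 0.5 g` (free fall /
impact) skip the correction; gap samples hold the orientation
(zero-rate prediction). Initialization takes the first usable
accelerometer sample's gravity direction with yaw 0.

## Filtering

Noise removal is a 4th-order zero-phase Butterworth low-pass at 30 Hz
(well above the ~3–4 Hz band of interest at twice the stride frequency).
Drift removal for the doubly integrated vertical displacement is a
4th-order zero-phase high-pass at 2/3 of the stride frequency, where the
stride frequency is the reciprocal of twice the median inter-peak
interval of the displacement, always measured at the sacrum and reused
at all locations. With the default gait configurations the derived
cutoffs fall at ~0.57 Hz (walk) and ~0.85 Hz (trot).

Zero-phase (forward–backward) filtering is used everywhere so filtering
never shifts events relative to the synchronization. Edge transients are
handled by odd-reflection padding of 3× the filter kernel length. Gaps
shorter than 5 samples are linearly bridged and re-masked; longer gaps
split the signal into independently filtered segments. Note the
high-pass also attenuates the once-per-stride asymmetry component a few
percent (it sits at only 1.5× the cutoff); this is an inherent property
of the stride-tuned drift-removal design, visible as a slight (<5%)
shrinkage of injected peak differences.

## Synchronization and alignment

The lag between the inertial and optical streams is the maximizer of the
Pearson correlation between the two angular-velocity magnitude traces
(magnitude is invariant to the unknown inter-system rotation), refined
below one sample by a parabola through the peak and its two neighbours.
Gap samples are excluded pairwise at every candidate lag via masked
FFT cross-correlations. Clock skew is assumed negligible. Measured
accuracy on the package's own benchmark (60 s, ≤10 Hz content, 200 Hz,
SNR 20 dB, fractional-sample lags): 95th-percentile error ≈ 0.1–0.2 ms.

One caveat specific to synthetic data: prescribed-kinematics trials are
exactly periodic, so the correlation has near-equal peaks at lags one
stride period apart. The pipeline's default search window is therefore
±0.5 s (`sync_max_lag`), i.e. the systems are assumed started within
half a second of each other. Real recordings contain aperiodic content
(speed changes, turns) that removes the ambiguity.

Time shifting uses: pure index shift for integer-sample lags; an
even-reflection frequency-domain fractional delay for gap-free signals
(accurate to <1e-6 of signal range in the interior; edge samples are
masked); linear interpolation as the gapped fallback; spherical linear
interpolation for quaternions.

The fixed IMU-body → optical-rigid-body rotation is the Kabsch solution
(centroid subtraction, SVD of the cross-covariance, determinant
correction) on per-time-paired 3-D angular-velocity samples. The implied
translation absorbs gyro bias and is discarded. Periods where the
windowed variance (10 samples, sliding, centred) of the two magnitudes
disagrees are excluded; the literal default threshold of 1e-3 (deg/s)²
is meaningful only for near-noiseless signals, so the pipeline guards it
with `max(threshold, 10 × median |Δvariance|)`, which still removes
occlusion spikes but keeps ordinary samples at realistic noise.

## Stride events

The timing reference is always the IMU (one segmentation shared by both
systems). The baseline detector marks stance candidates where the
moving-average-smoothed (50 ms boxcar — an FIR is used precisely because
zero-phase IIR smoothing rings around impact transients) angular-velocity
magnitude stays below 20 deg/s for ≥80 ms, then refines the region start
backwards and the region end forwards (≤0.2 s) to the nearest
acceleration-magnitude impact peak. Regions touching the record
boundaries are dropped. All thresholds are configuration. The detector
is a deliberately simple baseline behind a pluggable interface — any
callable `imu -> (hoof_on_times, hoof_off_times)` can replace it — and is
validated only on synthetic data with known events (worst-case error
there ≈ 2.4 ms; see limitations).

Mid-stance (50% of stance, snapped to the nearest sample so both systems
use the identical index) is the zero-angle reference for limb angles.

## Limb angles

Per stride: the rotation between hoof-off and next hoof-on orientations
`qr = q_on ⊗ q_off*` is decomposed about global z (swing–twist); the
residual swing's axis is horizontal and perpendicular to the sagittal
plane of that stride. This removes heading per stride — a fixed yaw
applied to the whole trajectory changes nothing (tested to 1e-6 deg).
The coronal axis is the sagittal axis rotated +90° about z, mirrored for
left-side limbs so outward tilt (abduction) is positive on both sides.
Sign of protraction is positive automatically because the axis is
oriented by the actual swing direction.

Each sample's orientation relative to mid-stance,
`q_rel(t) = q(t) ⊗ q*(t_mid)`, is swing–twist-decomposed about the
sagittal and coronal axes; the twist angles are the angle signals. They
are exactly zero at mid-stance by construction; after the optional 30 Hz
zero-phase denoising the per-stride mid-stance value (≲1e-3 deg) is
subtracted back out so the invariant holds exactly. Strides with >25%
gap samples are skipped and reported. A stride with no measurable swing
falls back to fixed horizontal axes (angles ≈ 0, which is also the
physically correct answer for no motion).

Parameters per stride: protraction = sagittal at hoof-on, retraction =
sagittal at hoof-off, abduction/adduction = coronal extrema over the
full stride (full stride rather than swing-only: the choice is
ambiguous in the source description; stance coronal motion is near zero
so the difference is negligible), sagittal ROM = |protraction −
retraction|, coronal ROM = abduction − adduction.

## Vertical displacement and symmetry

Navigation-frame vertical acceleration (gravity removed) is doubly
integrated with cyclic drift suppression: before each integration step
(acc→vel, vel→disp), each stride's samples have the mean over the
previous/current/next stride subtracted ("current and adjacent"
three-stride centred mean; first/last strides use the neighbours that
exist). At least 3 complete strides are required. The displacement then
passes the stride-tuned high-pass and the 30 Hz denoiser.

Within each stride window the two most prominent peaks and the two most
prominent troughs are kept in temporal order (prominence via standard
peak finding, 0.1 s minimum separation; "two most prominent" is this
package's rule for noisy extrema). Upward ranges pair each trough with
the following peak, downward ranges each peak with the following trough
(cyclically within the stride, anchored at the reference limb's
hoof-on). Symmetry parameters: `min_diff = Min1 − Min2`,
`max_diff = Max1 − Max2`, range differences likewise, and the symmetry
index `SI = (R1 − R2) / max(R1, R2)` per direction — 0 for perfect
symmetry, ±1 when one range vanishes, undefined (NaN) when both are
zero.

## Agreement statistics

Bland–Altman: differences `a − b` against pair means; bias; limits of
agreement at bias ± 1.96 SD. Because strides repeat within subjects, the
SD combines one-way ANOVA variance components (between-subject +
within-subject) rather than treating strides as independent; confidence
intervals for bias and LOAs follow the delta method on those components
(single-subject data falls back to the naive formulas with a warning).
`trial_mean` level averages within (subject, trial) first — which is why
trial-mean LOAs are systematically narrower than per-stride LOAs, a
dilution effect the structural test verifies.

ICC: one-way random-intercept model with subject as the grouping factor,
variance components by REML (exact restricted likelihood reduced to
group sufficient statistics, maximized numerically; equals the ANOVA
estimator on balanced data). `ICC = t00 / (t00 + σ²/nj)` with `nj` the
mean group size for unbalanced data, clipped to [0, 1]. Three response
modes exist: `stacked` (default in the agreement tables: both systems'
values as repeated measurements per subject — high when horses separate
cleanly relative to stride and system scatter), `difference`, and
`mean`. The difference response answers a different question (does the
*disagreement* vary by horse) and approaches 0, not 1, for perfectly
agreeing systems.

## Synthetic gait simulator

Kinematic (prescribed-trajectory) simulation — no force model — because
the pipeline consumes kinematics only. Per limb, the sagittal cannon
angle starts at the configured protraction at hoof-on, transitions to a
quiet vertical plateau over the first 15% of stance, descends to the
configured retraction over the last 15%, and swings back smoothly
(cosine arcs, C¹ at events, extrema exactly at the events). The coronal
angle is a low-amplitude C¹ lobe confined to the swing. Limb phase
offsets follow a lateral-sequence walk (0, ¼, ½, ¾) and a diagonal trot.
Defaults: walk 0.85 strides/s, duty 0.6, ±25° sagittal; trot
1.275 strides/s, duty 0.4, ±30°; chosen so the derived high-pass cutoffs
land at 0.57 / 0.85 Hz. The upper body oscillates vertically twice per
stride (40 mm default range); asymmetry is injected as first-harmonic
terms that shift the two peaks apart by a configured `max_diff` and the
two troughs by `min_diff` while leaving the other pair untouched (the
waveform is parameterized directly by what the symmetry module
measures, making recovery well-posed).

The ideal gyroscope is the numerical derivative of the truth
orientation — so integrating it reproduces the truth to round-off — plus
constant bias and white noise (defaults 0.01–0.02 deg/s bias,
0.2 deg/s noise). The ideal accelerometer is rotated gravity (plus the
vertical second derivative for the upper body and short Gaussian impact
transients at limb hoof events), plus white noise (0.05 m/s²). The
optical stream is the truth re-expressed in a yaw-rotated room frame
with the rigid-body frame rotated from the IMU body frame by a
configurable fixed mounting rotation (default 35° about a near-vertical
axis), delayed by a configurable lag, with 1.9 mm position noise, 0.3°
orientation noise, and Poisson occlusion gaps. Everything is
deterministic under the seed.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: soft-tissue artifact, hoof-impact
saturation and high-g content, stride-to-stride timing and amplitude
variability, turns and speed changes (trials are exactly periodic),
optical marker-model errors beyond white noise, and any real lameness
mechanics. Event-detection accuracy in particular is only demonstrated
for signals with a genuinely quiet stance plateau; the production
replacement for the baseline detector plugs into the same interface.

## Problem sizes

The test suite uses 8–25-stride trials for most checks, 200-stride
trials for limb-parameter recovery, 50 strides for asymmetry recovery,
n = 10⁴ for Bland–Altman coverage, and a 7-subject × 2-gait × 6-stride
experiment for the structural agreement test. `scripts/acceptance.py`
runs 100 seeded 60 s synchronization trials. These sizes give stable
statistics while keeping a full run in minutes on one core.
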