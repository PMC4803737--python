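# Methods

This note documents the models implemented in `wearkin`, the conventions and
parameter choices they rest on, what the synthetic generators do and do not
emulate, and the numerical decisions that matter for reproducing results.

## Conventions

All frames are right-handed.  The sternum (body) frame has z up along the
craniocaudal axis, x antero-posterior (forward), y lateral.  Quaternions are
stored scalar-first `(w, x, y, z)`; `scipy.spatial.transform.Rotation` is used
internally with the appropriate reordering.  Files are comma-delimited UTF-8
with a mandatory header whose first column is `time_s`; floats are written at
full `repr` precision so write→read round-trips are loss-free to 1e-9.
Sampling must be uniform: each step may deviate from 1/rate by at most 1 ns.

Arm angles: ψ (abduction) is the angle of the humerus axis from the downward
craniocaudal axis; θ (horizontal flexion) is its azimuth about the
craniocaudal axis measured from the frontal plane.  θ = 0° keeps the arm in
the frontal plane (pure abduction); θ = 90° is sagittal flexion.  The rest
humerus axis in the arm-segment frame is −z, so (θ, ψ) are read off
`R_sternumᵀ·R_arm·(0,0,−1)`; θ is set to 0 at the ψ = 0 pole where the
azimuth is undefined.  With this convention the two calibration movements lie
exactly on coordinate planes.

## KPF sensors

Single layer: R = l²ρ/V₀ − (ρ/d)·Δα.  The curvature-squared remainder is
omitted — it matters only near cusps, which body-shape sensing does not
produce — and the scapular strain sensor defaults to Δα = 0, using the
piezoresistive term alone.  Thickness under strain is not modelled; the rest
thickness enters only through V₀.

Two-point calibration solves Δα = c₁ΔR + c₂ through both bench poses exactly.
A calibration with c₁ = 0 (equal angles) is rejected as degenerate even
though the defining formula allows it: the map cannot be inverted to measure
angles.

Characterization uses the *population* SD (divisor P) per stimulus level, a
deliberate match to the bench procedure that averages a fixed set of repeated
cycles.  The sensitivity is the OLS slope through the per-level means (the
bench procedure states a linear approximation without naming the fit; OLS on
level means is the minimal choice, and whether the original fit used
per-trial points is unknowable — with balanced repetitions the two coincide).
The goniometer's equivalent angular error is σ_max/|S|; with the bench values
S = 955 Ω/° and σ_max = 5100 Ω this is 5.34°, i.e. 5.3° at one decimal.

## Shoulder models

**Socket-ball**: trochlea at p = p₀ + L·d(θ, ψ) with a fixed gleno-humeral
(GH) center p₀ and humerus length L.  ‖p − p₀‖ = L identically.

**Bi-articular**: the GH center itself moves.  Each planar movement has an
elliptic arc anchored at p₀: displacement b(1−cos φ)·ĥ + a·sin φ·ẑ, with
signed semi-axes (a vertical, b along the in-plane horizontal ĥ) and phase
φ ∈ [0, φ_max].  The scapular strain channel drives the phase, φ = g·(s−s₀),
clipped to [0, φ_max]; at the rest reading s₀ the model coincides with the
socket-ball map everywhere, and humerus length is conserved exactly
(‖F(θ,ψ,s) − c(s,θ)‖ = L).

For azimuths between the two identified planes the arc plane is rotated about
the craniocaudal axis (ĥ sweeps from y to x) and (a, b, φ_max) are
interpolated linearly in w = clip(θ/90°, 0, 1).  This "rotating-arc" blend
was chosen over a pointwise linear interpolation of the two arcs because it
keeps the blended center path a genuine elliptic arc at every azimuth and
reduces exactly to the identified planar arcs at θ = 0°/90°.  Whether the
underlying center surface is truly a 3-D ellipsoid or two planar arcs is not
decidable from planar calibration data; the two-arc reading is the minimal
model consistent with it.  The strain→phase map is taken linear, consistent
with the linear electromechanical characteristic of the KPF strain sensor.

The end effector is the trochlea; a `rescale` factor scales positions along
the arm axis to full hand reach (arm ≈ 0.8 m vs trochlea ≈ 0.3 m).

**Identification** is a joint nonlinear least squares over both calibration
movements with unknowns (L, p₀, a_f, b_f, a_s, b_s, g, s₀), solved with
`scipy.optimize.least_squares` (xtol = ftol = gtol = 1e-14, per-parameter
scaling by the socket-ball length scale).  Initialisation: p₀ and L come from
the *linear* least-squares socket-ball fit (p = p₀ + L·d is linear in both),
arcs start at 2 cm, g at 1/strain-span, s₀ at the lowest-elevation reading.
φ_max per arc is set afterwards from the largest phase reached during
calibration.  Model comparison guards the degenerate case: when the
bi-articular fit does not improve on the socket-ball residual (e.g. data
generated by a fixed-center joint, or a constant strain channel), the arcs
collapse to a point and g is zeroed, so the identified map *is* the
socket-ball model.  Identification is scale-equivariant: scaling all gold
positions by λ scales L, p₀ and the semi-axes by λ.

A note on identifiability: the product of g with the semi-axes (the initial
center velocity per Ω) is well conditioned, while g and (a, b) individually
trade off along a weakly constrained direction; with 2 mm gold noise on the
default movements, L is recovered to ≲0.2% and semi-axes to several percent,
and the reconstruction error — the quantity that matters downstream — stays
at the noise scale.

**Reach discrimination**: elevation epochs are contiguous runs with
ψ ≥ 30° lasting ≥ 0.5 s.  Within an epoch, EMG is active when the
MVC-normalized envelope exceeds 10% MVC, the scapula is active when the
strain excursion from its out-of-epoch baseline exceeds 3× the baseline SD
(floored at 1 Ω).  EMG activity labels the epoch physiological even when the
scapula also moves, since a normal scapulohumeral rhythm coexists with
deltoid drive; scapular activity without EMG is compensatory; neither is
inactive.  The defaults are configuration, not physiology: the discrimination
is demonstrated graphically in the source experiments and no numeric
thresholds exist to inherit.

## EMG pipeline

Order of operations is fixed: mean subtraction → 10 Hz high-pass → 300 Hz
low-pass (2nd-order Butterworth each) → rectification → MVC normalization →
6 Hz envelope.  All filters run forward-backward (`sosfiltfilt`): the
analyses are offline, zero phase keeps envelopes aligned with kinematics, and
corner frequencies are kept at their printed values, so each stage's
magnitude response is squared.  The default sampling rate is 1000 Hz (the
300 Hz low-pass requires fs > 600 Hz; the source protocol does not state the
rate).  The MVC level is located by the fixed 2 s/6 s/2 s protocol timing
rather than by thresholding, and is the maximum active-window RMS over
trials.  SNR uses the complete baseline trial and base-10 logarithms (dB
convention).

## Gait redundancy

The knee angle from the IMU pair is the rotation-angle magnitude of
R_thighᵀ·R_shank (0° at full extension).  For a hinge joint this equals the
flexion angle about the medio-lateral axis; unlike a single Euler component
it is invariant to a constant mounting rotation applied identically to both
sensors, which is why it was chosen.  It is unsigned, adequate for a joint
that does not hyperextend in these tasks.

X and σ are the rectangle-rule discretizations of the time-averaged mean and
RMS of θ_IMU − θ_g over the analysis window (so σ ≥ |X| always, by
Cauchy–Schwarz).  The equivalence test is a one-sample Student t-test of the
difference against zero.  Consecutive samples of a movement trace are
strongly autocorrelated and a full-rate test badly inflates rejection; the
difference is therefore decimated to one sample per 0.5 s by default
(`decimate_s`), which restores the nominal 5% type-I rate under independent
noise.  Full-rate testing remains available (`decimate_s=None`) and is the
right choice when the per-sample noise is known to be independent.
Zero-variance differences are handled by convention: identically zero →
verified with t = 0; constant nonzero → t = ±∞, not verified.

## Grasp classifier

Pose templates are per-dimension means and population SDs; SDs are floored at
0.5° (angles) and 0.1 N (force) so that degenerate training (repeated
identical poses) cannot create zero-volume ellipsoids.  Membership:
Σ((x−μ)/(k·σ))² ≤ 1 with k = 3 and inclusive boundary.  For a sample drawn
from its own template this statistic is χ²_d/k², so the self-containment
probability is P(χ²_d ≤ k²) ≈ 0.971 for d = 3, k = 3 — the oracle the tests
check against.  Overlapping ellipsoids are resolved by the smallest
normalized distance, which reduces to the plain membership rule when
ellipsoids are disjoint.  The force channel enters the R⁴ classifier raw (in
newtons); the three-level discretization (<1 N zero, 1–10 N inclusive low,
>10 N high) is a separate interaction indicator, not a classifier input.

## Synthetic bench

Generators are pure functions of (configuration, seed), all randomness from
`numpy.random.default_rng`.

*Shoulder*: both planar movements ramp 0→max with a half-cosine profile over
6 s at 100 Hz (601 samples each).  The scapulohumeral rhythm is a constant
ratio: the scapular phase is `split·ψ`, with split 0.4 for abduction (60° of
scapular rotation over 150°, the classical kinesiology split) and 0.5 for
flexion (60° over 120°).  Arc semi-axes default to (5, 3) cm frontal and
(4, 2.5) cm sagittal — centimetre-scale humeral-head excursion; the strain
channel gains 85 Ω per scapular degree around a 1000 Ω rest reading (the ΔR
scale of the KPF bench, ≈5100 Ω over a full movement).  IMU pairs are exactly
consistent with the generating angles before noise; noise defaults are 0.5°
orientation wobble, 25 Ω strain, 1 mm gold standard.  The socket-ball
reconstruction error of this world equals the arc-chord length at full
elevation and grows monotonically with it — the qualitative model-comparison
shape — and `rhythm_split=0` collapses the world to a socket-ball joint.

*EMG*: 20–250 Hz band-limited Gaussian noise with schedule-stepped amplitude.
This reproduces envelope- and SNR-level behaviour but is not a motor-unit
model: no firing statistics, no spectral compression with fatigue, no
electrode artefacts.  Tests passing on it say nothing about decomposition-
grade processing, which the pipeline does not attempt.

*Gait*: knee profile amplitude·sin²(πt/T) (0° at full extension), thigh
identity, shank rotated about y by exactly the profile; the goniometer
channel adds configurable bias and iid noise.  Real goniometer error is
autocorrelated and hysteretic; the iid model is what makes the decimated
t-test calibration interpretable, and is the reason the null-rate acceptance
band is a property of the procedure rather than of any specific recording.

*Grasp*: Gaussian clusters at the template means; grips 2 and 7 (pulp and key
pinch) share identical angle means and differ only in index force (0.2 N vs
12 N), exercising the R³→R⁴ disambiguation.  The force dimension is clipped
at 0 N (an FSR cannot read negative force); force SDs are kept small relative
to the means so the clipping is negligible for the statistics under test.

## Problem sizes

Default test and acceptance runs use: 601 samples per calibration movement;
20 000 draws for containment estimates; 2000 replicates (4 strides at 100 Hz
each, decimated to 8 test samples) for the null-rate calibration and 100
replicates of 500 full-rate samples for the power check; 4 s tones for filter
responses.  These sizes put Monte-Carlo error comfortably inside the asserted
tolerances while keeping the full suite in seconds.

## Known limitations

- Elbow/wrist kinematics, 7-DoF arm chains, and magnetic-disturbance
  compensation inside the IMUs are out of scope; segment orientations are
  inputs.
- The published error tables for the shoulder comparison and the per-activity
  t/p cells derive from unreleased optical-lab recordings with unstated
  sample counts; this package reproduces the procedures and their qualitative
  orderings, not those numeric cells.
- Hysteresis, aging/washing, and transient response of KPF sensors are
  characterized upstream but not modelled here.
- The compensatory/physiological thresholds are defaults to be tuned per
  subject; only the decision structure is fixed.
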