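# Methods

## Scope and model structure

`ankledyn` estimates the sagittal ankle joint moment during sit-to-stand
(STS) by two independent routes and quantifies their agreement. The
forward route is neuromusculoskeletal: sEMG → activation → Hill-type
muscle forces × via-point moment arms → moment. The inverse route is
mechanical: segment kinematics + chair reaction force → four-segment
rigid-link dynamics → moment. Both operate on a single subject model
(anthropometry, muscle constants, muscle paths, MVC constants).

## Subject model and scaling

The reference subject (73 kg, 1.70 m, 10-kg waist load) is shipped as a
YAML config. Segment lengths are stature percentages (foot 14.77 %,
shank 23.86 %, thigh 28.13 %, HAT 50.17 %) and segment masses are
body-mass percentages (3.6/10.6/22.7/63.1 %); COM factors k_i and
inertias J_i are fixed per segment. Other subjects are produced by
isometric scaling: all lengths (segment lengths, fiber/tendon lengths,
path coordinates, knee-frame offset) scale with the stature ratio, peak
forces and masses with the body-mass ratio, inertias with
mass × stature². This is the simplest dimensionally consistent rule;
pennation angles, COM factors and MVC constants are scale-invariant.

The waist load is worn above the hip, so it is added to the HAT segment
mass m₃ and to the total weight G = (body mass + load)·g, with
g = 9.81 m/s². The foot segment's parameters are stored for completeness
but do not enter the moment expression, which involves only shank, thigh
and HAT.

## EMG processing

Raw sEMG (1000 Hz, mV) is band-pass filtered with a 4th-order zero-phase
Butterworth (default 20–450 Hz, configurable) and full-wave rectified.
The envelope is the RMS over contiguous, non-overlapping 0.05-s windows
(50 samples; a trailing incomplete window is discarded; window centres
form the 20-Hz grid every downstream forward-path quantity lives on).
Activation is linear: a = RMS/RMS_MVC, clipped to [0, 1] — values above
MVC are saturated rather than propagated. No electromechanical delay or
nonlinear activation shaping is applied. The per-muscle RMS_MVC values
in the shipped config are plausible surface-electrode magnitudes
(0.35–0.5 mV); MVC calibration is an input, not something the package
derives.

The RMS of N independent noise samples has relative standard error
≈ 1/√(2N) ≈ 10.7 % per window at N = 50; this, plus a small pass-band
loss from filtering (the synthesis band and the analysis band coincide,
so the carrier is attenuated only at the band edges), bounds how well
any windowed estimator can track an envelope.

## Hill muscle-tendon model

Three fitted dimensionless curves define the contractile behaviour: a
five-Gaussian active force–length curve, an exponential passive curve
2.342·10⁻⁶·exp(8.085·l_m/l_m0), and a seven-Gaussian force–velocity
curve with v_max = 10 optimal fiber lengths per second (lengthening
positive; the eccentric branch exceeds isometric force). Gaussian fits
can dip below zero at extreme abscissae; values are clamped at zero
because muscle cannot push. At the reference points the fits give
f_active(1) ≈ 1.002 and f_velocity(0) ≈ 1.029 — within the fitted
curves' own tolerance of the nominal 1.0.

The series tendon is treated as **rigid** at its slack length l_t. The
published model calls the tendon elastic but provides no force–strain
parameters, so a series-elastic equilibrium is not solvable from the
shipped constants alone; the rigid-tendon reduction is the standard
closure that uses only them. Fiber length then follows from the posed
path length l_mt via the constant-thickness triangle
l_m = √((l_mt − l_t)² + (l_m0 sin θ₀)²), pennation from
θ_m = arcsin(l_m0 sin θ₀ / l_m), and fiber velocity from central
differences of l_m on the window grid. Tendon force is
(a·f_active·f_velocity + f_passive)·F_m0·cos θ_m; its sagittal component
is F_T·cos φ_m.

## Geometry

Muscle paths are 3-D polylines (origin, optional via points, insertion)
in the ankle frame (X anterior, Y proximal, Z lateral); medial
gastrocnemius' proximal points are configured in the knee frame and
translated by the standing knee-origin offset (−11.2, 386, 0) mm.
Sagittal joint motion rotates foot-borne points about the ankle centre's
Z-axis and thigh-borne points about the knee centre's Z-axis, by the
deviation of each joint angle from the quiet-standing reference in which
the coordinates are defined. Segment elevation angles t_i (from the
horizontal; upright = 90°) map to joint deviations as
ankle = π/2 − t_shank (dorsiflexion positive, foot flat on the ground)
and knee = t_thigh − t_shank.

The moment arm about the ankle is the perpendicular distance from the
joint centre to the line through the two path points adjacent to the
joint crossing (last shank/thigh-borne point, first foot-borne point),
projected onto the sagittal plane and computed via Heron's formula as
h = 2S/c (triangle area over the attachment-to-attachment side). An
alternative h = 2S/p (semiperimeter denominator) is provided behind the
`as_printed` flag for reproduction studies; it is not the distance to
any triangle side and is off by ~25 % for typical shapes, so the
geometric form is the default. A virtual-work check (finite-difference
d l_mt/dθ vs h, within 5 % across ±0.25 rad for all four muscles) ties
the moment arms to the length kinematics.

φ_m is recomputed per time step from the joint-adjacent points; for
these muscles it is nearly constant (0.01–0.07 rad at reference).

## Inverse dynamics

The eight-term expression in the segment angles is evaluated exactly as
specified, including the mixed cos(t₁+t₂)/cos(t₁−t₃) arguments; no
sign "correction" is applied. Physical-plausibility anchors are the
analytic limits: upright static stance (all angles 90°, zero rates, zero
chair force) gives M = 0 to machine precision, and the moment is linear
in the segment masses and in g. The chair fractions n = F_chair/G and
q = (F_chair − n·m₂g)/(m₃g) are clamped to [0, 1] (the parsed formula
can exceed 1 when F_chair approaches G); both vanish at and after
seat-off. Angular velocity and acceleration are taken from the inertial
channels directly; a smoothed central-difference fallback
(`rates_from_angles`) exists for angle-only logs.

Because the synthetic generator uses this same routine to define its
ground-truth moment, the forward-vs-inverse comparison is independent of
whichever angle convention the expression encodes: both estimators see
the same self-consistent world.

## Synthetic trial generator

The generator's defaults are the study conditions. One trial lasts
3.5 s with seat-off at 40 % (1.4 s). Each segment angle follows a
quintic minimum-jerk profile s(u) = 10u³ − 15u⁴ + 6u⁵ (rest-to-rest at
both ends) between a seated and an upright value, with staggered phases
chosen so the hip leads the knee and the knee leads the ankle, matching
the observed STS coordination: HAT 60°→90° over 0–70 % of the trial,
thigh 55°→90° over 25–85 %, shank 80°→90° over 35–95 %. The seated
chair load is 80 % of total weight and decays along a minimum-jerk
ramp to zero at seat-off. These angle ranges and phases are plausible
rather than measured; they were chosen once so that the implied ankle
moment (roughly −80…+15 N·m on the reference subject) stays within the
four muscles' moment-generating capacity, leaving the redundancy
inversion feasible without clipping.

Ground-truth activations invert the forward model: since the rigid
tendon makes fiber kinematics independent of activation, the forward
moment is affine in the activation vector, M = Σ sᵢ(aᵢAᵢ + Pᵢ). The
muscle pair opposing the demanded moment sign (antagonists) is held at a
co-activation floor (default 0.05, emulating stabilising co-contraction);
the residual demand after passive and floor contributions is met by
equal activation increments across the agonist pair, i.e. the moment is
shared in proportion to each muscle's instantaneous capacity
F_m0·f_active·f_velocity·cos θ_m·cos φ_m·h. The inversion is exact, so
the noise-free round trip (ground-truth activations → forward moment vs
inverse moment) agrees to machine precision — well inside the 2 % RMS
the tests assert. Demands beyond agonist capacity raise an error rather
than silently saturating.

Raw sEMG is amplitude-modulated Gaussian noise: a unit-variance carrier
band-limited to 20–450 Hz, multiplied by a(t)·RMS_MVC with a(t)
interpolated between window centres. This is spectrally naive on
purpose — the estimator consumes only windowed RMS, for which the
envelope statistics are all that matter. Measurement noise defaults:
5 % relative per-window envelope-gain jitter (electrode/gain
fluctuation, part of the EMG synthesis), 0.5° additive noise on the IMU
angle channels, 5 N on the chair force (clipped at zero; samples at and
after seat-off stay exactly zero). All randomness flows from one seed;
identical specs give bit-identical trials.

What the generator does **not** emulate: motor-unit waveform structure,
electromechanical delay, non-sagittal motion, balance corrections,
jerky or multi-phase STS strategies, soft-tissue artefact on the IMUs,
and any muscles beyond the four modelled. Passing the agreement tests
therefore demonstrates internal consistency of the two estimator
implementations under realistic noise — not field accuracy on human
data, where the two routes disagree more (unmodelled muscles bias the
forward path low, and real sensor artefacts are not white).

## The ten-trial study

A cohort is emulated as ten seeded trials of the reference subject with
per-trial uniform ±10 % perturbation of body mass and stature (applied
through the scaling rule). Per trial, the full sEMG pipeline and the
inverse route run on the noisy streams; the inverse moment is linearly
interpolated onto the 20-Hz forward grid (the natural common base) and
summarised by Pearson correlation (Spearman available) and RMSE. With
the default noise the per-trial r is ≈ 0.99, comfortably above the
0.88 floor and 0.926 mean reported for the corresponding human
experiment — as expected for a self-consistent synthetic world, where
residual disagreement comes only from sensor noise and the RMS sampling
error.

## Numerical choices

- Window grid: 0.05 s, non-overlapping; 100-Hz kinematics are linearly
  interpolated to window centres; fiber velocity by central differences
  on that grid (one-sided at the ends).
- Moment arms and path lengths in mm internally; forces in N; public
  moments in N·m (h/1000 conversion at assembly).
- Curve clamps: f_active, f_velocity ≥ 0; tendon force ≥ 0; pennation
  arcsin argument clamped to 1 with a warning.
- Degenerate inputs raise typed errors (coincident path points, path
  shorter than tendon — named by muscle —, constant series in a
  correlation, < 3 overlapping samples, extrapolation requests).
- Problem sizes: trials are 3.5 s (3500 EMG samples/channel, 350 IMU
  samples, 70 windows); the ten-trial study runs in well under a second
  on one core, so the shipped experiments use it unreduced.

## Known limitations

- The rigid-tendon reduction understates fiber-length excursions for
  long-tendon muscles (gastrocnemius, soleus) relative to an elastic
  tendon model.
- The as-specified moment expression's mixed trigonometric arguments are
  kept verbatim; treat absolute inverse-moment magnitudes with care
  outside the self-consistent synthetic setting.
- The redundancy rule (equal agonist increments + antagonist floor) is
  one admissible inverse of an underdetermined map; real co-activation
  patterns differ.
- Subject scaling is isometric; real anthropometry is not.
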