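# Methods

This note documents the models, algorithms and numerical choices behind
`imugait`, in processing order, together with what the synthetic-data
generator does and does not emulate.

## Rotation conventions

Quaternions are scalar-first `(w, x, y, z)`, Hamilton convention, and every
exported operation returns the canonical representative with `w >= 0`
(stabilizes Euler-domain detrending and interpolation across the double
cover).  Euler angles are intrinsic Z-Y-X (yaw, pitch, roll).  The geodesic
angle between two rotations is evaluated through the relative quaternion
with `atan2`, which keeps full precision near zero where the textbook
`2 acos|<q1,q2>|` form saturates at ~3e-8 rad.

## Sensor fusion

Orientation is estimated per sensor by a gradient-descent complementary
filter on accelerometer + gyroscope only (no magnetometer).  Two deliberate
departures from the textbook formulation:

* **Exact gyro integration.**  The gyro term advances the quaternion by the
  exponential map of `omega * dt` instead of the first-order
  `q + q_dot dt`; at gait angular rates (several rad/s sampled at 60 Hz)
  the first-order form accumulates degree-level error per trial.
* **Un-normalized gradient.**  The gravity correction subtracts
  `beta * J^T f` rather than the unit-normalized gradient.  The normalized
  variant takes constant-size steps and therefore limit-cycles around
  equilibrium with amplitude ~`beta*dt` (~0.1 deg at beta = 0.1, 60 Hz);
  the raw-gradient form converges exponentially (rate ~2*beta) and reduces
  identically to pure strap-down integration at beta = 0.

The correction is *gated*: it is applied only when the accelerometer norm
lies within 5% of g, because during dynamic phases the accelerometer
measures mostly linear acceleration.  The gate cannot detect perpendicular
contamination (which barely changes the norm), so segments that accelerate
cyclically (thigh, shank, foot) still receive a small phase-locked tilt
pull of order `beta * a_perp/g`.  Consequence: the fusion gain must match
the gyro quality.  `beta = 0.1` (the default) suits noisy gyros, where the
induced pseudo-drift (~`beta * 0.03` rad/s) exceeds the 0.0010 rad/s drift
threshold and is removed by detrending; with a near-noiseless gyro the
same pull can fall *below* the threshold and accumulate silently, so the
`RunConfig.low_noise()` preset uses `beta = 5e-4`.

Initial orientation is the minimal (zero-yaw) rotation aligning the first
still second's mean accelerometer direction with gravity; heading is
unobservable and fixed later by registration.

## Drift detrending

From `t_start` (default 20 s, the end of the neutral-standing period) to
trial end, each unwrapped Z-Y-X Euler component is fit by least squares;
components with |slope| > 0.0010 rad/s have the fitted trend, anchored at
`t_start`, subtracted before re-converting to quaternions.  The operation
is idempotent (a second pass finds only sub-threshold slopes) and is
applied per axis.  Gimbal-locked samples in the window raise an error with
the sample index rather than guessing.  One ordering choice: sensors are
converted to the model axis convention (body-fixed 180° x, 90° y, −90° z)
*before* detrending, because in the raw vendor convention the neutral pose
sits exactly at Euler pitch −90° (gimbal lock) where the fit is undefined.

Caveat for short recordings: the line fit sees the gait oscillation as
noise, and with only ~20 strides the spurious slope estimate can exceed
the threshold, triggering unnecessary detrending; the procedure assumes
minutes-long trials (its SE shrinks as T^-3/2).

## Chain model, registration, IK

The chain is rotation-only: ground → pelvis (3 DOF: tilt, obliquity,
rotation) → trunk (3 DOF), and per leg pelvis → femur (3 DOF hip) → tibia
(1 DOF knee) → foot (1- or 2-DOF ankle: flexion ± inversion).  All
neutral-pose segment frames coincide with the model frame (X anterior,
Y left, Z up); within each joint the rotation order is FE→AA→IE, intrinsic
rotations about Y, X, Z.  Pelvis translation is carried as pass-through
state and never differentiated into outcomes.  Positive FE rotates about
+Y, so a forward limb tilt is negative FE; sign conventions are internal
and consistent between generator and estimator.

**Registration** uses a 3–4 s still window at the end of the standing
period.  Per sensor, the heading (yaw) — which magnetometer-free fusion
cannot observe — is measured against the circular-mean heading, removed,
and the pose aligned with the model's anterior axis; the residual rotation
at neutral is the fixed sensor-to-segment mounting offset.  At the neutral
pose the registered orientations equal the model frames exactly.  A known
limitation (inherent to one-pose registration, not an implementation
artifact): a mounting offset with a yaw component ψ cannot be separated
from the fusion's heading indeterminacy, leaving the estimated segment
orientation conjugated by Rz(ψ); during motion this leaks sagittal motion
into the frontal/axial angles at ~sin(ψ).  A non-still calibration window
(gyro RMS above threshold) raises an error.

**Inverse kinematics** minimizes, per frame, the weighted sum of squared
geodesic (axis-angle) differences between forward-kinematic segment
orientations and the measured targets (equal weights by default).  The
residuals are the rotation vectors of the relative rotations; the solver
is a damped Gauss–Newton with a numeric Jacobian, batched across frames.
Numerical choices: initialization by closed-form per-joint Euler
decomposition of the relative target rotations (exact for consistent
targets, so the iteration mostly verifies convergence); Jacobian refreshed
every 3 iterations (chord Gauss–Newton) with a forced refresh when a step
is rejected; backtracking line search keeps the objective non-increasing;
convergence when the gradient max-norm falls below `tol` (1e-8 rad for
the bare operation; the pipeline uses 1e-6, far below 0.001° in angle);
cap 100 iterations, non-converged frames keep their last iterate and are
flagged.  With all segments observed all DOFs are observable; unreachable
targets (e.g. axial rotation at a 1-DOF knee) resolve to the least-squares
projection, with roughly a third of unmatchable foot-inversion content
leaking into hip AA/IE under equal weights.

The **reference path** estimates each segment's orientation from its
four-marker cluster by the orthogonal Procrustes / Kabsch solution (SVD
with determinant +1 enforced), then runs the *same* IK.  Reference joint
angles are finally offset per DOF by the difference of neutral-window
means so both models share the IMU model's neutral pose; constant offsets
leave all variability outcomes unchanged.

## Events, strides, outcomes

Foot velocity is obtained by differentiating the forward-kinematic
calcaneus position of the solved angles (pelvis fixed — on a treadmill
this is the belt-referenced motion), zero-lag low-pass filtered (10 Hz,
net 4th order as forward–backward 2nd order).  Heel strikes are the first
local minimum of the speed after each prominent local maximum (mid-swing
peak).  The prominence floor is 25% of the speed range: the swing peak has
prominence near 100% while secondary stance/toe-off bumps stay below
~20%, so 25% separates them with margin on both sides (a 5% floor
double-fires on the toe-off dip).  Events closer than 0.4 × the median
interval are merged.  Right-foot events delimit the strides for all
reported angles.

After a steady-state discard (default 30 s) the next `n_strides` (default
200) strides are linearly resampled to 101 points (0–100% of the cycle);
the untouched concatenated samples over the same span form the companion
continuous series for the state-space metrics.

Outcomes per DOF: per-stride ROM (max − min of the normalized stride) and
its mean; meanSD (pointwise across-stride sample SD averaged over the 101
points); λ_max by Rosenstein's method on the continuous series resampled
to 100 points/stride (20 000 points at 200 strides), 5 embedding
dimensions, lag 10, nearest neighbour outside a Theiler window of one mean
period, least-squares slope of the mean log divergence over 0–0.5 strides,
reported per stride; DFAα of the per-stride ROM series (profile
integration, 16 log-spaced box sizes from 4 to N/4, per-box linear
detrend; constant series defined as α = 0); and multiscale sample entropy
of the continuous series at 120 Hz (coarse-grained by non-overlapping
means of 4, template length 2, Chebyshev tolerance 0.15 × SD of the
coarse-grained series, self-matches excluded, both template lengths
counted over the same N − m windows so a constant series gives exactly
−log 1 = 0; zero matches at length m+1 raise rather than return
infinity).

## Agreement and sensitivity statistics

Time-series agreement: RMSD per stride across the 101 paired points,
averaged over strides, with CV_rom = 100 × RMSD / reference mean ROM
(pooled over all analysis units).  Outcome agreement across
participant × condition units: ICC(2,1) — two-way random effects,
absolute agreement, single measures — from the two-way ANOVA mean
squares, with the F-based (McGraw–Wong) 95% CI and bands poor < 0.40 ≤
fair < 0.60 ≤ good < 0.75 ≤ excellent; Bland–Altman bias, t-based bias CI
(significant when it excludes zero) and limits of agreement
bias ± 1.96 SD(d).

Sensitivity: speed (preferred / 70% / 130%) and arm swing (preferred /
active / bound) are two one-way within-subject factors sharing the
preferred condition.  Each model × effect × DOF × outcome cell gets a
repeated-measures ANOVA; Mauchly's test at 0.05 triggers the
Greenhouse–Geisser correction of both degrees of freedom (partial eta²
from uncorrected sums of squares); the whole family — 240 tests in the
full 2 × 2 × 12 × 5 configuration — is controlled at q = 0.05 by
Benjamini–Hochberg step-up, and significant omnibus tests are followed by
Bonferroni-corrected paired t-tests against the preferred condition.  A
degenerate error term reports F = 0, p = 1.

## Synthetic data: what it emulates, and what it does not

Trials are a neutral-standing period (default 20 s; used for registration
and drift-fit anchoring) followed by constant-speed walking (default
420 s, ≥ 200 strides after discard) at 120 Hz ground truth.  Variability
is injected at the *stride* level: stride durations are mean + SD × fGn(H)
(fractional Gaussian noise by Davies–Harte circulant embedding; defaults
1.10 ± 0.022 s, H = 0.75 — healthy treadmill values) and each DOF's
amplitude is scaled per stride by 1 + 2.5% × fGn(0.75).  Pointwise noise
belongs to the measurement layer (gyro white noise and bias random walk,
accelerometer noise, marker jitter, random sensor-mounting misalignment),
at 60 Hz IMU / 120 Hz marker rates.

The sagittal leg patterns are derived, per condition, from a treadmill
foot-path construction: the ankle joint centre sweeps backward under the
hip at belt speed during stance (62% of the cycle) and returns along a
quintic arc whose end slopes match the stance sweep (C1-continuous foot
speed, so the speed profile has exactly one dominant swing maximum
followed by the contact minimum); heel lift starts in late stance; the
closed-form 2-link leg IK converts the path to hip/knee angles and the
ankle keeps the grounded foot flat while letting it pitch partially in
swing.  The resulting cycles are Fourier-fit (10 harmonics) into the same
per-DOF coefficient tables used for the trunk/pelvis/non-sagittal
harmonics.  Hip DOFs carry the negated pelvis harmonics so pelvis wobble
does not propagate into the grounded foot.  Speed conditions change belt
speed, stride time (∝ 1/√factor) and thereby the leg sweep amplitude
(hip-flexion ROM grows ~15–25% at the 130% condition); arm-swing
conditions scale the trunk/pelvis axial amplitudes (×1.4 active, ×0.65
bound) — the chain has no arms, mirroring how such effects reach the
recorded segments.  Ground-truth contact times are defined at the
foot-speed minimum of the noiseless nominal cycle.

Not emulated: ground-reaction forces and belt dynamics, soft-tissue
artefact, marker occlusion/gap-filling, muscle–tendon actuation,
double-support mechanics beyond what the foot path implies, and arm
segments.  Passing tests therefore demonstrate correctness of the
*processing chain* under controlled conditions — they do not certify
accuracy on human data, where soft tissue and model mismatch dominate.

## Problem sizes used in the test suite

The packaged checks run the full 200-stride, 7-minute configuration where
the quantity under test needs it (drift detrending, single-trial
agreement in the worked example) and deliberately reduced cohorts where
the check is about pipeline behaviour rather than asymptotics: the
cohort agreement check uses 3 subjects × 5 conditions × 20 strides of
90 s trials, and the condition-effect power check uses 50 seeded cohorts
of 4 subjects × 3 speed conditions × 12 strides with the marker path
sampled at 60 Hz and ROM as the outcome.  These sizes are the package's
own choices for a self-contained suite; all are overridable through
`RunConfig`.

## Known limitations

* One-pose registration cannot identify mounting yaw (see above); frontal
  and axial-plane angles inherit sagittal cross-talk of order sin(ψ).
* The drift threshold is an absolute slope criterion; drift just below
  0.0010 rad/s accumulates uncorrected (up to ~0.4 rad over 7 minutes in
  the worst case), and short trials can trigger spurious detrending.
* The accelerometer gate is norm-based and blind to perpendicular
  contamination; beta must be chosen against gyro quality.
* DFA on 200 strides carries the usual small-sample upward bias
  (~0.02–0.04 for uncorrelated input with the 4…N/4 box range).
* The divergence exponent and sample entropy are reported for fixed,
  documented reconstruction parameters; they are not tuned per signal.
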