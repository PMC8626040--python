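# imugait

Wearable inertial sensors promise gait analysis outside the laboratory, but
before an IMU-driven kinematic model can be trusted for clinical questions —
fall risk, aging, neurological disease — it must be shown to reproduce both
the joint-angle time series and the *stride-to-stride motor-variability*
outcomes that optoelectronic (marker-based) systems deliver, and to remain
sensitive to within-participant changes such as walking speed and arm-swing
amplitude.

`imugait` implements that whole validation workflow as a tested Python
library:

* **Orientation estimation** — magnetometer-free Madgwick-style fusion of
  60 Hz accelerometer + gyroscope streams, followed by removal of residual
  linear orientation drift: each unwrapped Z-Y-X Euler component is fit by a
  line from the 20 s mark onward and detrended when |slope| > 0.0010 rad/s.
* **Kinematics** — a rotation-only joint chain (3-DOF pelvis and trunk,
  3-DOF hips, 1-DOF knees, 1- or 2-DOF ankles), sensor-to-segment
  registration in a neutral standing pose (mounting offset + heading), and
  orientation-tracking inverse kinematics that minimizes weighted squared
  axis-angle differences between model and measured segment orientations.
  The reference path estimates segment orientations from rigid four-marker
  clusters at 120 Hz by orthogonal Procrustes and feeds the same IK.
* **Gait events and outcomes** — heel strikes as the foot-speed minima that
  follow each swing-phase maximum; 200 steady-state strides time-normalized
  to 101 points; per degree of freedom the five outcomes
  ROM, meanSD, the local divergence exponent λ_max (Rosenstein: 20 000
  points, 5 embedding dimensions, lag 10, slope over 0–0.5 strides), the
  detrended-fluctuation exponent DFAα of the per-stride ROM series, and
  multiscale sample entropy (m = 2, r = 0.15·SD, scale 4, 120 Hz).
* **Statistics** — concurrent validity (per-stride RMSD and CV, ICC(2,1)
  with F-based CI and poor/fair/good/excellent bands, Bland–Altman bias and
  95% limits of agreement) and within-participant sensitivity
  (repeated-measures ANOVA with Mauchly/Greenhouse–Geisser handling,
  Benjamini–Hochberg FDR over the full model × effect × angle × outcome
  family, Bonferroni post hocs against the preferred condition).
* **Synthetic ground truth** — a treadmill-gait generator with controllable
  stride-time and amplitude variability (fractional Gaussian noise with
  chosen Hurst persistence), speed and arm-swing condition presets, and
  simulated IMU (gyro bias random walk, white noise, mounting misalignment)
  and marker-cluster measurements, so every pipeline stage can be checked
  against a known answer.

## Worked example

Simulate one low-noise trial, run both measurement paths, and compare:

```python
from imugait.synthetic_data import GaitParams, generate_truth, simulate_imu, simulate_markers
from imugait.pipeline import (RunConfig, process_imu_trial,
                              process_marker_trial, trial_stride_matrix)
from imugait.kinematics import pose_offset_alignment
from imugait.agreement_stats import timeseries_rmsd
from imugait.variability_metrics import compute_outcomes

cfg = RunConfig.low_noise(gait=GaitParams(duration=270, seed=7), n_strides=200)
model = cfg.model()
truth = generate_truth(cfg.gait, model)
imu = process_imu_trial(simulate_imu(truth, cfg.noise, seed=7), model, cfg,
                        cfg.gait.still_duration)
ref = process_marker_trial(simulate_markers(truth, cfg.noise, seed=8), model, cfg)
ref = pose_offset_alignment(ref, imu, neutral_window=(16.0, 19.0))

m_ref, events = trial_stride_matrix(ref, model, cfg, cfg.gait.still_duration)
m_imu, _ = trial_stride_matrix(imu.resample(ref.t), model, cfg,
                               cfg.gait.still_duration, events=events)
rmsd, _ = timeseries_rmsd(m_ref, m_imu)
table = compute_outcomes(m_imu).values.round(3)
table["rmsd_vs_ref"] = rmsd.round(3)
print(table)
```

which prints (angles in degrees; λ_max per stride; DFAα and SaEn unitless):

```
               ROM  meanSD  lambda_max  dfa_alpha   saen  rmsd_vs_ref
dof
pelvis_FE    3.011   0.714       2.636      0.639  0.283        0.172
pelvis_AA    4.957   0.765       3.475      0.711  0.227        0.109
pelvis_IE    9.993   1.549       3.312      0.770  0.226        0.108
trunk_FE     3.062   0.735       2.563      0.702  0.303        0.235
trunk_AA     6.029   0.930       3.283      0.790  0.228        0.150
trunk_IE    11.971   1.862       3.361      0.709  0.227        0.166
hip_r_FE    46.653   6.374       3.298      0.747  0.220        0.546
hip_r_AA     6.868   1.046       3.282      0.635  0.229        0.154
hip_r_IE     6.550   1.014       3.552      0.512  0.232        0.152
knee_r_FE   57.518   8.566       3.296      0.700  0.239        0.415
ankle_r_FE  57.240   8.058       3.410      0.974  0.136        0.229
ankle_r_AA   6.046   0.924       3.271      0.619  0.213        0.233
```

The IMU path reproduces the reference path to well under a degree of RMSD
across 200 strides at every degree of freedom, and the DFAα of hip flexion
ROM (0.747) recovers the persistence injected by the generator (Hurst
H = 0.75).  Cohort-level analyses are one call each:
`run_validity(cfg)` (ICC/Bland–Altman per DOF × outcome) and
`run_sensitivity(cfg)` (speed/swing RM-ANOVAs with FDR control).

A CLI mirrors the stages: `imugait generate|fuse|ik|events|outcomes|validity|sensitivity|all`.

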