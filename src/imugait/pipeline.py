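"""End-to-end orchestration: raw signals -> angles -> outcomes -> statistics.

Two measurement paths are processed per trial:

* IMU path: Madgwick fusion of each 60 Hz sensor stream, drift
  detrending, conversion to the model axis convention, registration in
  the neutral standing window, and orientation-tracking IK.
* reference path: Procrustes orientations of the 120 Hz marker clusters
  fed to the same IK, then offset-aligned to the IMU model's neutral
  pose.

Stride events come from the foot (calcaneus) velocity of the solved
angles via forward kinematics; the five variability outcomes are
computed per DOF over a fixed number of steady-state strides.
:func:`run_validity` compares the two paths (time-series RMSD/CV, per
outcome ICC and Bland-Altman across subject x condition units);
:func:`run_sensitivity` runs the repeated-measures speed/swing response
analysis with Benjamini-Hochberg FDR control.

A :class:`RunConfig` fully determines a run (serializable to YAML,
seeded); every output directory receives a ``run_info.json`` with the
config hash and package version for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .agreement_stats import bland_altman, icc_2_1, timeseries_rmsd
from .gait_events import (
    StrideMatrix,
    detect_heel_strikes,
    extract_strides,
    lowpass_zero_lag,
)
from .imu_fusion import detrend_orientation, fuse_trial
from .kinematics import (
    ChainModel,
    JointAngleSeries,
    forward_kinematics,
    ik_orientation,
    pose_offset_alignment,
    register,
    segment_orientation_from_markers,
    sensor_to_model_frame,
)
from .sensitivity_stats import (
    benjamini_hochberg,
    bonferroni_posthoc,
    build_family,
    rm_anova,
)
from .synthetic_data import (
    CONDITIONS,
    GaitParams,
    SensorNoiseModel,
    generate_truth,
    simulate_imu,
    simulate_markers,
)
from .variability_metrics import OUTCOME_NAMES, compute_outcomes

log = logging.getLogger("imugait")

__all__ = ["RunConfig", "process_imu_trial", "process_marker_trial",
           "trial_stride_matrix", "run_validity", "run_sensitivity", "cli"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a cohort analysis."""

    gait: GaitParams = field(default_factory=GaitParams)
    noise: SensorNoiseModel = field(default_factory=SensorNoiseModel)
    n_subjects: int = 14
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    ankle_mode: str = "2dof"
    beta: float = 0.1  # fusion gain, rad/s
    drift_t_start: float = 20.0
    drift_threshold: float = 0.0010  # rad/s
    discard_s: float = 30.0
    n_strides: int = 200
    ik_tol: float = 1e-6  # IK gradient tolerance, rad (see methods note)
    outcomes: tuple[str, ...] = OUTCOME_NAMES
    subject_spread: float = 0.04  # between-subject SD of speed/stride time
    seed: int = 0
    out_dir: str | None = None

    def model(self) -> ChainModel:
        return ChainModel.default(self.ankle_mode)

    @classmethod
    def low_noise(cls, **kw) -> "RunConfig":
        """Near-ideal measurement configuration.

        Sensor noise, drift and mounting misalignment are reduced to
        instrument-floor levels and the fusion gain lowered to match
        (with a near-noiseless gyroscope, heavy gravity correction only
        injects linear-acceleration artefacts).  Used to verify that the
        processing chain itself — fusion, registration, IK, events —
        is unbiased.
        """
        cfg = cls(**kw)
        cfg.noise = SensorNoiseModel(
            gyro_noise_density=1e-4, gyro_bias_walk=1e-6,
            accel_noise_sd=0.005, marker_noise_mm=0.2, mount_deg=2.0,
        )
        # with a near-perfect gyro the gravity correction is only needed
        # against negligible drift; larger gains let the cyclic
        # centripetal acceleration bias the tilt at a rate that can hide
        # below the drift-detrend threshold
        cfg.beta = 0.0005
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gait" in d and isinstance(d["gait"], dict):
            d["gait"] = GaitParams(**d["gait"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = SensorNoiseModel(**d["noise"])
        for k in ("conditions", "outcomes"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(out_dir, config: RunConfig) -> None:
    import pathlib

    p = pathlib.Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    info = {"config_hash": config.config_hash(), "version": __version__,
            "config": config.to_dict()}
    (p / "run_info.json").write_text(json.dumps(info, indent=2))


# ---------------------------------------------------------------------------
# trial-level processing

def process_imu_trial(
    recordings: dict, model: ChainModel, cfg: RunConfig,
    still_duration: float,
) -> JointAngleSeries:
    """Raw IMU streams -> joint angles (deg) at the IMU rate.

    Fusion -> model-frame conversion -> drift detrending -> neutral-pose
    registration -> orientation-tracking IK.  The conversion precedes
    Euler-domain detrending because the raw sensor convention sits at
    gimbal lock in the neutral pose.
    """
    tracks = {}
    neutral = {}
    gyro_windows = {}
    for sid, rec in recordings.items():
        tr = fuse_trial(rec, beta=cfg.beta)
        tr.q = sensor_to_model_frame(tr.q)
        tr, drift = detrend_orientation(
            tr, t_start=min(cfg.drift_t_start, still_duration),
            threshold=cfg.drift_threshold,
        )
        slopes = {a: f"{x.slope:+.2e}{'*' if x.detrended else ''}"
                  for a, x in drift.axes().items()}
        log.debug("sensor %s drift slopes (rad/s): %s", sid, slopes)
        tracks[sid] = tr
        win = (rec.t >= still_duration - 4.0) & (rec.t <= still_duration - 1.0)
        neutral[sid] = tr.q[win]
        gyro_windows[sid] = rec.gyro[win]
    reg = register(neutral, model, gyro_windows=gyro_windows)
    targets = {sid: reg.apply(tr).q for sid, tr in tracks.items()}
    t = next(iter(recordings.values())).t
    angles, converged = ik_orientation(model, targets, tol=cfg.ik_tol)
    if not converged.all():
        log.warning("IK: %d/%d frames did not converge",
                    int((~converged).sum()), converged.size)
    return JointAngleSeries(t, angles, model.dof_labels)


def process_marker_trial(
    traj, model: ChainModel, cfg: RunConfig,
) -> JointAngleSeries:
    """Marker trajectories -> joint angles (deg) at the marker rate."""
    seg_tracks = segment_orientation_from_markers(traj)
    targets = {seg: tr.q for seg, tr in seg_tracks.items()}
    angles, converged = ik_orientation(model, targets, tol=cfg.ik_tol)
    if not converged.all():
        log.warning("marker IK: %d frames not converged",
                    int((~converged).sum()))
    return JointAngleSeries(np.asarray(traj.t, float), angles,
                            model.dof_labels)


def foot_speed(angles: JointAngleSeries, model: ChainModel,
               foot: str = "r") -> np.ndarray:
    """Low-pass filtered calcaneus speed from FK of the joint angles.

    Pelvis translation is unknown to both measurement paths, so the
    speed is computed with a fixed pelvis — on a treadmill this is the
    belt-referenced foot motion that carries the gait events.
    """
    _, pos = forward_kinematics(model, angles.angles)
    v = np.gradient(pos[f"calcn_{foot}"], 1.0 / angles.fs, axis=0)
    v = lowpass_zero_lag(v, angles.fs)
    return np.linalg.norm(v, axis=1)


def trial_stride_matrix(
    angles: JointAngleSeries, model: ChainModel, cfg: RunConfig,
    walk_start: float, events=None,
) -> tuple[StrideMatrix, "object"]:
    """Partition a trial into the analysis strides (right-foot events).

    Returns ``(stride matrix over the analysis DOFs, events)``.  If
    ``events`` is given (e.g. the reference path's, to pair strides
    across measurement systems) detection is skipped; event times are
    mapped onto this series' clock by nearest sample.
    """
    walk = angles.t >= walk_start
    sub = JointAngleSeries(angles.t[walk], angles.angles[walk],
                           list(angles.labels))
    if events is None:
        speed = foot_speed(sub, model)
        events = detect_heel_strikes(speed, sub.fs)
    else:
        # shared events assume the two series were sampled on the same
        # clock and grid (the IMU series is resampled onto the reference
        # timestamps before pairing)
        from .gait_events import StrideSet

        idx = np.clip(events.indices, 0, len(sub.t) - 1)
        events = StrideSet(idx, idx / sub.fs, sub.fs)
    keep = [sub.labels.index(d) for d in model.analysis_dofs]
    sub = JointAngleSeries(sub.t, sub.angles[:, keep], model.analysis_dofs)
    m = extract_strides(sub, events, discard_s=cfg.discard_s,
                        n_strides=cfg.n_strides)
    return m, events


def _subject_params(cfg: RunConfig, subject: int, condition: str) -> GaitParams:
    """Per-subject anthropometric-like jitter on the base gait parameters."""
    rng = np.random.default_rng(cfg.seed * 100003 + subject)
    g = cfg.gait
    spread = cfg.subject_spread
    g = dataclasses.replace(
        g,
        speed=g.speed * (1 + spread * rng.standard_normal()),
        stride_time_mean=g.stride_time_mean
        * (1 + spread * rng.standard_normal()),
        amp_sd_frac=g.amp_sd_frac * float(rng.uniform(0.8, 1.25)),
        seed=int(rng.integers(2**31 - 1)),
    )
    return g.condition(condition)


def _trial_paths(cfg: RunConfig, params: GaitParams, trial_seed: int,
                 model: ChainModel):
    """Simulate one trial and process it through both measurement paths."""
    truth = generate_truth(params, model)
    recs = simulate_imu(truth, cfg.noise, seed=trial_seed)
    traj = simulate_markers(truth, cfg.noise, seed=trial_seed + 1)
    imu = process_imu_trial(recs, model, cfg, params.still_duration)
    ref = process_marker_trial(traj, model, cfg)
    ref = pose_offset_alignment(
        ref, imu, neutral_window=(params.still_duration - 4.0,
                                  params.still_duration - 1.0))
    return truth, imu, ref


def run_validity(cfg: RunConfig):
    """Concurrent validity of the IMU path against the reference path.

    Returns a dict with two DataFrames: ``timeseries`` (per-DOF RMSD and
    CV_rom, pooled over subjects and conditions) and ``outcomes``
    (per DOF x outcome ICC(2,1) with CI/band, RMSD, CV_mean,
    Bland-Altman bias/CI/LOA) across subject x condition units.
    """
    import pandas as pd

    model = cfg.model()
    dofs = model.analysis_dofs
    rmsd_acc = []
    rows = []
    for s in range(cfg.n_subjects):
        for c, cond in enumerate(cfg.conditions):
            params = _subject_params(cfg, s, cond)
            trial_seed = (cfg.seed * 7919 + s * 53 + c) % (2**31 - 1)
            truth, imu, ref = _trial_paths(cfg, params, trial_seed, model)
            walk = params.still_duration
            m_ref, events = trial_stride_matrix(ref, model, cfg, walk)
            # pair strides by slicing the IMU series at the same times
            imu120 = imu.resample(ref.t)
            m_imu, _ = trial_stride_matrix(imu120, model, cfg, walk,
                                           events=events)
            rmsd, cv = timeseries_rmsd(m_ref, m_imu)
            rmsd_acc.append((rmsd, cv))
            out_ref = compute_outcomes(m_ref, outcomes=cfg.outcomes).values
            out_imu = compute_outcomes(m_imu, outcomes=cfg.outcomes).values
            for d in dofs:
                for o in cfg.outcomes:
                    rows.append({"subject": s, "condition": cond, "dof": d,
                                 "outcome": o,
                                 "ref": out_ref.loc[d, o],
                                 "imu": out_imu.loc[d, o]})
            log.info("validity: subject %d %s done", s, cond)
    ts = pd.DataFrame({
        "dof": dofs,
        "rmsd_deg": np.mean([r for r, _ in rmsd_acc], axis=0),
        "cv_rom_pct": np.mean([c for _, c in rmsd_acc], axis=0),
    })
    per_out = pd.DataFrame(rows)
    orecs = []
    for (d, o), g in per_out.groupby(["dof", "outcome"], sort=False):
        diff = g["imu"].to_numpy() - g["ref"].to_numpy()
        if len(g) < 3:
            # too few subject x condition units for ICC / Bland-Altman
            orecs.append({"dof": d, "outcome": o, "icc": np.nan,
                          "icc_lo": np.nan, "icc_hi": np.nan, "band": "",
                          "rmsd": float(np.sqrt(np.mean(diff**2))),
                          "cv_mean_pct": np.nan, "bias": float(diff.mean()),
                          "bias_lo": np.nan, "bias_hi": np.nan,
                          "loa_low": np.nan, "loa_high": np.nan,
                          "bias_significant": False})
            continue
        icc = icc_2_1(g["ref"].to_numpy(), g["imu"].to_numpy())
        ba = bland_altman(g["ref"].to_numpy(), g["imu"].to_numpy())
        ref_mean = g["ref"].mean()
        orecs.append({
            "dof": d, "outcome": o,
            "icc": icc.icc, "icc_lo": icc.ci_low, "icc_hi": icc.ci_high,
            "band": icc.band,
            "rmsd": float(np.sqrt(np.mean(diff**2))),
            "cv_mean_pct": float(100 * np.sqrt(np.mean(diff**2))
                                 / abs(ref_mean)) if ref_mean else np.nan,
            "bias": ba.bias, "bias_lo": ba.bias_ci_low,
            "bias_hi": ba.bias_ci_high,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            "bias_significant": ba.significant,
        })
    report = {"timeseries": ts, "outcomes": pd.DataFrame(orecs),
              "units": per_out}
    if cfg.out_dir:
        _write_provenance(cfg.out_dir, cfg)
        ts.to_csv(f"{cfg.out_dir}/validity_timeseries.csv", index=False)
        report["outcomes"].to_csv(f"{cfg.out_dir}/validity_outcomes.csv",
                                  index=False)
    return report


#: condition levels of the two within-participant effects; the preferred
#: condition is shared
EFFECT_LEVELS = {
    "speed": ("speed_preferred", "speed_70", "speed_130"),
    "swing": ("speed_preferred", "swing_active", "swing_bound"),
}


def run_sensitivity(cfg: RunConfig, unit_table=None):
    """Speed/swing response RM-ANOVAs with FDR control and post hocs.

    ``unit_table`` may reuse the per-unit outcome table of a previous
    :func:`run_validity` call (columns subject, condition, dof, outcome,
    ref, imu); otherwise the cohort is simulated here.  Returns a
    DataFrame with one row per model x effect x DOF x outcome.
    """
    import pandas as pd

    model = cfg.model()
    if unit_table is None:
        unit_table = run_validity(cfg)["units"]
    effects = {e: lv for e, lv in EFFECT_LEVELS.items()
               if all(l in set(cfg.conditions) for l in lv)}
    rows = []
    for mdl in ("imu", "ref"):
        for eff, levels in effects.items():
            for d in model.analysis_dofs:
                for o in cfg.outcomes:
                    sub = unit_table[(unit_table["dof"] == d)
                                     & (unit_table["outcome"] == o)]
                    piv = sub.pivot_table(index="subject",
                                          columns="condition", values=mdl)
                    y = piv[list(levels)].to_numpy()
                    res = rm_anova(y)
                    ph = bonferroni_posthoc(y, reference_level=0)
                    rows.append({
                        "model": mdl, "effect": eff, "dof": d, "outcome": o,
                        "F": res.F, "df1": res.df_num, "df2": res.df_den,
                        "eps": res.epsilon, "p": res.p,
                        "partial_eta2": res.partial_eta2,
                        "posthoc_lvl1": ph[1], "posthoc_lvl2": ph[2],
                    })
    rep = pd.DataFrame(rows)
    crit, dec = benjamini_hochberg(rep["p"].to_numpy(), q=0.05)
    rep["p_crit"] = crit
    rep["significant"] = dec
    if cfg.out_dir:
        _write_provenance(cfg.out_dir, cfg)
        rep.to_csv(f"{cfg.out_dir}/sensitivity.csv", index=False)
    return rep


# ---------------------------------------------------------------------------
# command-line interface

def _setup_logging(verbose: bool) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def cli():
    import click

    @click.group()
    @click.option("--verbose", is_flag=True)
    def main(verbose):
        """IMU-driven gait variability analysis pipeline."""
        _setup_logging(verbose)

    def _common(f):
        f = click.option("--config", "config_path", default=None,
                         help="YAML RunConfig")(f)
        f = click.option("--seed", type=int, default=0)(f)
        f = click.option("--out", "out_dir", default="imugait_out")(f)
        f = click.option("--ankle-mode",
                         type=click.Choice(["1dof", "2dof"]),
                         default=None)(f)
        f = click.option("--beta", type=float, default=None)(f)
        f = click.option("--drift-threshold", type=float, default=None)(f)
        f = click.option("--n-strides", type=int, default=None)(f)
        f = click.option("--discard-s", type=float, default=None)(f)
        f = click.option("--n-subjects", type=int, default=None)(f)
        f = click.option("--duration", type=float, default=None)(f)
        return f

    def _load(config_path, seed, out_dir, **over):
        cfg = (RunConfig.from_yaml(config_path) if config_path
               else RunConfig())
        cfg.seed = seed
        cfg.out_dir = out_dir
        dur = over.pop("duration", None)
        if dur is not None:
            cfg.gait = dataclasses.replace(cfg.gait, duration=dur)
        for k, v in over.items():
            if v is not None:
                setattr(cfg, k, v)
        return cfg

    @main.command()
    @_common
    @click.option("--condition", default="speed_preferred",
                  type=click.Choice(list(CONDITIONS)))
    def generate(config_path, seed, out_dir, condition, **over):
        """Write one synthetic trial (IMU CSV, marker CSV, truth angles)."""
        import pathlib

        from .imu_fusion import write_imu_csv
        from .kinematics import write_markers_csv, write_quaternion_table

        cfg = _load(config_path, seed, out_dir, **over)
        params = dataclasses.replace(cfg.gait.condition(condition),
                                     seed=cfg.seed)
        truth = generate_truth(params, cfg.model())
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_provenance(out, cfg)
        write_imu_csv(out / "imu.csv",
                      simulate_imu(truth, cfg.noise, seed=cfg.seed))
        write_markers_csv(out / "markers.csv",
                          simulate_markers(truth, cfg.noise,
                                           seed=cfg.seed + 1))
        write_quaternion_table(out / "truth_orientations.sto", truth.t,
                               truth.orientations)
        truth.angles.to_frame().to_csv(out / "truth_angles.csv")
        np.savetxt(out / "truth_contacts_r.txt", truth.contact_times["r"])
        np.savetxt(out / "truth_contacts_l.txt", truth.contact_times["l"])
        click.echo(f"trial written to {out}")

    @main.command()
    @_common
    @click.argument("imu_csv")
    def fuse(config_path, seed, out_dir, imu_csv, **over):
        """Fuse raw IMU CSV into detrended orientation tracks (.sto)."""
        import pathlib

        from .imu_fusion import read_imu_csv
        from .kinematics import write_quaternion_table

        cfg = _load(config_path, seed, out_dir, **over)
        recs = read_imu_csv(imu_csv)
        tracks = {}
        t = None
        for sid, rec in recs.items():
            tr = fuse_trial(rec, beta=cfg.beta)
            tr.q = sensor_to_model_frame(tr.q)
            tr, _ = detrend_orientation(tr, t_start=cfg.drift_t_start,
                                        threshold=cfg.drift_threshold)
            tracks[sid] = tr.q
            t = tr.t
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_quaternion_table(out / "orientations.sto", t, tracks)
        click.echo(f"orientations written to {out}")

    @main.command()
    @_common
    @click.argument("sto_path")
    @click.option("--still-duration", type=float, default=20.0)
    def ik(config_path, seed, out_dir, sto_path, still_duration, **over):
        """Registered orientation-tracking IK on a quaternion table."""
        import pathlib

        from .kinematics import read_quaternion_table

        cfg = _load(config_path, seed, out_dir, **over)
        model = cfg.model()
        t, tracks = read_quaternion_table(sto_path)
        win = (t >= still_duration - 4.0) & (t <= still_duration - 1.0)
        neutral = {sid: q[win] for sid, q in tracks.items()}
        reg = register(neutral, model)
        from .imu_fusion import OrientationTrack

        targets = {
            sid: reg.apply(OrientationTrack(sid, t, q)).q
            for sid, q in tracks.items()
        }
        angles, _ = ik_orientation(model, targets)
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        JointAngleSeries(t, angles, model.dof_labels).to_frame().to_csv(
            out / "angles.csv")
        click.echo(f"angles written to {out}")

    @main.command()
    @_common
    @click.argument("angles_csv")
    @click.option("--walk-start", type=float, default=20.0)
    def events(config_path, seed, out_dir, angles_csv, walk_start, **over):
        """Heel-strike events from a joint-angle CSV."""
        import pathlib

        import pandas as pd

        cfg = _load(config_path, seed, out_dir, **over)
        model = cfg.model()
        df = pd.read_csv(angles_csv, index_col=0)
        series = JointAngleSeries(df.index.to_numpy(), df.to_numpy(),
                                  list(df.columns))
        walk = series.t >= walk_start
        sub = JointAngleSeries(series.t[walk], series.angles[walk],
                               list(series.labels))
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = []
        for foot in ("r", "l"):
            ev = detect_heel_strikes(foot_speed(sub, model, foot), sub.fs)
            frames.append(ev.to_frame(foot))
        pd.concat(frames, ignore_index=True).to_csv(out / "events.csv",
                                                    index=False)
        click.echo(f"events written to {out}")

    @main.command()
    @_common
    @click.argument("angles_csv")
    @click.option("--walk-start", type=float, default=20.0)
    def outcomes(config_path, seed, out_dir, angles_csv, walk_start, **over):
        """Stride matrix and the five variability outcomes per DOF."""
        import pathlib

        import pandas as pd

        cfg = _load(config_path, seed, out_dir, **over)
        model = cfg.model()
        df = pd.read_csv(angles_csv, index_col=0)
        series = JointAngleSeries(df.index.to_numpy(), df.to_numpy(),
                                  list(df.columns))
        m, ev = trial_stride_matrix(series, model, cfg, walk_start)
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        m.to_frame().to_csv(out / "strides.csv", index=False)
        compute_outcomes(m, outcomes=cfg.outcomes).to_csv(
            out / "outcomes.csv")
        click.echo(f"outcomes written to {out}")

    @main.command()
    @_common
    def validity(config_path, seed, out_dir, **over):
        """Synthetic-cohort concurrent-validity analysis."""
        cfg = _load(config_path, seed, out_dir, **over)
        rep = run_validity(cfg)
        click.echo(rep["timeseries"].to_string(index=False))

    @main.command()
    @_common
    def sensitivity(config_path, seed, out_dir, **over):
        """Synthetic-cohort speed/swing sensitivity analysis."""
        cfg = _load(config_path, seed, out_dir, **over)
        rep = run_sensitivity(cfg)
        click.echo(rep.head(20).to_string(index=False))

    @main.command(name="all")
    @_common
    def run_all(config_path, seed, out_dir, **over):
        """Validity followed by sensitivity on the same cohort."""
        cfg = _load(config_path, seed, out_dir, **over)
        rep = run_validity(cfg)
        run_sensitivity(cfg, unit_table=rep["units"])
        click.echo(f"reports written to {out_dir}")

    main()
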