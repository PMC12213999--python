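"""High-level pipelines mirroring the two validation experiments.

Experiment 1 — fixation-grid validation: a synthetic cohort fixates the
7x5 target grid (-21..21 deg horizontally in 7-deg steps, -10..10 deg
vertically in 5-deg steps) monocularly and binocularly; gaze is
reconstructed after single-point kappa calibration and summarized with
the fixation accuracy/precision metrics, stratified central/peripheral.

Experiment 2 — vergence validation: (a) a depth series with the central
target at 610, 480 and 350 mm from the subject, analysed with a
random-intercept regression of measured on target vergence and
subject-intercept-corrected MAE; (b) a stepped pupil-size series at
constant fixation, analysed with a pupil-area mixed model and Spearman
rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixation import extract_window, stratify_and_aggregate
from .reconstruction import (
    KappaCalibration,
    angles_to_screen,
    calibrate_kappa,
    reconstruct_stream,
    synchronize_streams,
)
from .scene import SceneGeometry, default_scene
from .simulator import SimulationResult, SubjectParams, simulate_fixation_session, simulate_pupil_series
from .stats import MixedFitResult, fit_random_intercept, spearman_rho, subject_corrected_mae
from .vergence import vergence_mae, vergence_table

GRID_X_DEG = np.arange(-21.0, 21.1, 7.0)
GRID_Y_DEG = np.arange(-10.0, 10.1, 5.0)
DEPTH_SERIES_MM = (610.0, 480.0, 350.0)


def validation_target_grid(viewing_distance: float = 650.0):
    """The 7x5 validation grid as (angles_deg, positions_mm) arrays; target
    angles are those of the theoretical eye at the screen's z-axis."""
    angles, positions = [], []
    for gy in GRID_Y_DEG:
        for gx in GRID_X_DEG:
            x, y = angles_to_screen(gx, gy, viewing_distance)
            angles.append((gx, gy))
            positions.append((x, y, 0.0))
    return np.asarray(angles), np.asarray(positions)


def calibrate_subject(
    subject: SubjectParams,
    scene: SceneGeometry,
    noise_px: float = 0.0,
    rng_seed: int | None = None,
    duration_s: float = 10.0,
    s0=(0.0, 0.0, 0.0),
) -> dict[str, KappaCalibration]:
    """Monocular single-point calibration of both eyes (the fellow eye is
    occluded, so no fixation disparity contaminates kappa).

    The calibration fixation lasts ``duration_s`` (default 10 s).  A
    noise-propagation analysis of the rig geometry shows the cameras'
    ~26-deg elevation couples triangulation depth noise into the vertical
    axis component at roughly 3 deg per frame at 0.3-px feature noise, so
    the per-frame median needs a few hundred frames to stabilize; since
    this is the only subject-specific step, a generous epoch is cheap.
    """
    cals = {}
    for i, eye in enumerate(("left", "right")):
        # monocular: zero disparity/gain effects while the fellow eye is covered
        mono = SubjectParams(**{**subject.__dict__, "eso_disparity_deg": 0.0, "vergence_gain": 1.0})
        sim = simulate_fixation_session(
            [s0],
            scene=scene,
            subject=mono,
            duration_s=duration_s,
            noise_px=noise_px,
            rng_seed=None if rng_seed is None else rng_seed + i,
            eyes=(eye,),
        )
        feats = sim.features
        synced = synchronize_streams(
            feats[feats["cam"] == 1], feats[feats["cam"] == 2]
        )
        cals[eye] = calibrate_kappa(synced, scene, s0)
    return cals


def reconstruct_session(
    sim: SimulationResult,
    scene: SceneGeometry,
    calibrations: dict[str, KappaCalibration],
    use_cp_constraint: bool = True,
) -> pd.DataFrame:
    return reconstruct_stream(sim.features, scene, calibrations, use_cp_constraint)


def windows_from_session(
    gaze: pd.DataFrame,
    trials: pd.DataFrame,
    targets_deg,
    subject: str = "",
    condition: str = "",
):
    """Cut a reconstructed session into per-trial fixation windows."""
    windows = []
    for (_, trial), tdeg in zip(trials.iterrows(), targets_deg):
        for eye in gaze["eye"].unique():
            sub = gaze[gaze["eye"] == eye]
            w = extract_window(
                sub,
                onset_s=trial["onset_s"],
                duration_s=trial["duration_s"],
                target_deg=tuple(tdeg),
                eye=eye,
                subject=subject,
                condition=condition,
            )
            windows.append(w)
    return windows


@dataclass
class Experiment1Result:
    metrics: pd.DataFrame  # stratified per-subject and pooled metric table
    windows: list = field(default_factory=list)
    gaze: pd.DataFrame | None = None


def run_experiment1(
    n_subjects: int = 3,
    noise_px: float = 0.3,
    seed: int = 0,
    duration_s: float = 2.0,
    scene: SceneGeometry | None = None,
    asphericity: float = 0.0,
    conditions=("monocular", "binocular"),
    keep_gaze: bool = False,
    disparity_sd_deg: float = 0.3,
    calibration_duration_s: float = 10.0,
) -> Experiment1Result:
    """Fixation-grid accuracy/precision on a synthetic cohort.

    Per subject, kappa and fixation disparity are drawn from plausible
    population spreads, both eyes view the full grid under binocular (and
    optionally monocular, i.e. disparity-free single-eye) conditions, and
    the stratified metric table is computed after outlier rejection.
    """
    scene = scene or default_scene()
    rng = np.random.default_rng(seed)
    angles, positions = validation_target_grid()
    all_windows = []
    gaze_parts = []
    for s in range(n_subjects):
        subject = SubjectParams(
            kappa_left=(rng.normal(-5.0, 1.0), rng.normal(1.5, 0.75)),
            kappa_right=(rng.normal(5.0, 1.0), rng.normal(1.5, 0.75)),
            eso_disparity_deg=rng.normal(0.0, disparity_sd_deg) if disparity_sd_deg else 0.0,
            asphericity=asphericity,
        )
        cals = calibrate_subject(
            subject, scene, noise_px=noise_px,
            rng_seed=int(rng.integers(2**31 - 100)),
            duration_s=calibration_duration_s,
        )
        for condition in conditions:
            if condition == "monocular":
                eye_sets = (("left",), ("right",))
                sub = SubjectParams(**{**subject.__dict__, "eso_disparity_deg": 0.0})
            else:
                eye_sets = (("left", "right"),)
                sub = subject
            for eyes in eye_sets:
                sim = simulate_fixation_session(
                    positions,
                    scene=scene,
                    subject=sub,
                    duration_s=duration_s,
                    noise_px=noise_px,
                    rng_seed=int(rng.integers(2**31 - 100)),
                    include_saccade=True,
                    eyes=eyes,
                )
                gaze = reconstruct_stream(
                    sim.features, scene, {e: cals[e] for e in eyes}
                )
                all_windows.extend(
                    windows_from_session(
                        gaze,
                        sim.trials,
                        targets_deg=angles,
                        subject=f"s{s:03d}",
                        condition=condition,
                    )
                )
                if keep_gaze:
                    gaze_parts.append(gaze.assign(subject=f"s{s:03d}", condition=condition))
    metrics = stratify_and_aggregate(all_windows)
    return Experiment1Result(
        metrics=metrics,
        windows=all_windows,
        gaze=pd.concat(gaze_parts, ignore_index=True) if gaze_parts else None,
    )


def depth_series_targets(
    distances_mm=DEPTH_SERIES_MM,
    eye_z: float = 650.0,
    spread_mm: float = 40.0,
):
    """Five targets (centre plus 4 offsets) at each viewing distance of the
    wire-frame task, in screen coordinates (z = eye_z - distance)."""
    targets = []
    for d in distances_mm:
        z = eye_z - d
        targets += [
            (0.0, 0.0, z),
            (spread_mm, 0.0, z),
            (-spread_mm, 0.0, z),
            (0.0, spread_mm, z),
            (0.0, -spread_mm, z),
        ]
    return np.asarray(targets)


@dataclass
class Experiment2Result:
    vergence_fit: MixedFitResult
    mae_uncorrected: float
    mae_corrected: float
    per_window: pd.DataFrame
    pupil_fit: MixedFitResult | None = None
    pupil_spearman: tuple[float, float] | None = None
    pupil_table: pd.DataFrame | None = None


def _session_vergence_windows(
    sim: SimulationResult,
    scene: SceneGeometry,
    cals,
    subject_id: str,
) -> pd.DataFrame:
    """Per-fixation-window mean measured/target vergence for one session."""
    gaze = reconstruct_stream(sim.features, scene, cals)
    tmap = sim.truth[sim.truth["eye"] == "left"][
        ["timestamp_s", "target_x_mm", "target_y_mm", "target_z_mm"]
    ]
    vt = vergence_table(gaze, tmap)
    vt = vt.merge(
        sim.truth[sim.truth["eye"] == "left"][["timestamp_s", "trial"]], on="timestamp_s"
    )
    rows = []
    for (_, trial) in sim.trials.iterrows():
        t0, dur = trial["onset_s"], trial["duration_s"]
        win = vt[
            (vt["timestamp_s"] >= t0 + 0.6) & (vt["timestamp_s"] < t0 + dur - 0.5)
        ].dropna(subset=["alpha_measured_deg"])
        if len(win) == 0:
            continue
        rows.append(
            {
                "subject": subject_id,
                "trial": trial["trial"],
                "alpha_target_deg": win["alpha_target_deg"].mean(),
                "alpha_measured_deg": win["alpha_measured_deg"].mean(),
            }
        )
    return pd.DataFrame(rows)


def run_experiment2_depth(
    n_subjects: int = 5,
    noise_px: float = 0.3,
    seed: int = 0,
    duration_s: float = 2.0,
    disparity_sd_deg: float = 0.95,
    vergence_gain: float = 0.99,
    scene: SceneGeometry | None = None,
) -> Experiment2Result:
    """Depth-series vergence validation on a synthetic cohort with
    per-subject fixation disparities (SD ``disparity_sd_deg``) and a
    common vergence response gain."""
    scene = scene or default_scene()
    rng = np.random.default_rng(seed)
    targets = depth_series_targets()
    frames = []
    for s in range(n_subjects):
        subject = SubjectParams(
            kappa_left=(rng.normal(-5.0, 1.0), rng.normal(1.5, 0.75)),
            kappa_right=(rng.normal(5.0, 1.0), rng.normal(1.5, 0.75)),
            eso_disparity_deg=rng.normal(0.0, disparity_sd_deg),
            vergence_gain=vergence_gain,
        )
        cals = calibrate_subject(
            subject, scene, noise_px=noise_px, rng_seed=int(rng.integers(2**31 - 100))
        )
        sim = simulate_fixation_session(
            targets,
            scene=scene,
            subject=subject,
            duration_s=duration_s,
            noise_px=noise_px,
            rng_seed=int(rng.integers(2**31 - 100)),
        )
        frames.append(_session_vergence_windows(sim, scene, cals, f"s{s:03d}"))
    per_window = pd.concat(frames, ignore_index=True)
    fit = fit_random_intercept(
        per_window["alpha_target_deg"], per_window["alpha_measured_deg"], per_window["subject"]
    )
    mae_unc = vergence_mae(per_window["alpha_measured_deg"], per_window["alpha_target_deg"])
    mae_cor = subject_corrected_mae(
        per_window["alpha_measured_deg"],
        per_window["alpha_target_deg"],
        per_window["subject"],
        fit=fit,
    )
    return Experiment2Result(
        vergence_fit=fit,
        mae_uncorrected=mae_unc,
        mae_corrected=mae_cor,
        per_window=per_window,
    )


def run_experiment2_pupil(
    n_subjects: int = 5,
    noise_px: float = 0.3,
    seed: int = 0,
    levels: int = 5,
    duration_per_level_s: float = 2.0,
    scene: SceneGeometry | None = None,
) -> tuple[MixedFitResult, tuple[float, float], pd.DataFrame]:
    """Pupil-size series: mixed-model slope of measured vergence on
    projected pupil area, plus Spearman rank correlation, under the
    geometric (unbiased pupil-centre) forward model."""
    scene = scene or default_scene()
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subject = SubjectParams(
            kappa_left=(rng.normal(-5.0, 1.0), rng.normal(1.5, 0.75)),
            kappa_right=(rng.normal(5.0, 1.0), rng.normal(1.5, 0.75)),
            eso_disparity_deg=rng.normal(0.0, 0.3),
        )
        cals = calibrate_subject(
            subject, scene, noise_px=noise_px, rng_seed=int(rng.integers(2**31 - 100))
        )
        sim = simulate_pupil_series(
            scene=scene,
            subject=subject,
            levels=levels,
            duration_per_level_s=duration_per_level_s,
            noise_px=noise_px,
            rng_seed=int(rng.integers(2**31 - 100)),
        )
        gaze = reconstruct_stream(sim.features, scene, cals)
        tmap = sim.truth[sim.truth["eye"] == "left"][
            ["timestamp_s", "target_x_mm", "target_y_mm", "target_z_mm"]
        ]
        vt = vergence_table(gaze, tmap)
        feats1 = sim.features[(sim.features["cam"] == 1) & (sim.features["eye"] == "left")]
        for lvl in sorted(feats1["level"].unique()):
            t0 = lvl * duration_per_level_s
            t1 = t0 + duration_per_level_s
            win = vt[(vt["timestamp_s"] >= t0 + 0.6) & (vt["timestamp_s"] < t1 - 0.5)]
            area = feats1[
                (feats1["timestamp_s"] >= t0 + 0.6) & (feats1["timestamp_s"] < t1 - 0.5)
            ]["pupil_area_px2"].mean()
            rows.append(
                {
                    "subject": f"s{s:03d}",
                    "level": lvl,
                    "pupil_area_px2": area,
                    "alpha_measured_deg": win["alpha_measured_deg"].mean(),
                }
            )
    table = pd.DataFrame(rows)
    fit = fit_random_intercept(
        table["pupil_area_px2"], table["alpha_measured_deg"], table["subject"]
    )
    rho = spearman_rho(table["pupil_area_px2"], table["alpha_measured_deg"])
    return fit, rho, table


def run_experiment2(
    n_subjects: int = 5,
    noise_px: float = 0.3,
    seed: int = 0,
    duration_s: float = 2.0,
    levels: int = 5,
    scene: SceneGeometry | None = None,
) -> Experiment2Result:
    """Full second experiment: depth series plus pupil-size series."""
    res = run_experiment2_depth(
        n_subjects=n_subjects, noise_px=noise_px, seed=seed, duration_s=duration_s, scene=scene
    )
    pupil_fit, rho, table = run_experiment2_pupil(
        n_subjects=n_subjects,
        noise_px=noise_px,
        seed=seed + 1,
        levels=levels,
        duration_per_level_s=duration_s,
        scene=scene,
    )
    res.pupil_fit = pupil_fit
    res.pupil_spearman = rho
    res.pupil_table = table
    return res
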