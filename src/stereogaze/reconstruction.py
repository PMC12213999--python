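"""Stereo gaze reconstruction.

From per-camera pupil/glint pixel features and the rig geometry, this
module reconstructs, per frame and per eye:

* the corneal centre of curvature ``c`` — from the two glints in each
  camera: each (camera, light, glint) triple defines a plane containing
  ``c``; the two planes of one camera intersect in a ray through the
  camera origin toward ``c``, and the two cameras' rays are triangulated.
  No corneal-radius constant is involved.
* the virtual pupil centre ``p_v`` — triangulated from the back-projected
  pupil-centre rays, optionally refined under the constraint that
  ``|c - p_v|`` is a fixed per-eye distance estimated during calibration
  (which improves precision under pixel noise).
* the optical axis (through ``c`` and ``p_v``), the visual axis (optical
  axis offset by the calibrated angle kappa), and the point of gaze (POG),
  i.e. the intersection of the visual axis with the screen.

Kappa is calibrated from a single monocular fixation target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .eye import EyeState, direction_from_fick, fick_angles
from .geometry import (
    DegenerateGeometryError,
    Plane,
    Ray,
    as_vec3,
    intersect_line_plane,
    intersect_planes,
    normalize,
    triangulate_rays,
)
from .scene import SceneGeometry


class CalibrationError(RuntimeError):
    """Raised when too few valid frames are available to estimate kappa."""


@dataclass
class KappaCalibration:
    """Single-point calibration result for one eye."""

    kappa_h: float  # deg
    kappa_v: float  # deg
    cp_distance: float  # estimated |c - p_v|, mm
    s0: np.ndarray  # calibration target, mm
    n_frames: int = 0

    def __post_init__(self):
        self.s0 = as_vec3(self.s0)
        if abs(self.kappa_h) >= 15 or abs(self.kappa_v) >= 15:
            raise CalibrationError(
                f"implausible kappa ({self.kappa_h:.2f}, {self.kappa_v:.2f}) deg"
            )
        if not (1.0 < self.cp_distance < 10.0):
            raise CalibrationError(
                f"implausible |c - p_v| = {self.cp_distance:.2f} mm"
            )


# ---------------------------------------------------------------------------
# stream synchronization

_SYNC_COLS = [
    "pupil_x_px",
    "pupil_y_px",
    "pupil_area_px2",
    "glint1_x_px",
    "glint1_y_px",
    "glint2_x_px",
    "glint2_y_px",
]


def synchronize_streams(cam1: pd.DataFrame, cam2: pd.DataFrame) -> pd.DataFrame:
    """Interpolate camera-2 features onto camera-1 timestamps.

    Linear interpolation per column; a NaN camera-2 sample poisons the
    camera-1 timestamps it brackets (no interpolation across gaps).
    Camera-1 timestamps outside the camera-2 range get NaN.  Returns a
    frame on camera-1 timestamps with ``*_cam1`` / ``*_cam2`` columns.
    """
    t1 = cam1["timestamp_s"].to_numpy(float)
    t2 = cam2["timestamp_s"].to_numpy(float)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("empty feature stream")
    if not (np.all(np.diff(t1) >= 0) and np.all(np.diff(t2) >= 0)):
        raise ValueError("feature streams must be time-sorted")
    if t1[-1] < t2[0] or t2[-1] < t1[0]:
        raise ValueError("camera streams do not overlap in time")

    out = {"timestamp_s": t1}
    for col in _SYNC_COLS:
        if col in cam1.columns:
            out[f"{col}_cam1"] = cam1[col].to_numpy(float)
    idx = np.searchsorted(t2, t1, side="right") - 1
    for col in _SYNC_COLS:
        if col not in cam2.columns:
            continue
        v2 = cam2[col].to_numpy(float)
        vals = np.full(len(t1), np.nan)
        for i, (t, j) in enumerate(zip(t1, idx)):
            if j < 0 or j >= len(t2):
                continue
            if t2[j] == t:
                vals[i] = v2[j]
                continue
            if j + 1 >= len(t2):
                continue
            lo, hi = v2[j], v2[j + 1]
            if np.isnan(lo) or np.isnan(hi):
                continue
            w = (t - t2[j]) / (t2[j + 1] - t2[j])
            vals[i] = lo + w * (hi - lo)
        out[f"{col}_cam2"] = vals
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# per-frame geometry

def _glint_plane(camera, light, glint_px) -> Plane:
    """Plane through the camera origin, the light source and the
    back-projected glint ray; the reflection law puts ``c`` in it."""
    ray = camera.back_project(glint_px)
    n = np.cross(as_vec3(light) - camera.origin, ray.direction)
    return Plane(camera.origin, n)


def reconstruct_corneal_center(
    glints_cam1, glints_cam2, scene: SceneGeometry
) -> tuple[np.ndarray, float]:
    """Corneal centre of curvature from the two glints in both cameras.

    ``glints_cam{1,2}`` are ((g1x, g1y), (g2x, g2y)) pixel pairs, ordered by
    light source.  Returns (c, triangulation gap in mm).
    """
    rays = []
    for cam, glints in zip(scene.cameras, (glints_cam1, glints_cam2)):
        p1 = _glint_plane(cam, scene.light1, glints[0])
        p2 = _glint_plane(cam, scene.light2, glints[1])
        line = intersect_planes(p1, p2, through=cam.origin)
        # orient toward the subject (same half-space as the glint rays)
        ref = cam.back_project(glints[0]).direction
        d = line.direction if np.dot(line.direction, ref) >= 0 else -line.direction
        rays.append(Ray(cam.origin, d))
    return triangulate_rays(rays[0], rays[1])


def _constrained_pv(rays: list[Ray], c: np.ndarray, K: float, p0: np.ndarray) -> np.ndarray:
    """Point minimizing summed squared distance to the rays subject to
    ``|p - c| = K`` (Lagrange system solved by a 1-D root solve on the
    multiplier)."""
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for r in rays:
        Ai = np.eye(3) - np.outer(r.direction, r.direction)
        A += Ai
        b += Ai @ r.origin

    eye3 = np.eye(3)

    def p_of(lam):
        return np.linalg.solve(A - lam * eye3, b - lam * c)

    def g(lam):
        return np.linalg.norm(p_of(lam) - c) - K

    # ||p(lam) - c|| is monotonically increasing on (-inf, lam_min(A));
    # Newton from 0 converges in a few steps since the constraint is nearly
    # satisfied at the unconstrained optimum
    lam_max = np.linalg.eigvalsh(A)[0]  # smallest eigenvalue of A
    lam = 0.0
    ok = False
    for _ in range(30):
        gl = g(lam)
        if abs(gl) < 1e-12:
            ok = True
            break
        h = 1e-7
        dg = (g(lam + h) - gl) / h
        if dg <= 0:
            break
        step = -gl / dg
        new = lam + step
        if new >= 0.95 * lam_max:
            new = 0.5 * (lam + 0.95 * lam_max)
        lam = new
    if not ok:
        lo, hi = -2.0, 0.95 * lam_max
        if g(lo) * g(hi) > 0:
            # constraint unreachable along the multiplier path: radial
            # projection of the unconstrained optimum
            return c + K * normalize(p0 - c)
        lam = brentq(g, lo, hi, xtol=1e-12)
    return p_of(lam)


def reconstruct_virtual_pupil(
    pupil_cam1,
    pupil_cam2,
    scene: SceneGeometry,
    c: np.ndarray | None = None,
    cp_distance: float | None = None,
) -> tuple[np.ndarray, float]:
    """Virtual pupil centre from the two cameras' pupil-centre pixels.

    Plain ray triangulation; when ``cp_distance`` (the calibrated
    ``|c - p_v|``) and ``c`` are given, the estimate is refined to the
    point at that distance from ``c`` minimizing the summed squared
    distance to both rays.  Returns (p_v, triangulation gap in mm).
    """
    rays = [
        cam.back_project(px) for cam, px in zip(scene.cameras, (pupil_cam1, pupil_cam2))
    ]
    p_raw, gap = triangulate_rays(rays[0], rays[1])
    if cp_distance is None or c is None:
        return p_raw, gap
    return _constrained_pv(rays, as_vec3(c), float(cp_distance), p_raw), gap


def _frame_state(row, scene, cp_distance=None) -> EyeState | None:
    """EyeState (without visual axis) from one synchronized feature row;
    None when any required feature is NaN."""
    need = [
        row[f"glint{g}_{a}_px_cam{c}"] for g in (1, 2) for a in ("x", "y") for c in (1, 2)
    ] + [row[f"pupil_{a}_px_cam{c}"] for a in ("x", "y") for c in (1, 2)]
    if np.any(np.isnan(need)):
        return None
    g1 = (
        (row["glint1_x_px_cam1"], row["glint1_y_px_cam1"]),
        (row["glint2_x_px_cam1"], row["glint2_y_px_cam1"]),
    )
    g2 = (
        (row["glint1_x_px_cam2"], row["glint1_y_px_cam2"]),
        (row["glint2_x_px_cam2"], row["glint2_y_px_cam2"]),
    )
    c, gap_c = reconstruct_corneal_center(g1, g2, scene)
    pv, gap_pv = reconstruct_virtual_pupil(
        (row["pupil_x_px_cam1"], row["pupil_y_px_cam1"]),
        (row["pupil_x_px_cam2"], row["pupil_y_px_cam2"]),
        scene,
        c=c,
        cp_distance=cp_distance,
    )
    return EyeState(
        c=c,
        p_v=pv,
        optical_axis=normalize(pv - c),
        timestamp=float(row["timestamp_s"]),
        quality_gap_c=gap_c,
        quality_gap_pv=gap_pv,
    )


# ---------------------------------------------------------------------------
# kappa calibration and gaze

def calibrate_kappa(
    synced: pd.DataFrame,
    scene: SceneGeometry,
    s0,
    min_frames: int = 10,
) -> KappaCalibration:
    """Estimate kappa for one eye from a monocular fixation of target ``s0``.

    Two passes.  First, the virtual pupil is triangulated without
    constraints and the per-eye distance ``K = median |c - p_v|`` is
    estimated.  Second, the optical axes are re-reconstructed under the
    fixed-distance constraint (which suppresses the depth noise that
    otherwise leaks into the vertical axis component) and compared, in Fick
    angles, with the direction from ``c`` to ``s0``; kappa is the per-axis
    median of the differences.  Medians make both passes robust to
    occasional bad frames.
    """
    s0 = as_vec3(s0)
    dists = []
    for _, row in synced.iterrows():
        state = _frame_state(row, scene)
        if state is not None:
            dists.append(np.linalg.norm(state.p_v - state.c))
    if len(dists) < min_frames:
        raise CalibrationError(
            f"only {len(dists)} valid frames (< {min_frames}) for kappa calibration"
        )
    K = float(np.median(dists))
    dh, dv = [], []
    for _, row in synced.iterrows():
        state = _frame_state(row, scene, cp_distance=K)
        if state is None:
            continue
        oh, ov = fick_angles(state.optical_axis)
        th, tv = fick_angles(s0 - state.c)
        dh.append(th - oh)
        dv.append(tv - ov)
    return KappaCalibration(
        kappa_h=float(np.median(dh)),
        kappa_v=float(np.median(dv)),
        cp_distance=K,
        s0=s0,
        n_frames=len(dh),
    )


def visual_axis(state: EyeState, cal: KappaCalibration) -> np.ndarray:
    """Visual axis: the optical axis offset by kappa in Fick-angle space."""
    h, v = fick_angles(state.optical_axis)
    return direction_from_fick(h + cal.kappa_h, v + cal.kappa_v)


def point_of_gaze(state: EyeState, screen_plane: Plane) -> np.ndarray:
    """Intersection of the visual axis (from ``c``) with the screen plane."""
    if state.visual_axis is None:
        raise ValueError("visual axis not set; apply a kappa calibration first")
    return intersect_line_plane(Ray(state.c, state.visual_axis), screen_plane)


def gaze_angles(pog_x_mm: float, pog_y_mm: float, viewing_distance: float = 650.0):
    """Screen position (mm) to gaze angles (deg) of a theoretical eye on the
    screen's z-axis at ``viewing_distance`` (Fick convention, horizontal
    first; positive = left/down)."""
    gx = np.degrees(np.arctan2(pog_x_mm, viewing_distance))
    gy = np.degrees(np.arctan2(pog_y_mm, np.hypot(pog_x_mm, viewing_distance)))
    return float(gx), float(gy)


def angles_to_screen(gx_deg: float, gy_deg: float, viewing_distance: float = 650.0):
    """Inverse of :func:`gaze_angles`: gaze angles (deg) to screen mm."""
    x = viewing_distance * np.tan(np.radians(gx_deg))
    y = np.hypot(x, viewing_distance) * np.tan(np.radians(gy_deg))
    return float(x), float(y)


# ---------------------------------------------------------------------------
# stream-level driver

GAZE_COLUMNS = [
    "timestamp_s",
    "eye",
    "c_x", "c_y", "c_z",
    "pv_x", "pv_y", "pv_z",
    "oa_x", "oa_y", "oa_z",
    "va_x", "va_y", "va_z",
    "pog_x_mm", "pog_y_mm",
    "gx_deg", "gy_deg",
    "quality_gap_c_mm", "quality_gap_pv_mm",
]


def reconstruct_stream(
    features: pd.DataFrame,
    scene: SceneGeometry,
    calibrations: dict[str, KappaCalibration],
    use_cp_constraint: bool = True,
    viewing_distance: float = 650.0,
) -> pd.DataFrame:
    """Full per-frame reconstruction of a feature stream (both cameras, one
    or both eyes) into a tidy gaze table.  NaN frames yield NaN samples."""
    out_rows = []
    for eye_id, cal in calibrations.items():
        sub = features[features["eye"] == eye_id]
        cam1 = sub[sub["cam"] == 1].sort_values("timestamp_s")
        cam2 = sub[sub["cam"] == 2].sort_values("timestamp_s")
        synced = synchronize_streams(cam1, cam2)
        K = cal.cp_distance if use_cp_constraint else None
        for _, row in synced.iterrows():
            state = _frame_state(row, scene, cp_distance=K)
            rec = {"timestamp_s": row["timestamp_s"], "eye": eye_id}
            if state is None:
                rec.update({k: np.nan for k in GAZE_COLUMNS[2:]})
            else:
                state.visual_axis = visual_axis(state, cal)
                try:
                    pog = point_of_gaze(state, scene.screen.plane)
                    pog_xy = scene.screen.to_screen_xy(pog)
                    gx, gy = gaze_angles(pog_xy[0], pog_xy[1], viewing_distance)
                except DegenerateGeometryError:
                    pog_xy = np.array([np.nan, np.nan])
                    gx = gy = np.nan
                rec.update(
                    {
                        "c_x": state.c[0], "c_y": state.c[1], "c_z": state.c[2],
                        "pv_x": state.p_v[0], "pv_y": state.p_v[1], "pv_z": state.p_v[2],
                        "oa_x": state.optical_axis[0],
                        "oa_y": state.optical_axis[1],
                        "oa_z": state.optical_axis[2],
                        "va_x": state.visual_axis[0],
                        "va_y": state.visual_axis[1],
                        "va_z": state.visual_axis[2],
                        "pog_x_mm": pog_xy[0], "pog_y_mm": pog_xy[1],
                        "gx_deg": gx, "gy_deg": gy,
                        "quality_gap_c_mm": state.quality_gap_c,
                        "quality_gap_pv_mm": state.quality_gap_pv,
                    }
                )
            out_rows.append(rec)
    return pd.DataFrame(out_rows, columns=GAZE_COLUMNS)
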