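"""Vergence: target and measured vergence angles, their MAE, and the
depth-from-vergence conversion.

The centre of rotation (COR) of each eye is placed 13.5 mm behind the
corneal vertex along the optical axis; with corneal radius ``r`` this is
``COR = c - (13.5 - r) * OA``.  Target vergence follows from the triangle
(COR_left, COR_right, target) by the cosine law; measured vergence is the
angle between the two visual axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import angle_between, as_vec3, normalize


def center_of_rotation(c, optical_axis, r: float = 7.72, vertex_to_cor: float = 13.5):
    """COR = c - (vertex_to_cor - r) * OA  (all mm; OA a unit vector)."""
    return as_vec3(c) - (vertex_to_cor - r) * normalize(optical_axis)


def interocular_distance(cor_left, cor_right) -> float:
    """IOD = ||COR_left - COR_right|| in mm."""
    return float(np.linalg.norm(as_vec3(cor_left) - as_vec3(cor_right)))


def target_vergence(cor_left, cor_right, target) -> float:
    """Vergence angle (deg) demanded by a target, by the cosine law on the
    triangle formed by the two CORs and the target."""
    cor_left = as_vec3(cor_left)
    cor_right = as_vec3(cor_right)
    t = as_vec3(target)
    d_left = np.linalg.norm(cor_left - t)
    d_right = np.linalg.norm(cor_right - t)
    if d_left < 1e-12 or d_right < 1e-12:
        raise ValueError("target coincides with an eye's centre of rotation")
    iod = interocular_distance(cor_left, cor_right)
    arg = (d_left**2 + d_right**2 - iod**2) / (2 * d_left * d_right)
    return float(np.degrees(np.arccos(np.clip(arg, -1.0, 1.0))))


def measured_vergence(va_left, va_right) -> float:
    """Angle (deg) between the two visual axes (combined horizontal and
    vertical vergence)."""
    return angle_between(va_left, va_right)


def vergence_mae(measured, target) -> float:
    """Mean absolute vergence error (deg); NaNs excluded pairwise."""
    m = np.asarray(measured, dtype=float)
    t = np.asarray(target, dtype=float)
    if m.shape != t.shape:
        raise ValueError("measured and target series must have equal length")
    ok = ~(np.isnan(m) | np.isnan(t))
    if not np.any(ok):
        raise ValueError("no valid (non-NaN) pairs")
    return float(np.mean(np.abs(m[ok] - t[ok])))


def symmetric_target_vergence(distance_mm: float, iod_mm: float = 60.0) -> float:
    """Vergence (deg) for symmetric fixation of a target ``distance_mm``
    ahead of the midpoint of a baseline of length ``iod_mm``."""
    return float(np.degrees(2.0 * np.arctan2(iod_mm / 2.0, distance_mm)))


def depth_from_vergence(alpha_deg: float, iod_mm: float = 60.0) -> float:
    """Fixation distance (mm) from a vergence angle, assuming symmetric
    fixation on the perpendicular bisector of the interocular baseline:
    ``distance = (IOD/2) / tan(alpha/2)``.  Exact inverse of
    :func:`symmetric_target_vergence`."""
    if not (0.0 < alpha_deg < 180.0):
        raise ValueError("vergence angle must lie in (0, 180) degrees")
    return float((iod_mm / 2.0) / np.tan(np.radians(alpha_deg) / 2.0))


def fick_vergence_components(va_left, va_right) -> tuple[float, float]:
    """Auxiliary horizontal/vertical vergence components (deg) as Fick-angle
    differences between the two visual axes.  The total angle
    (:func:`measured_vergence`) is the primary quantity; this decomposition
    is a convenience output."""
    from .eye import fick_angles

    hl, vl = fick_angles(va_left)
    hr, vr = fick_angles(va_right)
    return float(hl - hr), float(vl - vr)


def vergence_table(
    gaze: pd.DataFrame,
    targets: pd.DataFrame,
    r: float = 7.72,
    vertex_to_cor: float = 13.5,
) -> pd.DataFrame:
    """Per-timestamp vergence record from a binocular gaze table.

    ``gaze`` is the tidy output of the reconstruction (rows for eyes
    'left' and 'right' on shared timestamps); ``targets`` maps each
    timestamp to the fixated 3-D target (columns ``timestamp_s``,
    ``target_x_mm``, ``target_y_mm``, ``target_z_mm``).
    """
    left = gaze[gaze["eye"] == "left"].set_index("timestamp_s")
    right = gaze[gaze["eye"] == "right"].set_index("timestamp_s")
    common = left.index.intersection(right.index)
    tmap = targets.set_index("timestamp_s")
    rows = []
    for ts in common:
        lr, rr = left.loc[ts], right.loc[ts]
        rec = {"timestamp_s": ts}
        vals = [lr[k] for k in ("c_x", "oa_x", "va_x")] + [rr[k] for k in ("c_x", "oa_x", "va_x")]
        if np.any(np.isnan(vals)) or ts not in tmap.index:
            rec.update(
                alpha_target_deg=np.nan, alpha_measured_deg=np.nan,
                d_left_mm=np.nan, d_right_mm=np.nan, iod_mm=np.nan,
            )
        else:
            cor_l = center_of_rotation(
                [lr["c_x"], lr["c_y"], lr["c_z"]],
                [lr["oa_x"], lr["oa_y"], lr["oa_z"]],
                r, vertex_to_cor,
            )
            cor_r = center_of_rotation(
                [rr["c_x"], rr["c_y"], rr["c_z"]],
                [rr["oa_x"], rr["oa_y"], rr["oa_z"]],
                r, vertex_to_cor,
            )
            t = tmap.loc[ts]
            tg = [t["target_x_mm"], t["target_y_mm"], t["target_z_mm"]]
            rec.update(
                alpha_target_deg=target_vergence(cor_l, cor_r, tg),
                alpha_measured_deg=measured_vergence(
                    [lr["va_x"], lr["va_y"], lr["va_z"]],
                    [rr["va_x"], rr["va_y"], rr["va_z"]],
                ),
                d_left_mm=float(np.linalg.norm(cor_l - np.asarray(tg, float))),
                d_right_mm=float(np.linalg.norm(cor_r - np.asarray(tg, float))),
                iod_mm=interocular_distance(cor_l, cor_r),
            )
        rows.append(rec)
    return pd.DataFrame(rows)
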