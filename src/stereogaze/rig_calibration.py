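"""Mirror-based localization of the light sources and the screen.

The IR light sources and the monitor sit behind the cameras' line of
sight, so they are observed indirectly: a planar mirror (whose pose is
known from a dot pattern on its reflective surface) shows virtual stereo
images of the lights and of a dot pattern attached to the screen.  The
virtual points are triangulated in 3-D and the law of reflection converts
them into real positions.
"""

from __future__ import annotations

import warnings

import numpy as np

from .camera import CameraModel
from .geometry import Plane, as_vec3, fit_plane, normalize, reflect_point, triangulate_rays
from .scene import Screen

CORRESPONDENCE_GAP_MM = 2.0


def triangulate_virtual_points(
    pixel_pairs,
    cam1: CameraModel,
    cam2: CameraModel,
    gap_warn_mm: float = CORRESPONDENCE_GAP_MM,
):
    """Triangulate pixel correspondences into 3-D points.

    ``pixel_pairs`` is a sequence of ((u1, v1), (u2, v2)).  Returns
    ``(points (n, 3), gaps (n,))``; a gap above ``gap_warn_mm`` (likely a
    bad correspondence) raises a warning but keeps the point.
    """
    points, gaps = [], []
    for i, (p1, p2) in enumerate(pixel_pairs):
        pt, gap = triangulate_rays(cam1.back_project(p1), cam2.back_project(p2))
        if gap > gap_warn_mm:
            warnings.warn(
                f"correspondence {i}: triangulation gap {gap:.2f} mm exceeds "
                f"{gap_warn_mm} mm — check the pairing"
            )
        points.append(pt)
        gaps.append(gap)
    return np.asarray(points), np.asarray(gaps)


def recover_real_positions(virtual_points, mirror: Plane) -> np.ndarray:
    """Reflect triangulated virtual points in the mirror plane to obtain the
    real positions of the (directly invisible) sources."""
    return np.asarray([reflect_point(p, mirror) for p in np.atleast_2d(virtual_points)])


def estimate_mirror_plane(mirror_dots_3d) -> tuple[Plane, float]:
    """Mirror pose from its own (real, directly visible) surface dots:
    total-least-squares plane fit.  Returns (plane, RMS residual in mm)."""
    return fit_plane(np.asarray(mirror_dots_3d, dtype=float))


def recover_screen_pose(
    virtual_dots,
    mirror: Plane,
    dot_layout,
    width_mm: float = 527.0,
    height_mm: float = 296.0,
    orient_toward=None,
) -> tuple[Screen, float]:
    """Screen frame from virtual images of the screen-mounted dot pattern.

    ``dot_layout`` gives the pattern's known 2-D coordinates (mm) with
    (0, 0) at the pattern centre, which is aligned with the screen centre.
    The virtual dots are reflected to real space, a total-least-squares
    plane is fitted, and the 2-D layout is registered to the in-plane dot
    coordinates with a rigid (Kabsch) fit.  Returns (screen, RMS planarity
    residual in mm).  ``orient_toward`` (e.g. a camera origin) fixes the
    normal's sign; default leaves it toward +z.
    """
    layout = np.asarray(dot_layout, dtype=float)
    if layout.ndim != 2 or layout.shape[1] != 2 or layout.shape[0] < 3:
        raise ValueError("dot_layout must be (n>=3, 2)")
    real = recover_real_positions(virtual_dots, mirror)
    if len(real) != len(layout):
        raise ValueError("layout and dot counts differ")
    plane, resid = fit_plane(real)
    normal = plane.normal
    if orient_toward is not None:
        if np.dot(as_vec3(orient_toward) - plane.point, normal) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    # orthonormal in-plane basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, normal)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = normalize(seed - normal * np.dot(seed, normal))
    e2 = np.cross(normal, e1)
    centroid = real.mean(axis=0)
    dots2d = np.column_stack([(real - centroid) @ e1, (real - centroid) @ e2])
    lay_c = layout - layout.mean(axis=0)
    # 2-D Kabsch: rotation taking layout coordinates into the plane basis
    H = lay_c.T @ dots2d
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R2 = (U @ np.diag([1.0, d]) @ Vt).T
    x_axis = R2[0, 0] * e1 + R2[1, 0] * e2
    # screen centre = image of the layout origin
    center2 = R2 @ (-layout.mean(axis=0))
    center = centroid + center2[0] * e1 + center2[1] * e2
    screen = Screen(
        center=center, normal=normal, x_axis=x_axis, width_mm=width_mm, height_mm=height_mm
    )
    return screen, resid
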