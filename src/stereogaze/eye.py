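"""Schematic model eye and gaze-direction conventions.

The eye is modelled with a spherical cornea of radius ``r`` (default
7.72 mm) whose best-fit centre ``c`` lies on the optical axis, a centre of
rotation (COR) 13.5 mm behind the corneal vertex, and a pupil in a plane a
few mm behind the vertex.  The optical axis runs from ``c`` out through the
pupil centre toward the scene; the visual axis deviates from it by the
subject- and eye-specific angle kappa, expressed as horizontal/vertical
Fick-angle offsets.

Fick convention used throughout: for a unit gaze direction ``d`` (pointing
from the eye toward the screen, i.e. with negative z in the screen frame),

    horizontal = atan2(d_x, -d_z)        (positive = leftward, +x)
    vertical   = atan2(d_y, hypot(d_x, d_z))   (positive = downward, +y)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import as_vec3, normalize


def fick_angles(direction) -> tuple[float, float]:
    """(horizontal, vertical) Fick angles in degrees of a gaze direction."""
    d = normalize(direction)
    h = np.degrees(np.arctan2(d[0], -d[2]))
    v = np.degrees(np.arctan2(d[1], np.hypot(d[0], d[2])))
    return float(h), float(v)


def direction_from_fick(h_deg: float, v_deg: float) -> np.ndarray:
    """Unit gaze direction from (horizontal, vertical) Fick angles in degrees."""
    h = np.radians(h_deg)
    v = np.radians(v_deg)
    return np.array([np.cos(v) * np.sin(h), np.sin(v), -np.cos(v) * np.cos(h)])


def rotate_fick(direction, dh_deg: float, dv_deg: float) -> np.ndarray:
    """Offset a gaze direction by (dh, dv) degrees in Fick-angle space."""
    h, v = fick_angles(direction)
    return direction_from_fick(h + dh_deg, v + dv_deg)


@dataclass
class ModelEye:
    """Ground-truth schematic eye used by the simulator.

    Parameters
    ----------
    cor : (3,) array
        Centre of rotation in scene coordinates (mm).
    optical_axis : (3,) array
        Unit vector from the corneal centre out toward the scene.
    kappa_h, kappa_v : float
        Angle between optical and visual axis, degrees (Fick offsets).
    corneal_radius : float
        Radius of the best-fit corneal sphere, mm.
    vertex_to_cor : float
        Distance from the corneal vertex back to the COR along the optical
        axis, mm.
    pupil_radius : float
        Physical pupil radius, mm.
    pupil_plane_depth : float
        Depth of the pupil plane behind the corneal vertex, mm (schematic-eye
        convention; affects only the forward model, not reconstruction).
    refractive_index : float
        Effective corneal/aqueous refractive index (keratometric convention).
    asphericity : float
        Optional perturbation: fractional flattening of the effective local
        corneal radius with angular distance from the apex,
        ``r_eff = r * (1 + asphericity * theta_apex_rad**2)``.  Zero keeps the
        cornea perfectly spherical (the reconstruction model's assumption).
    pupil_model : str
        ``"rigid"`` (default): the virtual pupil is a single entrance-pupil
        point on the optical axis, at the paraxial refracted depth of the
        pupil plane, rotating rigidly with the eye — the model assumed by
        the stereo reconstruction.  ``"refracted"``: each camera sees the
        pupil centre through its own finite-angle Snell refraction at the
        corneal sphere, which displaces the apparent pupil slightly off
        axis in a view-dependent way (a genuine aberration of
        pupil/corneal-reflection trackers that biases gaze by ~0.05-0.3 deg
        across the measurement range).
    """

    cor: np.ndarray
    optical_axis: np.ndarray
    kappa_h: float = 0.0
    kappa_v: float = 0.0
    corneal_radius: float = 7.72
    vertex_to_cor: float = 13.5
    pupil_radius: float = 2.0
    pupil_plane_depth: float = 3.6
    refractive_index: float = 1.3375
    asphericity: float = 0.0
    pupil_model: str = "rigid"

    def __post_init__(self):
        if self.pupil_model not in ("rigid", "refracted"):
            raise ValueError("pupil_model must be 'rigid' or 'refracted'")
        self.cor = as_vec3(self.cor)
        self.optical_axis = normalize(self.optical_axis)
        if self.corneal_radius <= 0:
            raise ValueError("corneal_radius must be positive")
        if self.vertex_to_cor <= 0:
            raise ValueError("vertex_to_cor must be positive")
        if not (0 < self.pupil_radius < self.corneal_radius):
            raise ValueError("pupil_radius must lie in (0, corneal_radius)")

    # -- derived anatomy ----------------------------------------------------
    @property
    def corneal_center(self) -> np.ndarray:
        """Centre c of the corneal sphere: COR + (vertex_to_cor - r) * OA."""
        return self.cor + (self.vertex_to_cor - self.corneal_radius) * self.optical_axis

    @property
    def corneal_vertex(self) -> np.ndarray:
        return self.cor + self.vertex_to_cor * self.optical_axis

    @property
    def pupil_center(self) -> np.ndarray:
        """Real (unrefracted) pupil centre on the optical axis."""
        return self.corneal_vertex - self.pupil_plane_depth * self.optical_axis

    @property
    def virtual_pupil_distance(self) -> float:
        """Distance (mm) from ``c`` to the entrance pupil: the paraxial
        refracted image of the pupil plane, found by tracing a marginal
        axial ray through the corneal sphere and intersecting its backward
        extension with the optical axis."""
        r = self.corneal_radius
        n = self.refractive_index
        p_ax = r - self.pupil_plane_depth  # pupil centre along axis, from c
        theta = 1e-4  # marginal-ray surface angle, rad
        s_ax, s_t = r * np.cos(theta), r * np.sin(theta)  # surface point
        inc = np.array([s_ax - p_ax, s_t])
        inc = inc / np.linalg.norm(inc)
        nrm = np.array([np.cos(theta), np.sin(theta)])
        cos1 = np.dot(inc, nrm)
        sin2 = n * np.sqrt(max(0.0, 1 - cos1**2))  # Snell, inside -> air
        cos2 = np.sqrt(1 - sin2**2)
        out = n * inc + (cos2 - n * cos1) * nrm
        mu = -s_t / out[1]  # back to the axis
        return float(s_ax + mu * out[0])

    @property
    def entrance_pupil(self) -> np.ndarray:
        """Rigid virtual-pupil point on the optical axis."""
        return self.corneal_center + self.virtual_pupil_distance * self.optical_axis

    @property
    def visual_axis(self) -> np.ndarray:
        return rotate_fick(self.optical_axis, self.kappa_h, self.kappa_v)

    def oriented_to(self, target, extra_h: float = 0.0, extra_v: float = 0.0) -> "ModelEye":
        """Copy of this eye rotated (about its COR) so the visual axis points
        at ``target``, optionally offset by (extra_h, extra_v) degrees — used
        to inject a fixation disparity.

        Solved by fixed-point iteration: the corneal centre moves with the
        optical axis, so the desired visual-axis direction depends weakly on
        the solution; convergence is fast because |c - COR| << viewing
        distance.
        """
        target = as_vec3(target)
        oa = normalize(target - self.cor)
        for _ in range(50):
            c = self.cor + (self.vertex_to_cor - self.corneal_radius) * oa
            va = normalize(target - c)
            h, v = fick_angles(va)
            oa_new = direction_from_fick(h + extra_h - self.kappa_h, v + extra_v - self.kappa_v)
            if np.linalg.norm(oa_new - oa) < 1e-15:
                oa = oa_new
                break
            oa = oa_new
        out = ModelEye(**{**self.__dict__})
        out.optical_axis = oa
        return out


@dataclass
class EyeState:
    """Reconstructed (or ground-truth) state of one eye at one instant."""

    c: np.ndarray  # corneal centre of curvature, mm
    p_v: np.ndarray  # virtual pupil centre, mm
    optical_axis: np.ndarray  # unit, from c through p_v
    visual_axis: np.ndarray | None = None  # unit; None before kappa is applied
    timestamp: float = 0.0
    quality_gap_c: float = 0.0  # triangulation gap for c, mm
    quality_gap_pv: float = 0.0  # triangulation gap for p_v, mm
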