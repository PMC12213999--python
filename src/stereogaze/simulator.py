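"""Physically based forward model of the binocular eye-tracking rig.

A schematic eye with a spherical cornea is viewed by the stereo camera
pair while two infrared sources produce first-Purkinje-image glints.  The
simulator solves the specular-reflection (Alhazen) problem for each glint
and traces Snell refraction through the cornea for the pupil centre, then
projects everything through the pinhole cameras.  It produces ideal or
pixel-noise-corrupted feature streams together with full ground truth, and
serves as the test oracle for the reconstruction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.measure import EllipseModel

from .camera import CameraModel
from .eye import EyeState, ModelEye, fick_angles
from .geometry import Ray, as_vec3, normalize, triangulate_rays
from .scene import SceneGeometry, default_scene


def fit_ellipse(points) -> tuple[float, float, float, float, float] | None:
    """Least-squares ellipse fit; returns (xc, yc, a, b, theta) or None."""
    model = EllipseModel.from_estimate(np.asarray(points, dtype=float))
    if not model:
        return None
    (xc, yc), (a, b) = model.center, model.axis_lengths
    return float(xc), float(yc), float(a), float(b), float(model.theta)

#: angular half-width of the reflective corneal cap about the optical axis;
#: a glint falling outside the cap is off the cornea (onto the sclera) and
#: is treated as occluded/undetectable.  The anatomical limbus sits near
#: 50 deg from the apex and the specular tear film extends slightly beyond
#: it; with this margin the cap keeps glints alive across the rig's
#: +/-21 x +/-10 deg target range (max apex angle ~51.5 deg, matching the
#: physical system, which tracked the full grid) while occluding them for
#: extreme (~40 deg temporal) eye rotations.
CORNEAL_CAP_DEG = 53.0

FEATURE_COLUMNS = [
    "timestamp_s",
    "cam",
    "eye",
    "pupil_x_px",
    "pupil_y_px",
    "pupil_area_px2",
    "glint1_x_px",
    "glint1_y_px",
    "glint2_x_px",
    "glint2_y_px",
]


class OccludedGlintError(RuntimeError):
    """No physical specular reflection on the camera-facing corneal cap."""


# ---------------------------------------------------------------------------
# glint: specular reflection on a sphere (Alhazen's problem, 1-D root solve)

def _sphere_reflection(light, camera, center, radius):
    """Point on the sphere where the light's specular reflection reaches the
    camera.  Solved by bracketing the signed reflection-law residual of the
    in-plane polar angle in the plane spanned by light, camera and centre."""
    L = as_vec3(light) - center
    O = as_vec3(camera) - center
    dO = np.linalg.norm(O)
    dL = np.linalg.norm(L)
    if dO <= radius or dL <= radius:
        raise OccludedGlintError("light or camera inside the corneal sphere")
    u = O / dO
    w = L - u * np.dot(L, u)
    nw = np.linalg.norm(w)
    if nw < 1e-12 * dL:
        # collinear light/camera/centre: normal-incidence glint if on the
        # same side of the sphere, otherwise no camera-facing solution
        if np.dot(L, u) > 0:
            return center + radius * u
        raise OccludedGlintError("light behind the eye relative to the camera")
    v = w / nw
    # 2-D in-plane coordinates
    O2 = np.array([dO, 0.0])
    L2 = np.array([np.dot(L, u), np.dot(L, v)])
    phi_L = np.arctan2(L2[1], L2[0])

    def resid(theta):
        g = radius * np.array([np.cos(theta), np.sin(theta)])
        n = g / radius
        to_o = O2 - g
        to_o = to_o / np.linalg.norm(to_o)
        to_l = L2 - g
        to_l = to_l / np.linalg.norm(to_l)
        # zero when the normal bisects the directions to camera and light
        return (n[0] * to_o[1] - n[1] * to_o[0]) + (n[0] * to_l[1] - n[1] * to_l[0])

    theta = brentq(resid, 0.0, phi_L, xtol=1e-13)
    return center + radius * (np.cos(theta) * u + np.sin(theta) * v)


def glint_point(eye: ModelEye, light, camera_origin) -> np.ndarray:
    """Corneal glint (first Purkinje image) of ``light`` seen by a camera.

    With a nonzero asphericity the effective local radius (and the sphere
    centre, keeping the vertex fixed) is updated from the glint's angular
    distance to the apex and the reflection re-solved — a small perturbation
    mimicking peripheral corneal flattening.

    Raises :class:`OccludedGlintError` when the reflection point falls off
    the corneal cap.
    """
    r = eye.corneal_radius
    c = eye.corneal_center
    g = _sphere_reflection(light, camera_origin, c, r)
    if eye.asphericity != 0.0:
        vertex = eye.corneal_vertex
        for _ in range(4):
            theta_apex = np.arccos(
                np.clip(np.dot(normalize(g - c), eye.optical_axis), -1.0, 1.0)
            )
            r_eff = r * (1.0 + eye.asphericity * theta_apex**2)
            c_eff = vertex - r_eff * eye.optical_axis
            g = _sphere_reflection(light, camera_origin, c_eff, r_eff)
            c = c_eff
    apex_angle = np.degrees(
        np.arccos(np.clip(np.dot(normalize(g - c), eye.optical_axis), -1.0, 1.0))
    )
    if apex_angle > CORNEAL_CAP_DEG:
        raise OccludedGlintError(
            f"glint {apex_angle:.1f} deg from the apex is off the corneal cap"
        )
    return g


# ---------------------------------------------------------------------------
# pupil: refraction at the corneal surface (Snell, 1-D root solve in-plane)

def _refract(incident, n, n1, n2):
    """Snell refraction of a unit direction at a surface with outward unit
    normal ``n`` (incident travelling into the surface)."""
    cos1 = -np.dot(incident, n)
    eta = n1 / n2
    sin2sq = eta**2 * (1.0 - cos1**2)
    if sin2sq >= 1.0:
        raise RuntimeError("total internal reflection (not physical here)")
    cos2 = np.sqrt(1.0 - sin2sq)
    return eta * incident + (eta * cos1 - cos2) * n


def refracted_camera_ray(eye: ModelEye, camera_origin, point) -> Ray:
    """Camera ray whose refraction at the cornea passes through ``point``
    (a point inside the eye, e.g. the pupil centre or a pupil-margin point).

    Returns the *unrefracted* ray from the camera through the corneal
    refraction point — the line along which the camera actually sees the
    refracted (virtual) image.
    """
    O = as_vec3(camera_origin)
    c = eye.corneal_center
    r = eye.corneal_radius
    P = as_vec3(point)
    u = normalize(O - c)
    w = (P - c) - u * np.dot(P - c, u)
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        # camera on the line through c and P: no bending by symmetry
        return Ray(O, normalize(P - O))
    v = w / nw
    O2 = np.array([np.dot(O - c, u), 0.0])
    P2 = np.array([np.dot(P - c, u), np.dot(P - c, v)])

    def miss(theta):
        s2 = r * np.array([np.cos(theta), np.sin(theta)])
        inc = s2 - O2
        inc = inc / np.linalg.norm(inc)
        n2v = s2 / r
        t = _refract(inc, n2v, 1.0, eye.refractive_index)
        rel = P2 - s2
        return t[0] * rel[1] - t[1] * rel[0]

    # bracket the in-plane surface angle; the image point is close to the
    # axis so the solution angle is small and positive
    phi_P = np.arctan2(P2[1], P2[0])
    lo, hi = 0.0, max(0.35, 2.5 * abs(phi_P))
    flo = miss(lo)
    fhi = miss(hi)
    tries = 0
    while flo * fhi > 0 and tries < 8:
        hi += 0.25
        fhi = miss(hi)
        tries += 1
    if flo * fhi > 0:
        raise RuntimeError("failed to bracket the corneal refraction point")
    theta = brentq(miss, lo, hi, xtol=1e-13)
    s = c + r * (np.cos(theta) * u + np.sin(theta) * v)
    return Ray(O, normalize(s - O))


def virtual_pupil_center(eye: ModelEye, camera_origin) -> np.ndarray:
    """Virtual (refracted) image of the pupil centre as seen by one camera.

    Convention: the point on the unrefracted camera ray closest to the real
    pupil centre.  With refractive index 1 this is exactly the real pupil
    centre; with a camera on the optical axis it lies on the axis.
    """
    P = eye.pupil_center
    ray = refracted_camera_ray(eye, camera_origin, P)
    s = np.dot(P - ray.origin, ray.direction)
    return ray.point_at(float(s))


def pupil_feature_ray(eye: ModelEye, camera_origin) -> Ray:
    """Line of sight along which one camera sees the (virtual) pupil centre.

    Under the rigid entrance-pupil model this is the ray through the
    on-axis entrance pupil; under the refracted model it is the
    finite-angle Snell solution for this viewpoint.
    """
    if eye.pupil_model == "rigid":
        return Ray(as_vec3(camera_origin), normalize(eye.entrance_pupil - camera_origin))
    return refracted_camera_ray(eye, camera_origin, eye.pupil_center)


def true_virtual_pupil(eye: ModelEye, scene: SceneGeometry) -> tuple[np.ndarray, float]:
    """Stereo ground-truth virtual pupil (the quantity the reconstruction
    estimates): the entrance pupil itself under the rigid model, otherwise
    the triangulation of the two cameras' refracted pupil rays."""
    if eye.pupil_model == "rigid":
        return eye.entrance_pupil, 0.0
    rays = [pupil_feature_ray(eye, cam.origin) for cam in scene.cameras]
    return triangulate_rays(rays[0], rays[1])


# ---------------------------------------------------------------------------
# projection of one observation

def _project_pupil_area(
    eye: ModelEye, cam: CameraModel, n_points: int = 8
) -> tuple[float, np.ndarray | None]:
    """Projected pupil area in px^2: refract the pupil margin point-by-point,
    project, and fit an ellipse."""
    oa = eye.optical_axis
    e1 = normalize(np.cross(oa, [0.0, 1.0, 0.0]))
    e2 = np.cross(oa, e1)
    pts = []
    for a in np.linspace(0, 2 * np.pi, n_points, endpoint=False):
        p = eye.pupil_center + eye.pupil_radius * (np.cos(a) * e1 + np.sin(a) * e2)
        ray = refracted_camera_ray(eye, cam.origin, p)
        px = cam.project(ray.point_at(np.dot(p - ray.origin, ray.direction)))
        if np.any(np.isnan(px)):
            return np.nan, None
        pts.append(px)
    fit = fit_ellipse(pts)
    if fit is None:
        return np.nan, None
    _, _, a_ax, b_ax, _ = fit
    return float(np.pi * a_ax * b_ax), np.asarray(pts)


def render_observation(
    eyes: dict[str, ModelEye],
    scene: SceneGeometry,
    timestamp: float = 0.0,
    noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
    compute_area: bool = True,
    area_noise_sigma: float = 0.0,
) -> tuple[list[dict], dict[str, EyeState]]:
    """Project glints and the virtual pupil of both eyes into both cameras.

    Returns one feature row per (camera, eye) with isotropic Gaussian pixel
    noise of SD ``noise_px`` added to pupil and glint centres (none when 0),
    plus the noiseless ground-truth :class:`EyeState` per eye.  Features
    that are occluded or fall outside the sensor are NaN.
    """
    if noise_px > 0 or area_noise_sigma > 0:
        if rng is None:
            raise ValueError("rng is required when noise is requested")
    rows = []
    truth: dict[str, EyeState] = {}
    for eye_id, eye in eyes.items():
        pv, gap = true_virtual_pupil(eye, scene)
        truth[eye_id] = EyeState(
            c=eye.corneal_center,
            p_v=pv,
            optical_axis=eye.optical_axis,
            visual_axis=eye.visual_axis,
            timestamp=timestamp,
            quality_gap_pv=gap,
        )
        for cam_idx, cam in enumerate(scene.cameras, start=1):
            ray = pupil_feature_ray(eye, cam.origin)
            pupil_px = cam.project(ray.point_at(600.0))
            glints_px = []
            for light in scene.lights:
                try:
                    g = glint_point(eye, light, cam.origin)
                    glints_px.append(cam.project(g))
                except OccludedGlintError:
                    glints_px.append(np.array([np.nan, np.nan]))
            area = np.nan
            if compute_area and not np.any(np.isnan(pupil_px)):
                area, _ = _project_pupil_area(eye, cam)
                if area_noise_sigma > 0 and np.isfinite(area):
                    area *= float(np.exp(rng.normal(0.0, area_noise_sigma)))
            if noise_px > 0:
                pupil_px = pupil_px + rng.normal(0.0, noise_px, 2)
                glints_px = [g + rng.normal(0.0, noise_px, 2) for g in glints_px]
            rows.append(
                {
                    "timestamp_s": timestamp,
                    "cam": cam_idx,
                    "eye": eye_id,
                    "pupil_x_px": pupil_px[0],
                    "pupil_y_px": pupil_px[1],
                    "pupil_area_px2": area,
                    "glint1_x_px": glints_px[0][0],
                    "glint1_y_px": glints_px[0][1],
                    "glint2_x_px": glints_px[1][0],
                    "glint2_y_px": glints_px[1][1],
                }
            )
    return rows, truth


# ---------------------------------------------------------------------------
# subjects and sessions

@dataclass
class SubjectParams:
    """Binocular subject viewing the screen from the rig's design position."""

    iod_mm: float = 63.0
    eye_height_mm: float = 0.0  # y of the COR midpoint
    viewing_distance_mm: float = 650.0  # z of the COR midpoint
    # optical axes deviate temporally from the visual axes (angle alpha/kappa
    # ~5 deg horizontally, ~1.5 deg vertically); in this Fick convention the
    # left eye (+x side) has a negative and the right eye a positive
    # horizontal kappa
    kappa_left: tuple[float, float] = (-5.0, 1.5)  # (horizontal, vertical) deg
    kappa_right: tuple[float, float] = (5.0, 1.5)
    eso_disparity_deg: float = 0.0  # >0: over-convergence relative to target
    vergence_gain: float = 1.0  # realized vergence = gain * demand + disparity
    corneal_radius: float = 7.72
    vertex_to_cor: float = 13.5
    pupil_radius: float = 2.0
    pupil_plane_depth: float = 3.6
    refractive_index: float = 1.3375
    asphericity: float = 0.0
    pupil_model: str = "rigid"

    def eye_pair(self) -> dict[str, ModelEye]:
        """Eyes at rest (optical axes toward the screen); the subject's left
        eye is on the +x side of the screen frame."""
        common = dict(
            corneal_radius=self.corneal_radius,
            vertex_to_cor=self.vertex_to_cor,
            pupil_radius=self.pupil_radius,
            pupil_plane_depth=self.pupil_plane_depth,
            refractive_index=self.refractive_index,
            asphericity=self.asphericity,
            pupil_model=self.pupil_model,
        )
        mid = np.array([0.0, self.eye_height_mm, self.viewing_distance_mm])
        left = ModelEye(
            cor=mid + np.array([self.iod_mm / 2, 0, 0]),
            optical_axis=[0, 0, -1.0],
            kappa_h=self.kappa_left[0],
            kappa_v=self.kappa_left[1],
            **common,
        )
        right = ModelEye(
            cor=mid - np.array([self.iod_mm / 2, 0, 0]),
            optical_axis=[0, 0, -1.0],
            kappa_h=self.kappa_right[0],
            kappa_v=self.kappa_right[1],
            **common,
        )
        return {"left": left, "right": right}

    def fixating(self, target) -> dict[str, ModelEye]:
        """Both eyes rotated about their CORs so the visual axes point at
        ``target``, plus the configured vergence response: the realized
        vergence exceeds the target vergence (cosine-law demand at the
        CORs) by exactly ``(gain - 1) * demand + disparity``, split equally
        between the eyes (each rotated nasally by half).

        Because the aiming is anchored at the corneal centre (which itself
        moves with the rotation), the applied per-eye offset is iterated
        until the realized excess matches the requested one.
        """
        from .vergence import measured_vergence, target_vergence

        pair = self.eye_pair()
        demand = target_vergence(pair["left"].cor, pair["right"].cor, target)
        want = (self.vergence_gain - 1.0) * demand + self.eso_disparity_deg
        if want == 0.0:
            return {
                "left": pair["left"].oriented_to(target),
                "right": pair["right"].oriented_to(target),
            }
        extra = want
        for _ in range(12):
            out = {
                "left": pair["left"].oriented_to(target, extra_h=-extra / 2),
                "right": pair["right"].oriented_to(target, extra_h=+extra / 2),
            }
            realized = (
                measured_vergence(out["left"].visual_axis, out["right"].visual_axis)
                - demand
            )
            err = want - realized
            if abs(err) < 1e-12:
                break
            extra += err
        return out


@dataclass
class SimulationResult:
    features: pd.DataFrame  # FEATURE_COLUMNS
    truth: pd.DataFrame  # ground-truth eye states per timestamp and eye
    trials: pd.DataFrame  # onset_s, duration_s, target position


def _truth_row(timestamp, eye_id, state: EyeState, target, trial):
    return {
        "timestamp_s": timestamp,
        "eye": eye_id,
        "trial": trial,
        "target_x_mm": target[0],
        "target_y_mm": target[1],
        "target_z_mm": target[2],
        "c_x": state.c[0],
        "c_y": state.c[1],
        "c_z": state.c[2],
        "pv_x": state.p_v[0],
        "pv_y": state.p_v[1],
        "pv_z": state.p_v[2],
        "oa_x": state.optical_axis[0],
        "oa_y": state.optical_axis[1],
        "oa_z": state.optical_axis[2],
        "va_x": state.visual_axis[0],
        "va_y": state.visual_axis[1],
        "va_z": state.visual_axis[2],
    }


def simulate_fixation_session(
    targets,
    scene: SceneGeometry | None = None,
    subject: SubjectParams | None = None,
    duration_s: float = 2.0,
    noise_px: float = 0.0,
    rng_seed: int | None = None,
    asynchrony_s: float = 0.1,
    include_saccade: bool = False,
    saccade_duration_s: float = 0.2,
    compute_area: bool = False,
    area_noise_sigma: float = 0.0,
    eyes: tuple[str, ...] = ("left", "right"),
) -> SimulationResult:
    """Simulate a fixation session: each target fixated for ``duration_s``.

    Camera-2 frames are captured ``asynchrony_s`` later than camera-1
    frames (and time-stamped accordingly) to emulate the rig's inter-camera
    timing discrepancy.  When ``include_saccade`` is on, the gaze point
    travels smoothly from the previous target during the first
    ``saccade_duration_s`` of each trial (inside the 0.6-s window that the
    analysis trims).
    """
    targets = [as_vec3(t) for t in targets]
    if len(targets) == 0:
        raise ValueError("empty target list")
    scene = scene or default_scene()
    subject = subject or SubjectParams()
    rng = np.random.default_rng(rng_seed)
    n_frames = int(round(duration_s * scene.sampling_rate))
    dt = 1.0 / scene.sampling_rate

    feat_rows: list[dict] = []
    truth_rows: list[dict] = []
    trial_rows: list[dict] = []
    prev_target = targets[0]
    cache: dict[tuple, tuple[list[dict], dict]] = {}

    def ideal_obs(gaze_pt):
        """Noiseless observation for one gaze point (cached: during steady
        fixation the physics is identical frame to frame)."""
        key = tuple(np.round(gaze_pt, 9))
        if key not in cache:
            pair = subject.fixating(gaze_pt)
            pair = {e: pair[e] for e in eyes}
            cache[key] = render_observation(
                pair, scene, timestamp=0.0, noise_px=0.0, compute_area=compute_area
            )
        return cache[key]

    pixel_keys = [
        "pupil_x_px", "pupil_y_px",
        "glint1_x_px", "glint1_y_px", "glint2_x_px", "glint2_y_px",
    ]
    for k, target in enumerate(targets):
        onset = k * duration_s
        trial_rows.append(
            {
                "trial": k,
                "onset_s": onset,
                "duration_s": duration_s,
                "target_x_mm": target[0],
                "target_y_mm": target[1],
                "target_z_mm": target[2],
            }
        )

        def gaze_point(t_in_trial):
            if include_saccade and t_in_trial < saccade_duration_s and k > 0:
                u = t_in_trial / saccade_duration_s
                s = u * u * (3 - 2 * u)  # smoothstep
                return prev_target + s * (target - prev_target)
            return target

        for i in range(n_frames):
            t1 = onset + i * dt
            for cam_idx, t_cam in ((1, t1), (2, t1 + asynchrony_s)):
                rows, truth = ideal_obs(gaze_point(t_cam - onset))
                for row in rows:
                    if row["cam"] != cam_idx:
                        continue
                    out = dict(row)
                    out["timestamp_s"] = t_cam
                    if noise_px > 0:
                        for key in pixel_keys:
                            out[key] = out[key] + rng.normal(0.0, noise_px)
                    if area_noise_sigma > 0 and np.isfinite(out["pupil_area_px2"]):
                        out["pupil_area_px2"] *= float(
                            np.exp(rng.normal(0.0, area_noise_sigma))
                        )
                    feat_rows.append(out)
                if cam_idx == 1:
                    for eye_id, state in truth.items():
                        truth_rows.append(_truth_row(t1, eye_id, state, target, k))
        prev_target = target
    return SimulationResult(
        features=pd.DataFrame(feat_rows, columns=FEATURE_COLUMNS),
        truth=pd.DataFrame(truth_rows),
        trials=pd.DataFrame(trial_rows),
    )


def simulate_pupil_series(
    scene: SceneGeometry | None = None,
    subject: SubjectParams | None = None,
    levels: int = 5,
    pupil_radius_range_mm: tuple[float, float] = (1.5, 3.5),
    duration_per_level_s: float = 2.0,
    noise_px: float = 0.0,
    rng_seed: int | None = None,
    target=None,
    area_noise_sigma: float = 0.0,
) -> SimulationResult:
    """Stepped pupil-size series at constant central fixation.

    Emulates an ambient-light manipulation: the physical pupil radius steps
    across ``levels`` plateaus (largest ~3.5 mm, i.e. 7 mm diameter) while
    the subject keeps fixating one target, so ground-truth vergence is
    constant throughout.  Projected pupil areas are computed geometrically.
    """
    if levels < 2:
        raise ValueError("need at least 2 pupil levels")
    scene = scene or default_scene()
    subject = subject or SubjectParams()
    target = as_vec3(target) if target is not None else np.zeros(3)
    radii = np.linspace(pupil_radius_range_mm[0], pupil_radius_range_mm[1], levels)
    parts = []
    for lvl, radius in enumerate(radii):
        sub = SubjectParams(**{**subject.__dict__, "pupil_radius": float(radius)})
        res = simulate_fixation_session(
            [target],
            scene=scene,
            subject=sub,
            duration_s=duration_per_level_s,
            noise_px=noise_px,
            rng_seed=None if rng_seed is None else rng_seed + lvl,
            compute_area=True,
            area_noise_sigma=area_noise_sigma,
        )
        offset = lvl * duration_per_level_s
        res.features["timestamp_s"] += offset
        res.truth["timestamp_s"] += offset
        res.trials["onset_s"] += offset
        res.trials["trial"] = lvl
        res.truth["trial"] = lvl
        res.features["level"] = lvl
        parts.append(res)
    return SimulationResult(
        features=pd.concat([p.features for p in parts], ignore_index=True),
        truth=pd.concat([p.truth for p in parts], ignore_index=True),
        trials=pd.concat([p.trials for p in parts], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# rasterized eye images (for exercising the feature-extraction stage)

def render_eye_image(
    pupil_center_px,
    glints_px,
    pupil_axes_px=(40.0, 32.0),
    pupil_angle_deg: float = 0.0,
    shape=(200, 200),
    background: int = 120,
    iris_value: int = 70,
    pupil_value: int = 25,
    iris_scale: float = 2.2,
    glint_sigma_px: float = 1.8,
    glint_peak: int = 255,
) -> np.ndarray:
    """Paint a synthetic IR eye ROI: dark iris disk, darker elliptical pupil
    and bright Gaussian glint spots on a mid-gray background (8-bit)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full(shape, float(background))
    cx, cy = pupil_center_px
    a, b = pupil_axes_px
    phi = np.radians(pupil_angle_deg)
    xr = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    yr = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    iris = (xr / (a * iris_scale)) ** 2 + (yr / (b * iris_scale)) ** 2 <= 1.0
    img[iris] = iris_value
    pupil = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    img[pupil] = pupil_value
    for g in glints_px:
        if g is None or np.any(np.isnan(g)):
            continue
        gx, gy = g
        blob = glint_peak * np.exp(-((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * glint_sigma_px**2))
        img = np.maximum(img, blob)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
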