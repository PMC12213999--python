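"""Physics of the forward model: reflection law at the cornea, Snell
refraction of the pupil, projection consistency, session synthesis."""

import numpy as np
import pytest

from stereogaze.eye import ModelEye
from stereogaze.geometry import Ray, normalize, triangulate_rays
from stereogaze.simulator import (
    OccludedGlintError,
    SubjectParams,
    glint_point,
    refracted_camera_ray,
    render_observation,
    simulate_fixation_session,
    simulate_pupil_series,
    virtual_pupil_center,
)
from stereogaze.vergence import center_of_rotation, measured_vergence, target_vergence


def make_eye(**kw):
    kw.setdefault("cor", [0.0, 0.0, 650.0])
    kw.setdefault("optical_axis", [0.0, 0.0, -1.0])
    return ModelEye(**kw)


class TestGlintPoint:
    def test_colocated_light_and_camera(self):
        """Light at the camera on the line through c: normal-incidence glint
        at the sphere point nearest the camera."""
        eye = make_eye()
        cam = np.array([0.0, 0.0, 0.0])
        g = glint_point(eye, cam, cam)
        c = eye.corneal_center
        expected = c + eye.corneal_radius * normalize(cam - c)
        assert np.linalg.norm(g - expected) < 1e-9

    def test_mirror_symmetric_configuration(self):
        """Light and camera symmetric about an axis through c: the glint
        lies on the bisecting plane (x = c_x)."""
        eye = make_eye()
        c = eye.corneal_center
        g = glint_point(eye, c + [50.0, 40.0, -600.0], c + [-50.0, 40.0, -600.0])
        assert abs(g[0] - c[0]) < 1e-9

    def test_reflection_law_and_coplanarity(self, scene):
        eye = SubjectParams().fixating([30.0, -40.0, 0.0])["left"]
        c = eye.corneal_center
        for cam in scene.cameras:
            for light in scene.lights:
                g = glint_point(eye, light, cam.origin)
                n = normalize(g - c)
                to_l = normalize(light - g)
                to_o = normalize(cam.origin - g)
                th_in = np.arccos(np.clip(np.dot(to_l, n), -1, 1))
                th_out = np.arccos(np.clip(np.dot(to_o, n), -1, 1))
                assert abs(th_in - th_out) < 1e-9
                # light, camera, c, glint coplanar
                assert abs(np.dot(np.cross(light - c, cam.origin - c), g - c)) / 1e6 < 1e-9

    def test_camera_inside_sphere_raises(self):
        eye = make_eye()
        with pytest.raises(OccludedGlintError):
            glint_point(eye, [0, 0, 0], eye.corneal_center + [1.0, 0, 0])


class TestVirtualPupil:
    def test_unit_index_gives_real_pupil(self):
        eye = make_eye(refractive_index=1.0, pupil_model="refracted")
        pv = virtual_pupil_center(eye, [100.0, 200.0, 0.0])
        assert np.linalg.norm(pv - eye.pupil_center) < 1e-9

    def test_on_axis_camera_keeps_pv_on_axis(self):
        eye = make_eye(pupil_model="refracted")
        pv = virtual_pupil_center(eye, [0.0, 0.0, 0.0])
        off_axis = pv - eye.corneal_center
        off_axis -= eye.optical_axis * np.dot(off_axis, eye.optical_axis)
        assert np.linalg.norm(off_axis) < 1e-9

    def test_snell_residual_at_corneal_intersection(self, scene):
        """The refraction solver satisfies |n1 sin(th1) - n2 sin(th2)| < 1e-9
        at the corneal surface point."""
        eye = SubjectParams(pupil_model="refracted").fixating([50.0, 30.0, 0.0])["right"]
        c = eye.corneal_center
        for cam in scene.cameras:
            ray = refracted_camera_ray(eye, cam.origin, eye.pupil_center)
            # surface point: intersection of the ray with the corneal sphere
            oc = ray.origin - c
            b = np.dot(ray.direction, oc)
            disc = b**2 - (np.dot(oc, oc) - eye.corneal_radius**2)
            s = ray.point_at(-b - np.sqrt(disc))
            n = normalize(s - c)
            inc = ray.direction
            sin1 = np.linalg.norm(np.cross(inc, n))
            # refracted direction continues to the real pupil centre
            t = normalize(eye.pupil_center - s)
            sin2 = np.linalg.norm(np.cross(t, n))
            assert abs(1.0 * sin1 - eye.refractive_index * sin2) < 1e-9

    def test_entrance_pupil_depth_is_paraxial(self):
        """Rigid-model entrance pupil sits ~3.05 mm behind the vertex for a
        3.6-mm pupil plane (n = 1.3375, r = 7.72)."""
        eye = make_eye()
        depth = eye.corneal_radius - eye.virtual_pupil_distance
        assert depth == pytest.approx(3.05, abs=0.02)


class TestRenderObservation:
    def test_reprojection_via_independent_pinhole(self, scene, subject):
        """Feature pixels match an independent K [R|t] projection of the
        underlying 3-D points to < 1e-6 px."""
        pair = subject.fixating([0.0, 0.0, 0.0])
        rows, truth = render_observation(pair, scene, compute_area=False)
        for row in rows:
            cam = scene.cameras[row["cam"] - 1]
            eye = pair[row["eye"]]
            # independent projection: world -> camera -> homogeneous pixel
            Rinv = cam.pose.rotation.T
            for point, keys in [
                (glint_point(eye, scene.light1, cam.origin), ("glint1_x_px", "glint1_y_px")),
                (glint_point(eye, scene.light2, cam.origin), ("glint2_x_px", "glint2_y_px")),
                (eye.entrance_pupil, ("pupil_x_px", "pupil_y_px")),
            ]:
                pc = Rinv @ (point - cam.pose.translation)
                uv = cam.K @ (pc / pc[2])
                assert abs(uv[0] - row[keys[0]]) < 1e-6
                assert abs(uv[1] - row[keys[1]]) < 1e-6

    def test_deterministic_with_seed(self, scene, subject):
        pair = subject.fixating([0.0, 0.0, 0.0])
        r1, _ = render_observation(pair, scene, noise_px=0.5,
                                   rng=np.random.default_rng(7), compute_area=False)
        r2, _ = render_observation(pair, scene, noise_px=0.5,
                                   rng=np.random.default_rng(7), compute_area=False)
        assert r1 == r2

    def test_large_rotation_occludes_glint(self, scene):
        """An eye rotated 40 deg temporally pushes at least one glint off
        the corneal cap -> NaN feature."""
        eye = make_eye(
            cor=[31.5, 0.0, 650.0],
            optical_axis=[np.sin(np.radians(40)), 0, -np.cos(np.radians(40))],
        )
        rows, _ = render_observation({"left": eye}, scene, compute_area=False)
        nan_glints = sum(
            np.isnan(r["glint1_x_px"]) or np.isnan(r["glint2_x_px"]) for r in rows
        )
        assert nan_glints >= 1


class TestFixationSession:
    def test_frame_count(self, scene, subject):
        sim = simulate_fixation_session([[0, 0, 0]], scene=scene, subject=subject,
                                        duration_s=2.0)
        f = sim.features
        assert len(f[(f.cam == 1) & (f.eye == "left")]) == 100  # 2 s at 50 Hz

    def test_zero_disparity_axes_intersect_target(self, scene, subject):
        t = np.array([40.0, -25.0, 0.0])
        sim = simulate_fixation_session([t], scene=scene, subject=subject, duration_s=0.04)
        row = sim.truth.iloc[0:2]
        rays = [
            Ray([r.c_x, r.c_y, r.c_z], [r.va_x, r.va_y, r.va_z])
            for _, r in row.iterrows()
        ]
        p, gap = triangulate_rays(rays[0], rays[1])
        assert np.linalg.norm(p - t) < 1e-6
        assert gap < 1e-6

    def test_eso_disparity_raises_vergence_by_offset(self):
        sub = SubjectParams(eso_disparity_deg=0.5)
        t = np.zeros(3)
        pair = sub.fixating(t)
        corl = center_of_rotation(pair["left"].corneal_center, pair["left"].optical_axis)
        corr = center_of_rotation(pair["right"].corneal_center, pair["right"].optical_axis)
        excess = measured_vergence(
            pair["left"].visual_axis, pair["right"].visual_axis
        ) - target_vergence(corl, corr, t)
        assert excess == pytest.approx(0.5, abs=1e-9)

    def test_empty_target_list_raises(self, scene, subject):
        with pytest.raises(ValueError):
            simulate_fixation_session([], scene=scene, subject=subject)

    def test_camera2_timestamps_carry_asynchrony(self, scene, subject):
        sim = simulate_fixation_session([[0, 0, 0]], scene=scene, subject=subject,
                                        duration_s=0.1, asynchrony_s=0.1)
        f = sim.features
        t1 = sorted(f[(f.cam == 1) & (f.eye == "left")].timestamp_s)
        t2 = sorted(f[(f.cam == 2) & (f.eye == "left")].timestamp_s)
        assert np.allclose(np.asarray(t2) - np.asarray(t1), 0.1)


class TestPupilSeries:
    def test_distinct_area_plateaus_constant_vergence(self, scene):
        sub = SubjectParams()
        sim = simulate_pupil_series(scene=scene, subject=sub, levels=5,
                                    duration_per_level_s=0.08)
        f = sim.features[(sim.features.cam == 1) & (sim.features.eye == "left")]
        areas = f.groupby("level")["pupil_area_px2"].mean()
        assert len(areas) == 5
        assert areas.is_monotonic_increasing
        assert areas.iloc[-1] > areas.iloc[0] * 2
        # ground-truth vergence constant across levels
        verg = []
        for _, grp in sim.truth.groupby("trial"):
            l = grp[grp.eye == "left"].iloc[0]
            r = grp[grp.eye == "right"].iloc[0]
            verg.append(measured_vergence([l.va_x, l.va_y, l.va_z], [r.va_x, r.va_y, r.va_z]))
        assert np.ptp(verg) < 1e-9

    def test_too_few_levels_raises(self, scene):
        with pytest.raises(ValueError):
            simulate_pupil_series(scene=scene, levels=1)

    def test_noiseless_reconstruction_constant_vergence(self, scene, subject, calibrations):
        """Full reconstruction of a noiseless pupil series recovers the same
        vergence at every pupil size (within 1e-3 deg)."""
        from stereogaze.reconstruction import reconstruct_stream
        from stereogaze.vergence import vergence_table

        sim = simulate_pupil_series(scene=scene, subject=subject, levels=3,
                                    duration_per_level_s=0.08)
        gaze = reconstruct_stream(sim.features, scene, calibrations)
        tmap = sim.truth[sim.truth.eye == "left"][
            ["timestamp_s", "target_x_mm", "target_y_mm", "target_z_mm"]
        ]
        vt = vergence_table(gaze, tmap).dropna()
        assert len(vt) >= 3
        assert np.ptp(vt.alpha_measured_deg.to_numpy()) < 1e-3


def test_gaze_error_grows_with_pixel_noise(scene, subject, calibrations):
    """Median gaze-angle error is rank-correlated (rho > 0.9) with the
    pixel-noise SD over {0, 0.1, 0.3, 1.0} px."""
    from scipy.stats import spearmanr

    from stereogaze.reconstruction import reconstruct_stream

    noises = [0.0, 0.1, 0.3, 1.0]
    errors = []
    for i, npx in enumerate(noises):
        sim = simulate_fixation_session(
            [[0.0, 0.0, 0.0]], scene=scene, subject=subject, duration_s=0.6,
            noise_px=npx, rng_seed=100 + i, asynchrony_s=0.0,
        )
        gaze = reconstruct_stream(sim.features, scene, calibrations)
        err = np.hypot(gaze.gx_deg, gaze.gy_deg)  # target at the origin
        errors.append(np.nanmedian(err))
    rho, _ = spearmanr(noises, errors)
    assert rho > 0.9
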