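"""Stereo reconstruction: synchronization, corneal centre, virtual pupil,
single-point kappa calibration, point of gaze and gaze angles."""

import numpy as np
import pandas as pd
import pytest

from stereogaze.eye import EyeState, fick_angles
from stereogaze.geometry import DegenerateGeometryError, Plane, normalize
from stereogaze.reconstruction import (
    CalibrationError,
    KappaCalibration,
    angles_to_screen,
    calibrate_kappa,
    gaze_angles,
    point_of_gaze,
    reconstruct_corneal_center,
    reconstruct_stream,
    reconstruct_virtual_pupil,
    synchronize_streams,
    visual_axis,
)
from stereogaze.simulator import SubjectParams, render_observation, simulate_fixation_session


def frame_features(row_list, cam, eye="left"):
    r = next(x for x in row_list if x["cam"] == cam and x["eye"] == eye)
    glints = ((r["glint1_x_px"], r["glint1_y_px"]), (r["glint2_x_px"], r["glint2_y_px"]))
    pupil = (r["pupil_x_px"], r["pupil_y_px"])
    return glints, pupil


def stream_df(ts, vals, cam=1, eye="left"):
    df = pd.DataFrame({"timestamp_s": ts, "pupil_x_px": vals})
    for c in ("pupil_y_px", "pupil_area_px2", "glint1_x_px", "glint1_y_px",
              "glint2_x_px", "glint2_y_px"):
        df[c] = vals
    df["cam"] = cam
    df["eye"] = eye
    return df


class TestSynchronizeStreams:
    def test_linear_signal_interpolates_exactly(self):
        t1 = np.arange(0, 1.0, 0.02)
        cam1 = stream_df(t1, 10 * t1)
        cam2 = stream_df(t1 + 0.1, 10 * (t1 + 0.1))
        out = synchronize_streams(cam1, cam2)
        ok = ~np.isnan(out["pupil_x_px_cam2"])
        assert ok.sum() > 30
        assert np.allclose(out.loc[ok, "pupil_x_px_cam2"], 10 * out.loc[ok, "timestamp_s"])

    def test_nan_poisons_bracketing_timestamps(self):
        t = np.arange(0, 1.0, 0.02)
        vals = 10 * t
        vals[25] = np.nan
        cam1 = stream_df(t, 10 * t)
        cam2 = stream_df(t + 0.01, vals)
        out = synchronize_streams(cam1, cam2)
        v = out["pupil_x_px_cam2"].to_numpy()
        assert np.isnan(v[25]) and np.isnan(v[26])
        assert not np.isnan(v[23]) and not np.isnan(v[28])

    def test_sinusoid_interpolation_error_small(self):
        """1-Hz sinusoid sampled at 50 Hz, 0.1-s inter-camera shift: linear
        interpolation recovers the signal to < 0.5% of amplitude."""
        t1 = np.arange(0, 2.0, 0.02)
        s = np.sin(2 * np.pi * t1)
        cam1 = stream_df(t1, s)
        t2 = t1 + 0.1
        cam2 = stream_df(t2, np.sin(2 * np.pi * t2))
        out = synchronize_streams(cam1, cam2)
        ok = ~np.isnan(out["pupil_x_px_cam2"])
        err = np.abs(out.loc[ok, "pupil_x_px_cam2"] - np.sin(2 * np.pi * out.loc[ok, "timestamp_s"]))
        assert err.max() < 0.005

    def test_non_overlapping_ranges_raise(self):
        with pytest.raises(ValueError):
            synchronize_streams(stream_df([0, 0.1], [1, 1]), stream_df([5, 5.1], [1, 1]))


class TestCornealCenter:
    def test_noiseless_recovery(self, scene, subject):
        pair = subject.fixating([0.0, 0.0, 0.0])
        rows, truth = render_observation(pair, scene, compute_area=False)
        g1, _ = frame_features(rows, 1)
        g2, _ = frame_features(rows, 2)
        c, gap = reconstruct_corneal_center(g1, g2, scene)
        assert np.linalg.norm(c - truth["left"].c) < 1e-3
        assert gap < 1e-6

    def test_swapped_glints_blow_up_gap(self, scene, subject):
        pair = subject.fixating([0.0, 0.0, 0.0])
        rows, _ = render_observation(pair, scene, compute_area=False)
        g1, _ = frame_features(rows, 1)
        g2, _ = frame_features(rows, 2)
        _, gap_ok = reconstruct_corneal_center(g1, g2, scene)
        _, gap_bad = reconstruct_corneal_center((g1[1], g1[0]), g2, scene)
        assert gap_bad > 10 * max(gap_ok, 1e-6)

    def test_invariant_to_corneal_radius(self, scene):
        """The glint-plane construction never uses the corneal radius: with
        a perturbed simulated radius, the reconstruction still matches the
        perturbed eye's true c."""
        for r in (7.0, 7.72, 8.5):
            pair = SubjectParams(corneal_radius=r).fixating([0.0, 0.0, 0.0])
            rows, truth = render_observation(pair, scene, compute_area=False)
            g1, _ = frame_features(rows, 1)
            g2, _ = frame_features(rows, 2)
            c, _ = reconstruct_corneal_center(g1, g2, scene)
            assert np.linalg.norm(c - truth["left"].c) < 1e-3


class TestVirtualPupil:
    def test_noiseless_recovery(self, scene, subject):
        pair = subject.fixating([0.0, 0.0, 0.0])
        rows, truth = render_observation(pair, scene, compute_area=False)
        _, p1 = frame_features(rows, 1)
        _, p2 = frame_features(rows, 2)
        pv, gap = reconstruct_virtual_pupil(p1, p2, scene)
        assert np.linalg.norm(pv - truth["left"].p_v) < 1e-3
        assert gap < 1e-6

    def test_true_distance_constraint_is_inactive(self, scene, subject):
        pair = subject.fixating([0.0, 0.0, 0.0])
        rows, truth = render_observation(pair, scene, compute_area=False)
        _, p1 = frame_features(rows, 1)
        _, p2 = frame_features(rows, 2)
        c = truth["left"].c
        pv_free, _ = reconstruct_virtual_pupil(p1, p2, scene)
        K = float(np.linalg.norm(truth["left"].p_v - c))
        pv_con, _ = reconstruct_virtual_pupil(p1, p2, scene, c=c, cp_distance=K)
        assert np.linalg.norm(pv_free - pv_con) < 1e-6

    def test_constraint_improves_optical_axis_under_noise(self, scene, subject):
        """Paired comparison over noisy frames: the fixed |c - p_v|
        refinement reduces the median optical-axis error."""
        rng = np.random.default_rng(42)
        pair = subject.fixating([0.0, 0.0, 0.0])
        rows, truth = render_observation(pair, scene, compute_area=False)
        _, p1 = frame_features(rows, 1)
        _, p2 = frame_features(rows, 2)
        c = truth["left"].c
        oa_true = truth["left"].optical_axis
        K = float(np.linalg.norm(truth["left"].p_v - c))
        errs_free, errs_con = [], []
        for _ in range(100):
            n1 = np.asarray(p1) + rng.normal(0, 0.3, 2)
            n2 = np.asarray(p2) + rng.normal(0, 0.3, 2)
            pv_f, _ = reconstruct_virtual_pupil(n1, n2, scene)
            pv_c, _ = reconstruct_virtual_pupil(n1, n2, scene, c=c, cp_distance=K)
            errs_free.append(np.degrees(np.arccos(np.clip(np.dot(normalize(pv_f - c), oa_true), -1, 1))))
            errs_con.append(np.degrees(np.arccos(np.clip(np.dot(normalize(pv_c - c), oa_true), -1, 1))))
        assert np.median(errs_con) <= np.median(errs_free)


class TestKappaCalibration:
    def _calibrate(self, kappa, noise_px=0.0, seed=None, duration=0.4, scene=None):
        sub = SubjectParams(kappa_right=kappa)
        sim = simulate_fixation_session(
            [[0.0, 0.0, 0.0]], scene=scene, subject=sub, duration_s=duration,
            noise_px=noise_px, rng_seed=seed, eyes=("right",), asynchrony_s=0.0,
        )
        f = sim.features
        synced = synchronize_streams(f[f.cam == 1], f[f.cam == 2])
        return calibrate_kappa(synced, scene, [0.0, 0.0, 0.0])

    def test_zero_kappa(self, scene):
        cal = self._calibrate((0.0, 0.0), scene=scene)
        assert abs(cal.kappa_h) < 0.01 and abs(cal.kappa_v) < 0.01

    def test_recovers_5_and_1p5_degrees(self, scene):
        cal = self._calibrate((5.0, 1.5), scene=scene)
        assert cal.kappa_h == pytest.approx(5.0, abs=0.01)
        assert cal.kappa_v == pytest.approx(1.5, abs=0.01)

    def test_noise_robustness_short_epoch(self, scene):
        """0.3-px pixel noise with a short (4-s) calibration epoch still
        recovers kappa to a fraction of a degree (the full-length,
        multi-seed recovery check lives in the acceptance suite)."""
        errs = []
        for s in range(3):
            cal = self._calibrate((5.0, 1.5), 0.3, seed=s, duration=4.0, scene=scene)
            errs.append(max(abs(cal.kappa_h - 5.0), abs(cal.kappa_v - 1.5)))
        assert np.median(errs) < 0.5

    def test_too_few_frames_raise(self, scene):
        sub = SubjectParams()
        sim = simulate_fixation_session(
            [[0.0, 0.0, 0.0]], scene=scene, subject=sub, duration_s=0.1,
            eyes=("right",), asynchrony_s=0.0,
        )
        f = sim.features
        synced = synchronize_streams(f[f.cam == 1], f[f.cam == 2])
        with pytest.raises(CalibrationError):
            calibrate_kappa(synced, scene, [0.0, 0.0, 0.0])


class TestVisualAxisAndPog:
    def _state(self, oa=( 0.0, 0.0, -1.0)):
        c = np.array([0.0, 0.0, 650.0])
        oa = normalize(oa)
        return EyeState(c=c, p_v=c + 4.67 * oa, optical_axis=oa)

    def _cal(self, kh=0.0, kv=0.0):
        return KappaCalibration(kappa_h=kh, kappa_v=kv, cp_distance=4.67, s0=[0, 0, 0])

    def test_zero_kappa_keeps_axis(self):
        s = self._state()
        assert np.allclose(visual_axis(s, self._cal()), s.optical_axis)

    def test_pure_horizontal_offset(self):
        va = visual_axis(self._state(), self._cal(kh=5.0))
        h, v = fick_angles(va)
        assert h == pytest.approx(5.0, abs=1e-9)
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_roundtrip_with_simulator_kappa(self, scene, subject):
        pair = subject.fixating([30.0, -20.0, 0.0])
        eye = pair["left"]
        s = EyeState(c=eye.corneal_center, p_v=eye.entrance_pupil,
                     optical_axis=eye.optical_axis)
        cal = self._cal(kh=subject.kappa_left[0], kv=subject.kappa_left[1])
        va = visual_axis(s, cal)
        assert np.arccos(np.clip(np.dot(va, eye.visual_axis), -1, 1)) < 1e-6

    def test_pog_straight_ahead(self):
        s = self._state()
        s.visual_axis = s.optical_axis
        pog = point_of_gaze(s, Plane([0, 0, 0], [0, 0, 1]))
        assert np.allclose(pog, [0, 0, 0])

    def test_pog_parallel_to_screen_raises(self):
        s = self._state()
        s.visual_axis = np.array([1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            point_of_gaze(s, Plane([0, 0, 0], [0, 0, 1]))


class TestGazeAngles:
    def test_origin(self):
        assert gaze_angles(0.0, 0.0) == (0.0, 0.0)

    def test_unit_slope(self):
        gx, gy = gaze_angles(650.0, 0.0, 650.0)
        assert gx == pytest.approx(45.0, abs=1e-12)

    def test_inverse_roundtrip_on_grid(self, target_grid):
        angles, positions = target_grid
        for (gx, gy), (x, y, _) in zip(angles, positions):
            xi, yi = angles_to_screen(gx, gy)
            assert xi == pytest.approx(x, abs=1e-9)
            assert yi == pytest.approx(y, abs=1e-9)
            gxi, gyi = gaze_angles(x, y)
            assert gxi == pytest.approx(gx, abs=1e-9)
            assert gyi == pytest.approx(gy, abs=1e-9)


def test_stream_nan_frames_yield_nan_samples(scene, subject, calibrations):
    sim = simulate_fixation_session([[0, 0, 0]], scene=scene, subject=subject,
                                    duration_s=0.2, asynchrony_s=0.0)
    f = sim.features.copy()
    idx = f[(f.cam == 1) & (f.eye == "left")].index[3]
    f.loc[idx, "pupil_x_px"] = np.nan
    gaze = reconstruct_stream(f, scene, calibrations)
    left = gaze[gaze.eye == "left"].reset_index()
    assert np.isnan(left.loc[3, "gx_deg"])
    assert (~np.isnan(left["gx_deg"])).sum() == len(left) - 1
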