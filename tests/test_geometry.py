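import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitpose as gp
from gaitpose.errors import CalibrationError, MissingJointError, UndefinedAngleError
from gaitpose.geometry import ProjectedLengths, knee_angle_3d

from conftest import make_frame

finite = st.floats(-500.0, 500.0, allow_nan=False)


def _calib(l3=1.0, l4=1.0):
    return gp.LimbCalibration(
        left_thigh=l3, left_calf=l4, right_thigh=l3, right_calf=l4
    )


def _leg_3d(rng):
    """Random 3D leg with hip and ankle on the same depth side of the knee."""
    l3 = rng.uniform(0.3, 0.6)
    l4 = rng.uniform(0.3, 0.6)
    knee = np.zeros(3)

    def random_dir(length):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        v[2] = abs(v[2])  # same depth side
        v /= np.linalg.norm(v)
        return length * v

    hip = knee + random_dir(l3)
    ankle = knee + random_dir(l4)
    return hip, knee, ankle, l3, l4


class TestProjectedLengths:
    def test_3_4_5_triangle(self):
        f = make_frame({("left", "hip"): (0, 0), ("left", "knee"): (0, 3),
                        ("left", "ankle"): (4, 3)})
        p = gp.projected_lengths(f, "left")
        assert (p.thigh_proj, p.calf_proj, p.span_proj) == (3.0, 4.0, 5.0)

    def test_collinear(self):
        f = make_frame({("right", "hip"): (0, 0), ("right", "knee"): (0, 1),
                        ("right", "ankle"): (0, 2)})
        p = gp.projected_lengths(f, "right")
        assert (p.thigh_proj, p.calf_proj, p.span_proj) == (1.0, 1.0, 2.0)

    def test_missing_joint_named(self):
        f = make_frame({("left", "knee"): None})
        with pytest.raises(MissingJointError, match="left knee"):
            gp.projected_lengths(f, "left")

    def test_against_distance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = {(s, j): tuple(rng.uniform(0, 500, 2))
                   for s in ("left",) for j in ("hip", "knee", "ankle")}
            f = make_frame(pts)
            p = gp.projected_lengths(f, "left")
            h, k, a = (np.array(pts[("left", j)]) for j in ("hip", "knee", "ankle"))
            dist = lambda u, v: np.sqrt(((u - v) ** 2).sum())
            assert abs(p.thigh_proj - dist(h, k)) < 1e-12
            assert abs(p.calf_proj - dist(k, a)) < 1e-12
            assert abs(p.span_proj - dist(h, a)) < 1e-12

    def test_triangle_inequality_enforced(self):
        with pytest.raises(ValueError, match="triangle"):
            ProjectedLengths(1.0, 1.0, 5.0)


class TestKneeAngle2D:
    def test_straight_leg(self):
        f = make_frame({("left", "hip"): (0, -1), ("left", "knee"): (0, 0),
                        ("left", "ankle"): (0, 1)})
        assert gp.knee_angle_2d(f, "left") == pytest.approx(180.0)

    def test_right_angle(self):
        f = make_frame({("left", "hip"): (0, -1), ("left", "knee"): (0, 0),
                        ("left", "ankle"): (1, 0)})
        assert gp.knee_angle_2d(f, "left") == pytest.approx(90.0)

    def test_zero_length_segment(self):
        f = make_frame({("left", "hip"): (5, 5), ("left", "knee"): (5, 5),
                        ("left", "ankle"): (1, 0)})
        with pytest.raises(UndefinedAngleError):
            gp.knee_angle_2d(f, "left")

    def test_law_of_cosines_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            pts = {("left", j): tuple(rng.uniform(0, 100, 2))
                   for j in ("hip", "knee", "ankle")}
            f = make_frame(pts)
            p = gp.projected_lengths(f, "left")
            l1, l2, l5 = p.thigh_proj, p.calf_proj, p.span_proj
            expected = np.degrees(np.arccos(
                np.clip((l1**2 + l2**2 - l5**2) / (2 * l1 * l2), -1, 1)
            ))
            assert gp.knee_angle_2d(f, "left") == pytest.approx(expected, abs=1e-9)


class TestKneeAngle3D:
    def test_no_foreshortening_right_angle(self):
        p = ProjectedLengths(1.0, 1.0, np.sqrt(2.0))
        out = knee_angle_3d(p, _calib(), "left")
        assert float(out) == pytest.approx(90.0, abs=1e-9)
        assert not out.clamped

    def test_straight_leg(self):
        p = ProjectedLengths(1.0, 1.0, 2.0)
        assert float(knee_angle_3d(p, _calib(), "left")) == pytest.approx(180.0)

    def test_projection_exceeding_real_length_errors(self):
        p = ProjectedLengths(1.2, 1.0, 1.5)
        with pytest.raises(CalibrationError, match="thigh"):
            knee_angle_3d(p, _calib(), "left")

    def test_slight_excess_clamped_and_flagged(self):
        p = ProjectedLengths(1.02, 1.0, 1.4)
        out = knee_angle_3d(p, _calib(), "left")
        assert out.clamped
        assert 0.0 <= float(out) <= 180.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reduction_to_planar_law_of_cosines(self, seed):
        """With no foreshortening the 3D formula is the planar angle."""
        rng = np.random.default_rng(seed)
        l1, l2 = rng.uniform(0.1, 2.0, 2)
        l5 = rng.uniform(abs(l1 - l2) + 1e-6, l1 + l2 - 1e-6)
        p = ProjectedLengths(l1, l2, l5)
        got = float(knee_angle_3d(p, _calib(l1, l2), "left"))
        expected = np.degrees(np.arccos(
            np.clip((l1**2 + l2**2 - l5**2) / (2 * l1 * l2), -1, 1)
        ))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_orthographic_projection_oracle(self):
        """Dropping depth and reconstructing recovers the true 3D angle."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            hip, knee, ankle, l3, l4 = _leg_3d(rng)
            true_angle = np.degrees(np.arccos(np.clip(
                np.dot(hip - knee, ankle - knee) / (l3 * l4), -1, 1
            )))
            p = ProjectedLengths(
                float(np.linalg.norm((hip - knee)[:2])),
                float(np.linalg.norm((ankle - knee)[:2])),
                float(np.linalg.norm((hip - ankle)[:2])),
            )
            got = float(knee_angle_3d(p, _calib(l3, l4), "left"))
            worst = max(worst, abs(got - true_angle))
        assert worst < 1e-6

    def test_monotone_in_span(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            l3, l4 = rng.uniform(0.5, 1.0, 2)
            l1 = rng.uniform(0.1, l3)
            l2 = rng.uniform(0.1, l4)
            spans = np.linspace(abs(l1 - l2) + 1e-9, l1 + l2 - 1e-9, 20)
            angles = [
                float(knee_angle_3d(ProjectedLengths(l1, l2, s), _calib(l3, l4), "left"))
                for s in spans
            ]
            assert np.all(np.diff(angles) >= -1e-9)

    def test_output_in_range(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            l3, l4 = rng.uniform(0.5, 1.0, 2)
            l1 = rng.uniform(0.1, l3)
            l2 = rng.uniform(0.1, l4)
            l5 = rng.uniform(abs(l1 - l2), l1 + l2)
            out = knee_angle_3d(ProjectedLengths(l1, l2, l5), _calib(l3, l4), "left")
            assert 0.0 <= float(out) <= 180.0


class TestCalibration:
    def _standing(self, thigh=80.0, calf=75.0, n=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(n) / 30.0
        coords = np.zeros((n, 2, 3, 3))
        for si in range(2):
            x0 = 100.0 + 40.0 * si
            coords[:, si, 0, :2] = (x0, 100.0)
            coords[:, si, 1, :2] = (x0, 100.0 + thigh)
            coords[:, si, 2, :2] = (x0, 100.0 + thigh + calf)
        coords[..., :2] += rng.normal(0, noise, size=(n, 2, 3, 2))
        coords[..., 2] = 0.9
        return gp.GaitRecording(times, coords, fps=30)

    def test_constant_pose(self):
        rec = self._standing()
        calib = gp.calibrate_from_standing(rec, (0, 10))
        assert calib.left_thigh == pytest.approx(80.0)
        assert calib.right_calf == pytest.approx(75.0)

    def test_median_ignores_outlier(self):
        rec = self._standing()
        rec.coords[4, 0, 1, 1] += 300.0  # one wild left-knee frame
        calib = gp.calibrate_from_standing(rec, (0, 10))
        assert calib.left_thigh == pytest.approx(80.0)

    def test_noisy_recovery_within_one_pixel(self):
        rec = self._standing(n=30, noise=1.0, seed=11)
        calib = gp.calibrate_from_standing(rec, (0, 30))
        assert abs(calib.left_thigh - 80.0) < 1.0
        assert abs(calib.right_calf - 75.0) < 1.0

    def test_no_complete_frame_errors(self):
        rec = self._standing()
        rec.coords[..., 2] = 0.0
        with pytest.raises(CalibrationError):
            gp.calibrate_from_standing(rec, (0, 10))


class TestReconstructSeries:
    def test_standing_is_straight(self):
        rec = TestCalibration()._standing(n=12)
        calib = gp.calibrate_from_standing(rec, (0, 12))
        series = gp.reconstruct_series(rec, calib)
        for side in ("left", "right"):
            assert np.allclose(series.angle_2d[side], 180.0, atol=1e-6)
            assert np.allclose(series.angle_3d[side], 180.0, atol=1e-6)

    def test_frontoparallel_walk_2d_equals_3d(self):
        arch = gp.make_archetype("standard", jitter_deg=0.0)
        rec, truth = gp.simulate_recording(
            arch, duration_s=6, theta1_deg=0.0, noise_px=0.0, seed=2
        )
        calib = gp.calibrate_from_standing(rec, rec.meta["standing_frames"])
        series = gp.reconstruct_series(rec, calib)
        for side in ("left", "right"):
            assert np.nanmax(
                np.abs(series.angle_3d[side] - series.angle_2d[side])
            ) < 1e-6
            assert np.nanmax(
                np.abs(series.angle_3d[side] - truth.true_angles[side])
            ) < 1e-6

    def test_tilted_walk_3d_accurate_2d_biased(self, standard_noiseless):
        rec, truth = standard_noiseless
        calib = gp.calibrate_from_standing(rec, rec.meta["standing_frames"])
        series = gp.reconstruct_series(rec, calib)
        for side in ("left", "right"):
            err3 = np.nanmax(np.abs(series.angle_3d[side] - truth.true_angles[side]))
            err2 = np.nanmax(np.abs(series.angle_2d[side] - truth.true_angles[side]))
            assert err3 < 0.5
            assert err2 > 2.0

    def test_missing_joints_become_nan_not_abort(self, standard_noiseless):
        rec, _ = standard_noiseless
        rec = rec.copy()
        rec.coords[40:45, 0, 2, 2] = 0.0  # drop left ankle
        calib = gp.calibrate_from_standing(rec, rec.meta["standing_frames"])
        series = gp.reconstruct_series(rec, calib)
        assert np.all(np.isnan(series.angle_3d["left"][40:45]))
        assert np.all(np.isfinite(series.angle_3d["right"]))
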