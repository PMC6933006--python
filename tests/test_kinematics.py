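"""Resampling, stroke segmentation and the curvature smoothness metric."""

import numpy as np
import pytest

from moveson.kinematics import (Stroke, build_records, curvature_sq,
                                resample, segment_strokes, stroke_smoothness,
                                KAPPA_SQ_FLOOR)
from moveson.simulate import Trajectory, gen_trajectory
from moveson.sonification import TaskSpec

from conftest import make_circle_stroke


def _traj(t, y, x=None, z=None, valid=None, rate=60.0):
    t = np.asarray(t, float)
    zeros = np.zeros_like(t)
    return Trajectory(t=t, x=zeros if x is None else x, y=np.asarray(y, float),
                      z=zeros if z is None else z,
                      valid=np.ones_like(t, bool) if valid is None else valid,
                      rate_hz=rate)


class TestResample:
    def test_uniform_input_is_identity(self):
        t = np.arange(0, 2, 1 / 60.0)
        tr = resample(_traj(t, np.sin(t)), rate_hz=60.0)
        assert np.allclose(tr.t, t)
        assert np.allclose(tr.y, np.sin(t), atol=1e-12)

    def test_linear_signal_interpolated_exactly_from_jittered_times(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 2, 200))
        tr = resample(_traj(t, 3.0 * t + 1.0), rate_hz=60.0)
        assert np.allclose(tr.y, 3.0 * tr.t + 1.0, atol=1e-9)

    def test_long_dropout_gap_is_flagged_and_excluded(self):
        t = np.arange(0, 3, 1 / 60.0)
        valid = np.ones_like(t, bool)
        valid[(t > 1.0) & (t < 1.5)] = False  # 0.5 s gap > 250 ms limit
        tr = resample(_traj(t, np.sin(t), valid=valid), rate_hz=60.0)
        in_gap = (tr.t > 1.0) & (tr.t < 1.5)
        assert (~tr.valid[in_gap]).all()
        assert tr.valid[~in_gap].all()

    def test_all_invalid_raises(self):
        t = np.arange(0, 1, 1 / 60.0)
        with pytest.raises(ValueError):
            resample(_traj(t, t, valid=np.zeros_like(t, bool)))


class TestSegmentation:
    def test_scale_task_yields_eight_alternating_strokes(self):
        tr = resample(gen_trajectory(TaskSpec.scale(), 0.0, "inertial", seed=0))
        strokes = segment_strokes(tr)
        assert len(strokes) == 8
        directions = [s.direction for s in strokes]
        assert directions == ["up", "down"] * 4

    def test_flat_trajectory_has_no_strokes(self):
        t = np.arange(0, 5, 1 / 60.0)
        assert segment_strokes(_traj(t, np.full_like(t, 20.0))) == []

    def test_subthreshold_wiggles_are_not_strokes(self):
        # 5 cm oscillation < 30% of bar height: no stroke may be reported
        t = np.arange(0, 10, 1 / 60.0)
        y = 20 + 5.0 * np.sin(2 * np.pi * 0.5 * t)
        assert segment_strokes(_traj(t, y)) == []

    def test_segmentation_recall_on_generated_cohort(self):
        """>= 95% of true strokes recovered with correct direction."""
        found = expected = 0
        correct_dir = 0
        for seed in range(12):
            tr = resample(gen_trajectory(TaskSpec.scale(), 1.0, "inertial",
                                         seed=seed))
            strokes = segment_strokes(tr)
            expected += 8
            found += len(strokes)
            correct_dir += sum(
                s.direction == ("up" if i % 2 == 0 else "down")
                for i, s in enumerate(strokes))
        assert found >= 0.95 * expected
        assert correct_dir >= 0.95 * expected


class TestCurvature:
    def test_circle_curvature_matches_analytic(self, circle_stroke):
        series = curvature_sq(circle_stroke)
        interior = series.kappa_sq[2:-2]
        assert np.abs(interior - 0.01).max() < 0.01 * 0.01

    def test_straight_line_clamps_to_floor(self):
        t = np.arange(0, 2, 1 / 60.0)
        xyz = np.column_stack([np.zeros_like(t), 20 * t, np.zeros_like(t)])
        s = Stroke(t=t, xyz=xyz, direction="up", rate_hz=60.0)
        series = curvature_sq(s)
        assert (series.kappa_sq == KAPPA_SQ_FLOOR).all()
        assert series.clamped_fraction == 1.0
        assert stroke_smoothness(s) == pytest.approx(-np.log(KAPPA_SQ_FLOOR))

    def test_printed_exponent_variant_is_speed_dependent(self, circle_stroke):
        # p=1 reproduces the dimensionally inconsistent printed form:
        # for a circle it returns v^2/r^2, not the geometric 1/r^2
        series = curvature_sq(circle_stroke, exponent=1)
        v = 2 * np.pi * 10.0 / 5.0
        expected = v**4 / 10.0**2  # (v^2 a^2 - 0) / v^2 with a = v^2/r
        assert np.median(series.kappa_sq[2:-2]) == pytest.approx(expected,
                                                                 rel=0.01)

    def test_spatial_scaling_shifts_smoothness_by_2_log_s(self):
        base = make_circle_stroke(radius_cm=10.0)
        for s_factor in (2.0, 5.0):
            scaled = Stroke(t=base.t, xyz=base.xyz * s_factor,
                            direction="up", rate_hz=base.rate_hz)
            shift = stroke_smoothness(scaled) - stroke_smoothness(base)
            assert shift == pytest.approx(2 * np.log(s_factor), rel=1e-3)

    def test_traversal_speed_does_not_change_geometric_curvature(self):
        slow = make_circle_stroke(speed_factor=1.0)
        fast = make_circle_stroke(speed_factor=2.0)
        assert stroke_smoothness(fast) == pytest.approx(
            stroke_smoothness(slow), rel=1e-3)

    def test_finite_differences_agree_with_oversampled_oracle(self):
        """10x-oversampled finite differences as independent oracle (<2%)."""
        def path(t):
            # smooth curved 3D path with a mid-course correction bump
            x = 2.0 * np.sin(2 * np.pi * t / 4.0)
            y = 40.0 * (10 * (t / 2) ** 3 - 15 * (t / 2) ** 4
                        + 6 * (t / 2) ** 5)
            z = 1.5 * np.exp(-0.5 * ((t - 1.0) / 0.35) ** 2)
            return np.column_stack([x, y, z])

        t_lo = np.arange(0.05, 1.95, 1 / 60.0)
        t_hi = np.arange(0.05, 1.95, 1 / 600.0)
        lo = Stroke(t=t_lo, xyz=path(t_lo), direction="up", rate_hz=60.0)
        hi = Stroke(t=t_hi, xyz=path(t_hi), direction="up", rate_hz=600.0)
        k_lo = curvature_sq(lo).kappa_sq
        k_hi = curvature_sq(hi).kappa_sq[::10][:len(k_lo)]
        interior = slice(3, -3)
        rel = np.abs(k_lo[interior] - k_hi[interior]) / k_hi[interior]
        assert rel.max() < 0.02

    def test_too_short_stroke_rejected(self):
        t = np.arange(4) / 60.0
        with pytest.raises(ValueError):
            Stroke(t=t, xyz=np.zeros((4, 3)), direction="up", rate_hz=60.0)


class TestBuildRecords:
    @staticmethod
    def _stroke_sets(n_patients=4, n_sessions=3, strokes_per=8, seed=0):
        rng = np.random.default_rng(seed)
        sets = []
        for i in range(n_patients):
            for s in range(n_sessions + 1):  # session 0 = pre
                strokes = []
                for _ in range(strokes_per):
                    t = np.arange(0, 2, 1 / 60.0)
                    r = 10 + rng.uniform(-2, 2)
                    xyz = np.column_stack([r * np.cos(t), 20 * t,
                                           r * np.sin(t)])
                    strokes.append(Stroke(t=t, xyz=xyz, direction="up",
                                          rate_hz=60.0))
                sets.append(({"patient": f"P{i}", "group": i % 2,
                              "session": s, "mocap": i % 2}, strokes))
        return sets

    def test_one_record_per_stroke_sharing_covariates(self):
        records = build_records(self._stroke_sets(n_patients=2, n_sessions=1))
        one = records[(records["IDanon"] == "P0") & (records["session"] == 1)]
        assert len(one) == 8
        assert one["Group.c"].nunique() == 1
        assert one["pre.z"].nunique() == 1

    def test_outcome_is_z_scored(self):
        records = build_records(self._stroke_sets())
        assert records["MedianLC"].mean() == pytest.approx(0.0, abs=1e-9)
        assert records["MedianLC"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_centered_codes_and_session_centering(self):
        records = build_records(self._stroke_sets())
        assert set(records["Group.c"]) == {-0.5, 0.5}
        assert set(records["MoCap.c"]) == {-0.5, 0.5}
        per_patient = records.groupby("IDanon")["Session.c"].median()
        assert np.allclose(per_patient, 0.0)

    def test_pre_sessions_feed_covariate_not_outcome(self):
        records = build_records(self._stroke_sets(n_sessions=2))
        assert (records["session"] > 0).all()
        assert records["pre.z"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_incomplete_metadata_dropped(self):
        sets = self._stroke_sets(n_patients=2, n_sessions=1)
        sets.append(({"patient": "P9"}, sets[0][1]))  # missing group etc.
        records = build_records(sets)
        assert "P9" not in set(records["IDanon"])
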