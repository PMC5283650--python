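"""Skeleton I/O, time sync, rigid registration and stream merging."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dyadmotif.skeldata import (
    UPPER_BODY_JOINTS, DyadRecording, RigidTransform,
    SkeletonError, SkeletonTimeSeries, apply_time_offset,
    estimate_rigid_transform, merge_dyad, read_skeleton, write_skeleton,
)


def make_series(n=90, joints=("Head",), fps=30.0, seed=0, pid="p"):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fps
    pos = rng.normal(scale=10.0, size=(n, len(joints), 3)) + 1000.0
    tracked = np.ones((n, len(joints)), dtype=bool)
    return SkeletonTimeSeries(pid, t, joints, pos, tracked, fps)


class TestIO:
    def test_small_csv_identity_read(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "time_s,joint,x_mm,y_mm,z_mm,tracked\n"
            "0.0,Head,1.0,2.0,3.0,1\n"
            "0.03333333,Head,1.5,2.0,3.0,1\n"
            "0.06666667,Head,2.0,2.0,3.0,1\n")
        s = read_skeleton(p, required_joints=None)
        assert s.n_samples == 3
        assert s.joints == ("Head",)
        assert s.tracked.all()
        np.testing.assert_allclose(s.positions[:, 0, 0], [1.0, 1.5, 2.0])

    @pytest.mark.parametrize("schema", ["csv", "json"])
    def test_round_trip(self, tmp_path, schema):
        s = make_series(n=60, joints=UPPER_BODY_JOINTS, seed=3)
        path = tmp_path / f"s.{schema}"
        write_skeleton(s, path, schema=schema)
        back = read_skeleton(path, schema=schema)
        np.testing.assert_array_equal(back.timestamps, s.timestamps)
        assert set(back.joints) == set(s.joints)
        for j in s.joints:  # reader canonicalizes joint order
            np.testing.assert_array_equal(back.joint_positions(j),
                                          s.joint_positions(j))
        np.testing.assert_array_equal(
            back.tracked[:, [back.joint_index(j) for j in s.joints]],
            s.tracked)

    def test_nan_on_tracked_row_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "time_s,joint,x_mm,y_mm,z_mm,tracked\n"
            "0.0,Head,1.0,2.0,3.0,1\n"
            "0.0333,Head,NaN,2.0,3.0,1\n"
            "0.0667,Head,2.0,2.0,3.0,1\n")
        with pytest.raises(SkeletonError, match="line 3"):
            read_skeleton(p, required_joints=None)

    def test_missing_mandatory_joints_is_schema_error(self, tmp_path):
        s = make_series(joints=("Head", "Neck"))
        path = tmp_path / "s.csv"
        write_skeleton(s, path)
        with pytest.raises(SkeletonError, match="missing mandatory joints"):
            read_skeleton(path)

    def test_untracked_samples_preserved(self, tmp_path):
        s = make_series(n=60)
        tracked = s.tracked.copy()
        tracked[10:20, 0] = False
        s = SkeletonTimeSeries(s.participant_id, s.timestamps, s.joints,
                               s.positions, tracked, s.fps_nominal)
        path = tmp_path / "s.csv"
        write_skeleton(s, path)
        back = read_skeleton(path, required_joints=None)
        assert not back.tracked[10:20, 0].any()
        assert back.n_samples == 60


class TestSeriesInvariants:
    def test_nonmonotone_timestamps_rejected(self):
        s = make_series()
        t = s.timestamps.copy()
        t[5] = t[4]
        with pytest.raises(SkeletonError, match="strictly increasing"):
            SkeletonTimeSeries("p", t, s.joints, s.positions, s.tracked)

    def test_offnominal_sampling_rejected(self):
        n = 90
        t = np.arange(n) / 20.0  # 20 fps vs nominal 30
        s = make_series(n=n)
        with pytest.raises(SkeletonError, match="20%"):
            SkeletonTimeSeries("p", t, s.joints, s.positions, s.tracked, 30.0)


class TestTimeOffset:
    def test_zero_offset_identity(self):
        s = make_series()
        out = apply_time_offset(s, 0.0)
        np.testing.assert_array_equal(out.timestamps, s.timestamps)
        np.testing.assert_array_equal(out.positions, s.positions)

    def test_offset_inverse(self):
        s = make_series()
        out = apply_time_offset(apply_time_offset(s, 2.0), -2.0)
        np.testing.assert_allclose(out.timestamps, s.timestamps)

    def test_offset_arithmetic(self):
        s = make_series(n=3)
        out = apply_time_offset(s, 1.5)
        np.testing.assert_allclose(out.timestamps,
                                   [1.5, 1.5 + 1 / 30, 1.5 + 2 / 30])

    def test_nonfinite_offset_rejected(self):
        with pytest.raises(ValueError):
            apply_time_offset(make_series(), np.nan)


class TestRigidTransform:
    def test_identity_recovery(self, rng):
        pts = rng.normal(size=(10, 3)) * 100
        t = estimate_rigid_transform(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)
        assert t.residual_rms < 1e-9

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(8, 3)) * 100
        t = estimate_rigid_transform(pts, pts + [100.0, 0.0, 0.0])
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, [100, 0, 0], atol=1e-8)

    def test_random_rigid_recovery_matches_scipy_oracle(self, rng):
        """Noise-free recovery of a known (R*, t*), cross-checked against
        scipy's independent Kabsch solver."""
        for _ in range(5):
            r_true = Rotation.random(rng=rng).as_matrix()
            t_true = rng.normal(size=3) * 500
            src = rng.normal(size=(10, 3)) * 300
            dst = src @ r_true.T + t_true
            est = estimate_rigid_transform(src, dst)
            np.testing.assert_allclose(est.rotation, r_true, atol=1e-6)
            np.testing.assert_allclose(est.translation, t_true, atol=1e-6)
            oracle, _ = Rotation.align_vectors(dst - dst.mean(axis=0),
                                              src - src.mean(axis=0))
            np.testing.assert_allclose(est.rotation, oracle.as_matrix(),
                                       atol=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            estimate_rigid_transform(pts, pts)

    def test_apply_then_invert_is_identity(self, rng):
        r = Rotation.random(rng=rng).as_matrix()
        t = RigidTransform(r, rng.normal(size=3) * 100)
        pts = rng.normal(size=(20, 3)) * 1000
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts,
                                   atol=1e-6)

    def test_alignment_reduces_residual(self, rng):
        """Estimated transform never increases inter-camera RMS versus
        leaving the points untransformed."""
        for seed in range(5):
            g = np.random.default_rng(seed)
            r = Rotation.random(rng=g).as_matrix()
            src = g.normal(size=(12, 3)) * 200
            dst = src @ r.T + g.normal(size=3) * 400 + g.normal(size=(12, 3))
            est = estimate_rigid_transform(src, dst)
            before = np.sqrt(np.mean(np.sum((dst - src) ** 2, axis=1)))
            assert est.residual_rms <= before + 1e-12


class TestMergeDyad:
    def test_identity_merge(self):
        a = make_series(n=120, pid="a")
        b = SkeletonTimeSeries("b", a.timestamps, a.joints, a.positions,
                               a.tracked, a.fps_nominal)
        rec = merge_dyad(a, b, RigidTransform.identity(), grid_fps=30.0)
        np.testing.assert_allclose(rec.a.positions, rec.b.positions)
        np.testing.assert_array_equal(rec.a.timestamps, rec.b.timestamps)

    def test_grid_covers_intersection_only(self):
        a = make_series(n=120, pid="a")
        b = apply_time_offset(make_series(n=120, pid="b", seed=1), 1.0 / 60)
        rec = merge_dyad(a, b, grid_fps=30.0)
        assert rec.timestamps[0] >= b.timestamps[0]
        assert rec.timestamps[-1] <= a.timestamps[-1]

    def test_no_overlap_is_error(self):
        a = make_series(n=60, pid="a")
        b = apply_time_offset(make_series(n=60, pid="b"), 100.0)
        with pytest.raises(SkeletonError, match="overlap"):
            merge_dyad(a, b)

    def test_round_boundaries_preserved(self):
        a = make_series(n=300, pid="a")
        b = make_series(n=300, pid="b", seed=1)
        rounds = [("r1", 0.0, 4.0), ("r2", 4.0, 9.0)]
        rec = merge_dyad(a, b, rounds=rounds)
        assert [r[0] for r in rec.rounds] == ["r1", "r2"]
        assert rec.rounds[0][1:] == (0.0, 4.0)
        assert rec.rounds[1][1:] == (4.0, 9.0)

    def test_resampling_preserves_bandlimited_rms(self):
        """Linear resampling of a <=3 Hz signal onto a 30 fps grid changes
        its RMS by under 1%."""
        fps = 30.0
        t = np.arange(900) / fps
        sig = 50.0 * np.sin(2 * np.pi * 1.0 * t)  # 1 Hz, torso-sway band
        pos = np.zeros((900, 1, 3))
        pos[:, 0, 0] = sig
        s = SkeletonTimeSeries("p", t, ("Head",), pos,
                               np.ones((900, 1), bool), fps)
        # offset by half a sample so the merge grid falls between samples
        rec = merge_dyad(s, apply_time_offset(s, 1.0 / 60), grid_fps=fps)
        out = rec.a.positions[:, 0, 0]
        assert abs(np.sqrt(np.mean(out ** 2)) / np.sqrt(np.mean(sig ** 2)) - 1) < 0.01

    def test_tracking_gaps_survive_resampling(self):
        a = make_series(n=120, pid="a")
        tracked = a.tracked.copy()
        tracked[40:50, 0] = False
        a = SkeletonTimeSeries("a", a.timestamps, a.joints, a.positions,
                               tracked, a.fps_nominal)
        b = make_series(n=120, pid="b", seed=2)
        rec = merge_dyad(a, apply_time_offset(b, 1.0 / 60))
        assert not rec.a.tracked.all()


class TestDyadRecording:
    def test_overlapping_rounds_rejected(self):
        a = make_series(n=300, pid="a")
        b = make_series(n=300, pid="b", seed=1)
        with pytest.raises(SkeletonError, match="overlap"):
            DyadRecording(a, b, rounds=(("r1", 0.0, 5.0), ("r2", 4.0, 8.0)))

    def test_dir_round_trip(self, tmp_path):
        a = make_series(n=60, joints=UPPER_BODY_JOINTS, pid="a")
        b = make_series(n=60, joints=UPPER_BODY_JOINTS, pid="b", seed=1)
        rec = DyadRecording(a, b, rounds=(("r1", 0.0, 1.5),))
        rec.save_dir(tmp_path / "rec")
        back = DyadRecording.load_dir(tmp_path / "rec")
        for j in rec.a.joints:  # reader canonicalizes joint order
            np.testing.assert_array_equal(back.a.joint_positions(j),
                                          rec.a.joint_positions(j))
        assert back.rounds == rec.rounds
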