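"""Pose-evolution representation: joint reduction, time encoding,
heatmaps, aggregation, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posepheno.pose_evolution import (
    augment,
    joint_heatmap,
    pose_evolution_map,
    reduce_keypoints,
    scale_keypoints,
    time_encoding,
)
from posepheno.types import ValidationError


def kp17(head_xy=(100.0, 50.0), conf=1.0):
    """17 keypoints with eyes/ears mirrored about head_xy."""
    hx, hy = head_xy
    kp = np.zeros((17, 3))
    kp[:, 0] = np.linspace(90, 110, 17)
    kp[:, 1] = np.linspace(40, 200, 17)
    kp[:, 2] = conf
    kp[0, :2] = (hx, hy - 3)
    kp[1, :2] = (hx - 3, hy)  # left eye
    kp[2, :2] = (hx + 3, hy)  # right eye
    kp[3, :2] = (hx - 6, hy + 1)  # left ear
    kp[4, :2] = (hx + 6, hy + 1)  # right ear
    return kp


class TestReduceKeypoints:
    def test_symmetric_face_head_on_axis(self):
        out = reduce_keypoints(kp17(head_xy=(100.0, 50.0)))
        assert out.shape == (14, 3)
        assert out[1, 0] == pytest.approx(100.0)

    def test_single_visible_ear_dominates(self):
        kp = kp17()
        kp[[1, 2, 4], 2] = 0.0  # only left ear visible
        out = reduce_keypoints(kp)
        np.testing.assert_allclose(out[1, :2], kp[3, :2])
        assert out[1, 2] == pytest.approx(0.25)  # mean of (0,0,1,0)

    def test_matches_weighted_mean_oracle(self, rng):
        for _ in range(50):
            kp = kp17()
            kp[1:5, 2] = rng.uniform(0.0, 1.0, 4)
            out = reduce_keypoints(kp)
            w = kp[1:5, 2]
            expected = (kp[1:5, :2] * w[:, None]).sum(axis=0) / w.sum()
            np.testing.assert_allclose(out[1, :2], expected)
            assert out[1, 2] == pytest.approx(w.mean())

    def test_all_head_parts_invisible_gives_zero_confidence(self):
        kp = kp17()
        kp[1:5, 2] = 0.0
        out = reduce_keypoints(kp)
        assert out[1, 2] == 0.0

    def test_body_joints_pass_through_in_order(self):
        kp = kp17()
        out = reduce_keypoints(kp)
        np.testing.assert_array_equal(out[2:], kp[5:])
        np.testing.assert_array_equal(out[0], kp[0])


class TestTimeEncoding:
    def test_endpoints_are_one_hot(self):
        np.testing.assert_allclose(time_encoding(0.0, 1.0, 3), [1, 0, 0])
        np.testing.assert_allclose(time_encoding(1.0, 1.0, 3), [0, 0, 1])

    def test_quarter_point_three_channels(self):
        # l = 1/2; t = 0.25 sits in interval 1: (0.5, 0.5, 0)
        np.testing.assert_allclose(time_encoding(0.25, 1.0, 3), [0.5, 0.5, 0.0])

    def test_midpoint_peaks_middle_channel(self):
        np.testing.assert_allclose(time_encoding(0.5, 1.0, 3), [0, 1, 0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(2, 10), st.floats(0.0, 1.0))
    def test_partition_of_unity(self, C, t):
        enc = time_encoding(t, 1.0, C)
        assert enc.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(enc >= -1e-12) and np.all(enc <= 1 + 1e-12)
        assert np.count_nonzero(enc > 1e-12) <= 2

    def test_out_of_range_time_rejected(self):
        with pytest.raises(ValidationError):
            time_encoding(1.5, 1.0, 3)

    def test_triangular_profile_symmetry(self):
        # o_j(T - t) equals the channel-reversed encoding at t
        for t in np.linspace(0, 1, 21):
            np.testing.assert_allclose(
                time_encoding(1.0 - t, 1.0, 4),
                time_encoding(t, 1.0, 4)[::-1],
                atol=1e-12,
            )


class TestJointHeatmap:
    def test_zero_confidence_gives_zero_grid(self):
        assert not joint_heatmap((10, 10), 0.0, 20, 20, 2.0).any()

    def test_peak_cell_equals_confidence(self):
        hm = joint_heatmap((10, 12), 1.0, 24, 24, 2.0)
        assert hm[12, 10] == pytest.approx(1.0)
        assert hm.max() == pytest.approx(1.0)
        # radial symmetry around the peak
        assert hm[12, 8] == pytest.approx(hm[12, 12])
        assert hm[10, 10] == pytest.approx(hm[14, 10])

    def test_amplitude_scales_with_confidence(self):
        hm = joint_heatmap((10, 10), 0.4, 20, 20, 2.0)
        assert hm.max() == pytest.approx(0.4)

    def test_grid_sum_matches_gaussian_integral(self):
        # sum over an interior Gaussian ~ conf * 2*pi*sigma^2 within 1%
        for sigma in (2.0, 3.0):
            hm = joint_heatmap((30, 30), 0.7, 60, 60, sigma)
            assert hm.sum() == pytest.approx(0.7 * 2 * np.pi * sigma**2, rel=0.01)

    def test_keypoint_outside_grid_keeps_tail(self):
        hm = joint_heatmap((-3, 10), 1.0, 20, 20, 2.0)
        assert hm.max() > 0
        assert hm[10, 0] > hm[10, 5]


def static_clip(F=8, x=30.0, y=20.0, conf=1.0):
    seq = np.zeros((F, 14, 3))
    seq[:, :, 0] = x
    seq[:, :, 1] = y
    seq[:, :, 2] = conf
    return seq


class TestPoseEvolutionMap:
    def test_single_frame_uses_only_first_channel(self):
        seq = np.zeros((1, 14, 3))
        seq[0, 0] = (30.0, 20.0, 1.0)
        pe = pose_evolution_map(seq, C=3, H=40, W=60, sigma=2.0)
        assert pe.shape == (42, 40, 60)
        assert pe.joint_slice(0, 0).max() == 1.0
        assert not pe.joint_slice(0, 1).any()
        assert not pe.joint_slice(0, 2).any()
        # and the normalised slice equals the unit-peak heatmap
        hm = joint_heatmap((30, 20), 1.0, 40, 60, 2.0)
        np.testing.assert_allclose(pe.joint_slice(0, 0), hm, atol=1e-12)

    def test_static_pose_gives_identical_channel_slices(self):
        pe = pose_evolution_map(static_clip(F=9), C=3, H=40, W=60, sigma=2.0)
        for j in range(14):
            s0 = pe.joint_slice(j, 0)
            for c in (1, 2):
                np.testing.assert_allclose(pe.joint_slice(j, c), s0, atol=1e-9)

    def test_nonzero_slices_have_max_exactly_one(self):
        rng = np.random.default_rng(3)
        seq = static_clip(F=6)
        seq[:, :, 0] += rng.uniform(-5, 5, size=(6, 14))
        seq[:, :, 2] = rng.uniform(0.3, 1.0, size=(6, 14))
        pe = pose_evolution_map(seq, C=3, H=40, W=60, sigma=2.0)
        for k in range(42):
            s = pe.tensor[k]
            assert s.max() == 1.0 or not s.any()
        assert pe.tensor.min() >= 0.0 and pe.tensor.max() <= 1.0

    def test_all_zero_confidence_clip_warns_not_crashes(self):
        seq = static_clip(F=4, conf=0.0)
        with pytest.warns(UserWarning, match="all-zero"):
            pe = pose_evolution_map(seq, C=3, H=20, W=20, sigma=2.0)
        assert not pe.tensor.any()

    def test_time_reversal_reverses_channels(self):
        rng = np.random.default_rng(7)
        seq = static_clip(F=10)
        seq[:, :, 0] = 10 + np.cumsum(rng.uniform(1, 3, size=(10, 14)), axis=0)
        pe_fwd = pose_evolution_map(seq, C=3, H=40, W=80, sigma=2.0)
        pe_rev = pose_evolution_map(seq[::-1], C=3, H=40, W=80, sigma=2.0)
        for j in range(14):
            for c in range(3):
                np.testing.assert_allclose(
                    pe_rev.joint_slice(j, c),
                    pe_fwd.joint_slice(j, 2 - c),
                    atol=1e-9,
                )

    def test_translation_equivariance_in_interior(self):
        seq = static_clip(F=5, x=25.0, y=18.0)
        pe_a = pose_evolution_map(seq, C=2, H=50, W=70, sigma=2.0)
        moved = seq.copy()
        moved[:, :, 0] += 7
        moved[:, :, 1] += 4
        pe_b = pose_evolution_map(moved, C=2, H=50, W=70, sigma=2.0)
        np.testing.assert_allclose(
            pe_b.tensor[:, 4:, 7:], pe_a.tensor[:, :-4, :-7], atol=1e-9
        )

    def test_accepts_raw_17_keypoint_clips(self):
        seq17 = np.zeros((3, 17, 3))
        seq17[:, :, 0] = 30
        seq17[:, :, 1] = 20
        seq17[:, :, 2] = 1.0
        pe = pose_evolution_map(seq17, C=2, H=30, W=30, sigma=2.0)
        assert pe.shape == (28, 30, 30)


class TestAugment:
    def test_zero_noise_is_identity(self):
        pe = pose_evolution_map(static_clip(), C=2, H=20, W=20, sigma=2.0)
        out = augment(pe, 0.0, seed=0)
        np.testing.assert_array_equal(out.tensor, pe.tensor)

    def test_same_seed_reproduces(self):
        pe = pose_evolution_map(static_clip(), C=2, H=20, W=20, sigma=2.0)
        a = augment(pe, 0.05, seed=42)
        b = augment(pe, 0.05, seed=42)
        np.testing.assert_array_equal(a.tensor, b.tensor)

    def test_output_clipped_to_unit_interval(self):
        pe = pose_evolution_map(static_clip(), C=2, H=20, W=20, sigma=2.0)
        out = augment(pe, 0.5, seed=1)
        assert out.tensor.min() >= 0.0 and out.tensor.max() <= 1.0

    def test_noise_standard_deviation_matches(self):
        """Moment check on ~10^6 non-saturated cells."""
        from posepheno.pose_evolution import PoseEvolutionMap

        base = PoseEvolutionMap(np.full((16, 250, 250), 0.5), channels=2)
        out = augment(base, 0.05, seed=9)
        diff = out.tensor - base.tensor
        assert diff.std() == pytest.approx(0.05, rel=0.05)


def test_scale_keypoints_scales_xy_only():
    kp = np.array([[[8.0, 16.0, 0.5]]])
    out = scale_keypoints(kp, 0.125)
    np.testing.assert_allclose(out, [[[1.0, 2.0, 0.5]]])
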