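"""Scene simulator: pose templates, scenario generation, clip corpus."""

import numpy as np
import pytest

from posepheno.simulate import (
    ClipDatasetConfig,
    ScenarioConfig,
    benchmark_scenario,
    generate_clip_dataset,
    generate_scenario,
    pose_template,
    random_actors,
)
from posepheno.types import ACTION_LABELS, ValidationError

L_ANKLE, R_ANKLE = 15, 16
L_HIP, R_HIP = 11, 12


class TestPoseTemplate:
    def test_transition_starts_at_sit(self):
        np.testing.assert_allclose(
            pose_template("sit-to-stand", 0.0, 100),
            pose_template("sit", 0.0, 100),
        )

    def test_transition_ends_at_stand(self):
        np.testing.assert_allclose(
            pose_template("sit-to-stand", 1.0, 100),
            pose_template("stand", 0.0, 100),
        )

    def test_stand_to_sit_is_reversed_transition(self):
        for phi in np.linspace(0, 1, 11):
            np.testing.assert_allclose(
                pose_template("stand-to-sit", phi, 80),
                pose_template("sit-to-stand", 1.0 - phi, 80),
            )

    def test_walk_half_cycle_swaps_ankle_offsets(self):
        stand = pose_template("stand", 0.0, 100)
        for phi in (0.1, 0.25, 0.4):
            a = pose_template("walk", phi, 100) - stand
            b = pose_template("walk", (phi + 0.5) % 1.0, 100) - stand
            np.testing.assert_allclose(a[L_ANKLE], b[R_ANKLE], atol=1e-9)
            np.testing.assert_allclose(a[R_ANKLE], b[L_ANKLE], atol=1e-9)

    def test_sit_is_compressed_relative_to_stand(self):
        sit = pose_template("sit", 0.0, 100)
        stand = pose_template("stand", 0.0, 100)
        # hips closer to the ground when seated (y is negative above ground)
        assert sit[L_HIP, 1] > stand[L_HIP, 1]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            pose_template("running", 0.0, 100)


def small_scenario(seed=0, **overrides):
    actors = random_actors(overrides.pop("n_actors", 1), seed=seed)
    kwargs = dict(
        n_frames=100,
        actors=actors,
        action_script=[("stand", 100 / 30.0)],
        keypoint_jitter_sigma=0.5,
        detection_dropout_prob=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


class TestGenerateScenario:
    def test_one_actor_no_disturbance_gives_one_detection_per_frame(self):
        stream, truth, _ = generate_scenario(small_scenario())
        assert len(stream) == 100
        assert all(len(f) == 1 for f in stream)
        assert len(truth) == 100

    def test_same_seed_reproduces_stream_exactly(self, tmp_path):
        from posepheno.io import write_detections

        cfg = small_scenario(seed=5, n_actors=2)
        a, b = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_detections(generate_scenario(cfg)[0], a)
        write_detections(generate_scenario(cfg)[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_occlusion_window_removes_exactly_those_frames(self):
        actors = random_actors(1, seed=3)
        cfg = small_scenario(
            seed=3, occlusion_windows=[(actors[0].actor_id, 30, 50)]
        )
        stream, _, _ = generate_scenario(cfg)
        present = [f.frame_index for f in stream if len(f) == 1]
        absent = [f.frame_index for f in stream if len(f) == 0]
        assert absent == list(range(30, 50))
        assert len(present) == 80

    def test_two_targets_rejected(self):
        actors = random_actors(2, seed=0)
        actors[1].is_target = True
        with pytest.raises(ValidationError, match="target"):
            small_scenario(n_actors=1, actors=actors)

    def test_script_must_cover_all_frames(self):
        with pytest.raises(ValidationError, match="frames"):
            small_scenario(action_script=[("stand", 1.0)])

    def test_annotations_follow_the_script(self):
        cfg = small_scenario(
            action_script=[("sit", 1.0), ("sit-to-stand", 1.0), ("stand", 100 / 30.0 - 2.0)]
        )
        _, _, segments = generate_scenario(cfg)
        assert [s.label for s in segments] == ["sit", "sit-to-stand", "stand"]
        assert segments[0].start_frame == 0
        assert segments[-1].end_frame == 99

    def test_scene_change_teleports_actors(self):
        cfg = small_scenario(seed=9, scene_changes=[50], keypoint_jitter_sigma=0.0)
        stream, _, _ = generate_scenario(cfg)
        x_before = stream[49].detections[0].box[0]
        x_after = stream[50].detections[0].box[0]
        assert abs(x_after - x_before) > 50


class TestClipDataset:
    def test_balanced_counts(self):
        clips, labels = generate_clip_dataset(10, 30, seed=0)
        assert len(clips) == 50
        for label in ACTION_LABELS:
            assert labels.count(label) == 10

    def test_clip_shapes(self):
        clips, _ = generate_clip_dataset(2, 45, seed=0)
        assert all(c.shape == (45, 17, 3) for c in clips)

    def test_seeds_change_jitter_not_counts(self):
        a_clips, a_labels = generate_clip_dataset(5, 30, seed=1)
        b_clips, b_labels = generate_clip_dataset(5, 30, seed=2)
        assert a_labels == b_labels
        assert not np.allclose(a_clips[0], b_clips[0])

    def test_noise_free_walk_root_strictly_monotone(self):
        cfg = ClipDatasetConfig(keypoint_jitter_sigma=0.0)
        clips, labels = generate_clip_dataset(5, 40, seed=4, config=cfg)
        for clip, label in zip(clips, labels):
            root_x = clip[:, [L_HIP, R_HIP], 0].mean(axis=1)
            diffs = np.diff(root_x)
            if label == "walk":
                assert np.all(diffs > 0) or np.all(diffs < 0)
            elif label in ("sit", "stand"):
                assert np.allclose(diffs, 0.0)


def test_benchmark_scenario_has_prescribed_disturbances():
    cfg = benchmark_scenario(seed=0)
    assert cfg.n_frames == 600
    assert len(cfg.actors) == 3
    assert len(cfg.occlusion_windows) == 2
    assert len(cfg.scene_changes) == 1
    # one window on the target so long-term fusion is exercised
    assert any(w[0] == cfg.target.actor_id for w in cfg.occlusion_windows)
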