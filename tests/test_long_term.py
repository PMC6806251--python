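"""Long-term tracker: pruning, sampling, embeddings, affinity, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posepheno.long_term import (
    AppearanceEmbedding,
    PassthroughEmbedder,
    PatchMeanEmbedder,
    affinity,
    embed,
    fuse_to_track,
    prune_tracklets,
    sample_representative,
    tracklet_classification_accuracy,
)
from posepheno.short_term import Tracklet, build_tracklets
from posepheno.types import ValidationError

from conftest import make_detection, make_stream


def make_tracklet(tid, start, length, kp_conf=0.9, box_confs=None, appearance=None):
    dets = []
    for k in range(length):
        det = make_detection(
            start + k,
            x=50.0,
            kp_conf=kp_conf,
            box_conf=box_confs[k] if box_confs else 0.9,
            appearance=appearance,
        )
        dets.append(det)
    return Tracklet(tracklet_id=tid, detections=dets)


class TestPruning:
    def test_zero_thresholds_are_identity(self):
        tracklets = [make_tracklet(0, 0, 3), make_tracklet(1, 10, 1, kp_conf=0.1)]
        assert prune_tracklets(tracklets, 0, 0.0) == tracklets

    def test_short_tracklet_removed(self):
        tracklets = [make_tracklet(0, 0, 2)]
        assert prune_tracklets(tracklets, 5, 0.0) == []

    def test_hand_built_mixed_set(self):
        # survivors by hand: length >= 3 AND confident-keypoint fraction >= 0.5
        t_ok = make_tracklet(0, 0, 5, kp_conf=0.9)
        t_short = make_tracklet(1, 10, 2, kp_conf=0.9)
        t_lowconf = make_tracklet(2, 20, 5, kp_conf=0.2)  # all below 0.5
        t_edge = make_tracklet(3, 30, 3, kp_conf=0.5)  # conf exactly at 0.5 counts
        t_long_low = make_tracklet(4, 40, 9, kp_conf=0.49)
        survivors = prune_tracklets(
            [t_ok, t_short, t_lowconf, t_edge, t_long_low], 3, 0.5
        )
        assert [t.tracklet_id for t in survivors] == [0, 3]


class TestRepresentativeSampling:
    def test_highest_confidence_wins(self):
        t = make_tracklet(0, 0, 3, box_confs=[0.5, 0.9, 0.7])
        assert sample_representative(t).box_conf == 0.9

    def test_ties_broken_by_earliest_frame(self):
        t = make_tracklet(0, 5, 4, box_confs=[0.8, 0.8, 0.8, 0.8])
        assert sample_representative(t).frame_index == 5

    def test_agrees_with_argmax_oracle(self, rng):
        for _ in range(100):
            confs = list(rng.uniform(0.1, 1.0, size=rng.integers(1, 8)))
            t = make_tracklet(0, 0, len(confs), box_confs=confs)
            assert sample_representative(t).box_conf == max(confs)


class TestEmbedding:
    def test_passthrough_returns_stored_vector(self):
        vec = np.arange(8.0)
        det = make_detection(0, appearance=vec)
        emb = embed(det, PassthroughEmbedder())
        np.testing.assert_array_equal(emb.vector, vec)

    def test_passthrough_without_vector_raises(self):
        det = make_detection(0)
        with pytest.raises(ValidationError, match="appearance"):
            embed(det, PassthroughEmbedder())

    def test_patch_embedder_deterministic_and_fixed_dim(self):
        image = np.random.default_rng(0).random((200, 200))
        embedder = PatchMeanEmbedder(lambda f: image, grid=4)
        det = make_detection(0, x=100.0, y=100.0)
        a, b = embedder(det), embedder(det)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (16,)

    def test_identity_clusters_are_separable(self, rng):
        """Monte-Carlo on the appearance model: unit-separated identities
        with sigma = 0.05 keep inter-actor distances above intra-actor
        distances in at least 99% of sampled pairs."""
        d = 16
        u = rng.normal(size=d)
        u /= np.linalg.norm(u)
        v = rng.normal(size=d)
        v /= np.linalg.norm(v)
        v = u + (v - u) / np.linalg.norm(v - u)  # exactly distance 1 from u
        wins = 0
        n = 1000
        for _ in range(n):
            a1, a2 = u + rng.normal(0, 0.05, d), u + rng.normal(0, 0.05, d)
            b = v + rng.normal(0, 0.05, d)
            if np.linalg.norm(a1 - b) > np.linalg.norm(a1 - a2):
                wins += 1
        assert wins / n >= 0.99


class TestAffinity:
    def test_identical_vectors_give_zero(self):
        e = AppearanceEmbedding(np.array([1.0, 2.0]))
        assert affinity(e, e) == 0.0

    def test_pythagorean_case(self):
        a = AppearanceEmbedding(np.array([0.0, 0.0]))
        b = AppearanceEmbedding(np.array([3.0, 4.0]))
        assert affinity(a, b) == 5.0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValidationError, match="dimension"):
            affinity(AppearanceEmbedding(np.ones(3)), AppearanceEmbedding(np.ones(4)))

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 12))
            expected = sum((a - b) ** 2 for a, b in zip(x, y)) ** 0.5
            got = affinity(AppearanceEmbedding(x), AppearanceEmbedding(y))
            assert got == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=4, max_size=4),
        st.lists(st.floats(-10, 10), min_size=4, max_size=4),
        st.lists(st.floats(-10, 10), min_size=4, max_size=4),
    )
    def test_metric_axioms(self, xs, ys, zs):
        a = AppearanceEmbedding(np.array(xs))
        b = AppearanceEmbedding(np.array(ys))
        c = AppearanceEmbedding(np.array(zs))
        assert affinity(a, b) == pytest.approx(affinity(b, a))
        assert affinity(a, b) >= 0
        assert affinity(a, c) <= affinity(a, b) + affinity(b, c) + 1e-9


class TestFusion:
    def _tracklets_with_identities(self, identities):
        out = []
        for tid, vec in enumerate(identities):
            out.append(make_tracklet(tid, tid * 20, 5, appearance=np.asarray(vec)))
        return out

    def test_reference_always_accepted(self):
        tracklets = self._tracklets_with_identities([[1, 0], [0, 1], [1, 0.1]])
        track = fuse_to_track(tracklets, reference_id=0, tau=0.0)
        assert track.accepted[0] is True

    def test_tau_zero_merges_only_exact_duplicates(self):
        tracklets = self._tracklets_with_identities([[1, 0], [1, 0], [0, 1]])
        track = fuse_to_track(tracklets, reference_id=0, tau=0.0)
        assert track.accepted == {0: True, 1: True, 2: False}

    def test_missing_reference_advises_relaxing_pruning(self):
        tracklets = self._tracklets_with_identities([[1, 0]])
        with pytest.raises(ValidationError, match="pruned"):
            fuse_to_track(tracklets, reference_id=99, tau=0.5)

    def test_accepted_set_grows_with_tau(self):
        rng = np.random.default_rng(5)
        idents = [rng.normal(size=4) for _ in range(6)]
        tracklets = self._tracklets_with_identities(idents)
        previous = set()
        for tau in (0.0, 0.3, 0.6, 1.0, 1.5, 2.0):
            track = fuse_to_track(tracklets, reference_id=0, tau=tau)
            accepted = {tid for tid, ok in track.accepted.items() if ok}
            assert previous <= accepted
            previous = accepted

    def test_overlapping_tracklets_lower_affinity_wins(self):
        ref = make_tracklet(0, 0, 5, appearance=np.array([1.0, 0.0]))
        near = make_tracklet(1, 3, 5, appearance=np.array([0.995, 0.1]))
        far = make_tracklet(2, 3, 5, appearance=np.array([0.9, 0.44]))
        track = fuse_to_track([ref, near, far], reference_id=0, tau=2.0)
        # frames 3..7 overlap between ref (3,4), near, far: ref wins 3-4,
        # near (closer to ref) wins 5-7 over far
        assert len(track) == len(set(track.frames))
        chosen_57 = [d for d in track.detections if 5 <= d.frame_index <= 7]
        for det in chosen_57:
            np.testing.assert_array_equal(det.appearance, near.detections[0].appearance)

    def test_three_actor_scenario_recovers_target_tracklets(self):
        """Hand-checkable: two well-separated bystander identities and a
        target split into tracklets by a gap; τ = 0.5 accepts exactly the
        target's tracklets."""
        t0 = make_tracklet(0, 0, 6, appearance=np.array([1.0, 0.0, 0.0]))
        t1 = make_tracklet(1, 40, 6, appearance=np.array([0.99, 0.02, 0.0]))
        o0 = make_tracklet(2, 0, 6, appearance=np.array([0.0, 1.0, 0.0]))
        o1 = make_tracklet(3, 40, 6, appearance=np.array([0.0, 0.0, 1.0]))
        o2 = make_tracklet(4, 80, 6, appearance=np.array([0.05, 0.99, 0.0]))
        o3 = make_tracklet(5, 80, 6, appearance=np.array([0.0, 0.05, 0.99]))
        track = fuse_to_track([t0, t1, o0, o1, o2, o3], reference_id=0, tau=0.5)
        accepted = {tid for tid, ok in track.accepted.items() if ok}
        assert accepted == {0, 1}


class TestBinaryAccuracy:
    def test_all_correct_is_one(self):
        assert tracklet_classification_accuracy([True, False], [True, False]) == 1.0

    def test_count_arithmetic(self):
        # TP=3, TN=5, FP=1, FN=1 -> 8/10
        pred = [True] * 3 + [False] * 5 + [True] + [False]
        truth = [True] * 3 + [False] * 5 + [False] + [True]
        assert tracklet_classification_accuracy(pred, truth) == 0.8

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            tracklet_classification_accuracy([], [])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            tracklet_classification_accuracy([True], [True, False])


def test_occluded_actor_from_simulator_splits_then_fuses():
    """A 2-actor scene with one occlusion window produces >= 2 tracklets
    for the occluded actor, and appearance fusion reunites them."""
    from posepheno.simulate import ScenarioConfig, generate_scenario, random_actors

    actors = random_actors(2, seed=11)
    config = ScenarioConfig(
        n_frames=120,
        actors=actors,
        action_script=[("stand", 4.0)],
        occlusion_windows=[(actors[0].actor_id, 50, 70)],
        keypoint_jitter_sigma=0.5,
        seed=11,
    )
    stream, truth, _ = generate_scenario(config)
    tracklets = build_tracklets(stream, 0.1)
    by_actor = {}
    lookup = {}
    for f, i, actor_id in truth:
        lookup[id(stream[f].detections[i])] = actor_id
    for t in tracklets:
        by_actor.setdefault(lookup[id(t.detections[0])], []).append(t)
    target_tracklets = by_actor[actors[0].actor_id]
    assert len(target_tracklets) >= 2
    ref = max(target_tracklets, key=len)
    track = fuse_to_track(tracklets, ref.tracklet_id, tau=0.7)
    accepted = {tid for tid, ok in track.accepted.items() if ok}
    assert accepted == {t.tracklet_id for t in target_tracklets}
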