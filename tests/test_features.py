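import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bddkit as bk
from bddkit.errors import InsufficientDataError, ValidationError
from bddkit.features import ExpressionTrack, PoseTrack
from bddkit.labels import N_KEYPOINTS


def brute_force_entropy(weights, n_categories):
    """Independent term-by-term oracle: -sum p log p / log n."""
    total = sum(weights)
    acc = 0.0
    for w in weights:
        p = w / total
        if p > 0:
            acc -= p * math.log(p)
    return acc / math.log(n_categories)


def make_expression_track(probs, **kw):
    probs = np.atleast_2d(probs)
    return ExpressionTrack(np.arange(len(probs)), probs, **kw)


def make_pose_track(xy, present=None, **kw):
    xy = np.asarray(xy, float)
    if present is None:
        present = np.ones(xy.shape[:2], bool)
    return PoseTrack(np.arange(xy.shape[0]), xy, present, **kw)


class TestExpressionEntropy:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            ([1 / 7] * 7, 1.0),
            ([0, 0, 0, 0, 1, 0, 0], 0.0),
            ([0.5, 0.5, 0, 0, 0, 0, 0], math.log(2) / math.log(7)),
        ],
    )
    def test_reference_values(self, dist, expected):
        assert bk.expression_entropy(dist) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            p = rng.dirichlet(np.full(7, rng.uniform(0.2, 5.0)))
            assert bk.expression_entropy(p) == pytest.approx(
                brute_force_entropy(p, 7), abs=1e-12
            )

    def test_unnormalized_variant_in_nats(self):
        p = [0.5, 0.5, 0, 0, 0, 0, 0]
        assert bk.expression_entropy(p, normalized=False) == pytest.approx(
            math.log(2), abs=1e-12
        )

    @given(st.permutations(range(7)), st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, perm, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(7))
        assert bk.expression_entropy(p[list(perm)]) == pytest.approx(
            bk.expression_entropy(p), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    def test_concavity_jensen(self, seed):
        g = np.random.default_rng(seed)
        p, q = g.dirichlet(np.ones(7)), g.dirichlet(np.ones(7))
        mixed = bk.expression_entropy((p + q) / 2)
        avg = (bk.expression_entropy(p) + bk.expression_entropy(q)) / 2
        assert mixed >= avg - 1e-12

    def test_invalid_sum_rejected(self):
        with pytest.raises(ValidationError):
            bk.expression_entropy([0.2] * 7)


class TestAggregation:
    def test_mean_of_indicator_frames(self):
        track = make_expression_track(
            [[1, 0, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0, 0]]
        )
        agg = bk.aggregate_expression_distribution(track)
        assert np.allclose(agg.probs, [0.5, 0.5, 0, 0, 0, 0, 0])

    def test_single_frame_identity(self, rng):
        d = rng.dirichlet(np.ones(7))
        agg = bk.aggregate_expression_distribution(make_expression_track([d]))
        assert np.allclose(agg.probs, d, atol=1e-15)

    def test_permuted_frames_average_back(self, rng):
        base = rng.dirichlet(np.ones(7))
        # each class column holds a fixed multiset of values across frames
        frames = np.stack([base] * 100)
        agg = bk.aggregate_expression_distribution(make_expression_track(frames))
        assert np.allclose(agg.probs, base, atol=1e-12)

    def test_empty_track_errors(self):
        empty = ExpressionTrack(np.array([], int), np.empty((0, 7)))
        with pytest.raises(InsufficientDataError, match="no expression data"):
            bk.aggregate_expression_distribution(empty)


class TestMotionAmplitude:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0), (3, 4), 5.0),
            ((0.3, 0.7), (0.3, 0.7), 0.0),
            ((0.1, 0.2), (0.4, 0.6), 0.5),
        ],
    )
    def test_euclidean(self, a, b, expected):
        assert bk.motion_amplitude(a, b) == pytest.approx(expected, abs=1e-12)


class TestJointAmplitudes:
    def test_single_moving_joint(self):
        xy = np.full((3, N_KEYPOINTS, 2), 0.5)
        xy[:, 0, :] = [(0, 0), (0, 0.1), (0, 0.2)]
        amps = bk.joint_amplitudes(make_pose_track(xy), stride=1)
        assert amps.amplitude[0] == pytest.approx(0.1, abs=1e-12)
        assert np.all(amps.amplitude[1:] == 0)
        assert amps.dz == pytest.approx(0.1, abs=1e-12)

    def test_static_subject(self):
        xy = np.full((5, N_KEYPOINTS, 2), 0.5)
        amps = bk.joint_amplitudes(make_pose_track(xy))
        assert np.all(amps.amplitude == 0)
        assert amps.dz == 0

    def test_always_absent_joint(self):
        xy = np.full((4, N_KEYPOINTS, 2), 0.5)
        present = np.ones((4, N_KEYPOINTS), bool)
        present[:, 10] = False  # right ankle never captured
        amps = bk.joint_amplitudes(make_pose_track(xy, present))
        assert amps.amplitude[10] == 0
        assert amps.pair_count[10] == 0

    @pytest.mark.parametrize("stride", [1, 2, 5])
    def test_stride_scales_uniform_motion(self, stride):
        n = 12
        d = 0.01
        xy = np.full((n, N_KEYPOINTS, 2), 0.2)
        xy[:, 3, 1] = 0.1 + d * np.arange(n)  # constant per-frame displacement
        amps = bk.joint_amplitudes(make_pose_track(xy), stride=stride)
        assert amps.amplitude[3] == pytest.approx(stride * d, abs=1e-12)

    def test_too_few_frames(self):
        xy = np.full((1, N_KEYPOINTS, 2), 0.5)
        with pytest.raises(InsufficientDataError, match="insufficient pose data"):
            bk.joint_amplitudes(make_pose_track(xy))


class TestActionEntropy:
    @pytest.mark.parametrize(
        "amps, expected",
        [
            (np.full(N_KEYPOINTS, 0.3), 1.0),
            (np.eye(N_KEYPOINTS)[4] * 0.2, 0.0),
            (
                np.array([0.1, 0.1] + [0.0] * 16),
                math.log(2) / math.log(18),
            ),
        ],
    )
    def test_reference_values(self, amps, expected):
        assert bk.action_entropy(amps) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            d = rng.gamma(0.7, 0.02, N_KEYPOINTS)
            assert bk.action_entropy(d) == pytest.approx(
                brute_force_entropy(d, 18), abs=1e-12
            )

    @given(st.floats(1e-6, 1e6), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, c, seed):
        d = np.random.default_rng(seed).gamma(1.0, 0.01, N_KEYPOINTS)
        assert bk.action_entropy(c * d) == pytest.approx(
            bk.action_entropy(d), abs=1e-9
        )

    def test_static_subject_gives_zero(self):
        assert bk.action_entropy(np.zeros(N_KEYPOINTS)) == 0.0

    def test_negative_amplitude_rejected(self):
        d = np.zeros(N_KEYPOINTS)
        d[0] = -0.1
        with pytest.raises(ValidationError):
            bk.action_entropy(d)


class TestSessionFeatures:
    def test_uniform_everything(self, rng):
        etrack = make_expression_track([[1 / 7] * 7] * 3)
        xy = np.zeros((3, N_KEYPOINTS, 2))
        xy[0] = 0.2
        xy[1] = 0.3  # every joint moves the same amount each step
        xy[2] = 0.4
        feats = bk.session_features(etrack, make_pose_track(xy))
        assert feats.expression_entropy == pytest.approx(1.0, abs=1e-12)
        assert feats.action_entropy == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_everything(self):
        etrack = make_expression_track([[0, 0, 0, 0, 1, 0, 0]] * 3)
        xy = np.full((3, N_KEYPOINTS, 2), 0.5)
        xy[:, 0, 0] = [0.1, 0.2, 0.3]  # one joint moving
        feats = bk.session_features(etrack, make_pose_track(xy))
        assert feats.expression_entropy == 0.0
        assert feats.action_entropy == 0.0

    def test_severity_lowers_both_entropies(self):
        out = {}
        for s in (0.2, 0.8):
            etrack = bk.generate_expression_track(s, 300, kappa=80.0, seed=21)
            ptrack = bk.generate_pose_track(s, 300, alpha=0.02, seed=22)
            out[s] = bk.session_features(etrack, ptrack)
        assert out[0.8].expression_entropy < out[0.2].expression_entropy
        assert out[0.8].action_entropy < out[0.2].action_entropy

    def test_aggregation_modes_differ_but_agree_on_constant_tracks(self):
        etrack = make_expression_track([[0.5, 0.5, 0, 0, 0, 0, 0]] * 4)
        xy = np.zeros((4, N_KEYPOINTS, 2))
        xy[1:] = 0.1
        h1 = bk.session_features(etrack, make_pose_track(xy)).expression_entropy
        h2 = bk.session_features(
            etrack, make_pose_track(xy), aggregation="per_frame_mean"
        ).expression_entropy
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_strictly_increasing_frame_indices_enforced(self):
        with pytest.raises(ValidationError):
            ExpressionTrack(np.array([0, 0]), np.full((2, 7), 1 / 7))
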