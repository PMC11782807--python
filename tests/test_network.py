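"""AFFB algebra, two-stage fusion structure, and network contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cinefuse.network import (AFFB, AttentionWeights, ModelConfig,
                              MultiViewCineNet, load_checkpoint,
                              save_checkpoint)


def brute_force_affb(components, w, b):
    """Loop-based oracle: shared affine scorer, softmax, weighted sum."""
    n = len(components)
    raw = [sum(w[j] * f[j] for j in range(len(f))) + b for f in components]
    m = max(raw)
    exps = [np.exp(a - m) for a in raw]
    total = sum(exps)
    alpha = [e / total for e in exps]
    fused = [0.0] * len(components[0])
    for i in range(n):
        for j in range(len(fused)):
            fused[j] += alpha[i] * components[i][j]
    return np.array(fused), np.array(alpha)


def make_affb(d, seed=0, bias=True):
    return AFFB(d, np.random.default_rng(seed), bias=bias)


class TestAffbAlgebra:
    def test_weights_nonnegative_and_sum_to_one(self, rng):
        affb = make_affb(6)
        _, w = affb.fuse(rng.normal(size=(5, 6)))
        assert np.all(w.normalized >= 0)
        assert w.normalized.sum() == pytest.approx(1.0, abs=1e-6)

    def test_identical_components_are_fixed_point(self, rng):
        affb = make_affb(4)
        v = rng.normal(size=4).astype(np.float32)
        fused, w = affb.fuse(np.tile(v, (7, 1)))
        assert np.allclose(fused, v, atol=1e-5)
        assert np.allclose(w.normalized, 1 / 7, atol=1e-6)

    def test_singleton_identity(self, rng):
        affb = make_affb(5)
        v = rng.normal(size=(1, 5)).astype(np.float32)
        fused, w = affb.fuse(v)
        assert np.allclose(fused, v[0], atol=1e-6)
        assert w.normalized.tolist() == [1.0]

    def test_hand_computed_two_component_example(self):
        # scorer = first component (w = e1, b = 0), inputs (2,0) and (0,0):
        # alpha = softmax(2, 0) = (e^2, 1)/(e^2+1); fused = alpha_1 * (2, 0)
        affb = make_affb(2)
        affb.scorer.weight.data = np.array([[1.0], [0.0]], dtype=np.float32)
        affb.scorer.bias.data = np.zeros(1, dtype=np.float32)
        fused, w = affb.fuse(np.array([[2.0, 0.0], [0.0, 0.0]]))
        e2 = np.exp(2.0)
        assert np.allclose(w.normalized, [e2 / (e2 + 1), 1 / (e2 + 1)], atol=1e-6)
        assert np.allclose(w.normalized, [0.8808, 0.1192], atol=1e-4)
        assert np.allclose(fused, [1.7616, 0.0], atol=1e-4)

    def test_permutation_invariance_of_fused_feature(self, rng):
        affb = make_affb(8)
        comps = rng.normal(size=(24, 8)).astype(np.float32)
        perm = rng.permutation(24)
        fused_a, _ = affb.fuse(comps)
        fused_b, _ = affb.fuse(comps[perm])
        assert np.allclose(fused_a, fused_b, atol=1e-5)

    @pytest.mark.parametrize("n", [1, 2, 4, 20, 24])
    def test_matches_loop_oracle_on_random_instances(self, n, rng):
        for trial in range(20):
            d = int(rng.integers(1, 9))
            affb = make_affb(d, seed=trial)
            comps = rng.normal(size=(n, d)).astype(np.float32)
            fused, w = affb.fuse(comps)
            ref_fused, ref_alpha = brute_force_affb(
                comps.astype(np.float64).tolist(),
                affb.scorer.weight.data[:, 0].astype(np.float64),
                float(affb.scorer.bias.data[0]),
            )
            assert np.allclose(fused, ref_fused, atol=1e-5)
            assert np.allclose(w.normalized, ref_alpha, atol=1e-5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n=st.integers(2, 10), d=st.integers(1, 8), seed=st.integers(0, 50))
    def test_fused_feature_in_convex_hull(self, n, d, seed):
        rng = np.random.default_rng(seed)
        affb = make_affb(d, seed=seed)
        comps = rng.normal(size=(n, d)).astype(np.float32)
        fused, _ = affb.fuse(comps)
        assert np.all(fused >= comps.min(axis=0) - 1e-5)
        assert np.all(fused <= comps.max(axis=0) + 1e-5)

    def test_rejects_empty_and_mismatched_dimensions(self):
        affb = make_affb(3)
        with pytest.raises(ValueError):
            affb.fuse(np.empty((0, 3)))
        with pytest.raises(ValueError):
            affb.fuse(np.ones((2, 4)))

    def test_normalized_weights_validated(self):
        with pytest.raises(ValueError):
            AttentionWeights(raw=np.zeros(2), normalized=np.array([0.7, 0.7]))


class TestTwoStageFusion:
    def test_trace_feature_counts(self, tiny_net, rng):
        x = rng.random((4, 20, 32, 32)).astype(np.float32)
        pred, trace = tiny_net.forward(x)
        assert trace.frame_features.shape[:2] == (4, 20)
        assert trace.spatial_summaries.shape[0] == 20
        assert trace.temporal_summaries.shape[0] == 4
        assert trace.n_features == 80 + 24 + 1
        assert trace.all_predictions().shape == (105,)
        assert np.isfinite(pred)

    def test_all_equal_inputs_fix_every_summary(self, tiny_net, rng):
        # identical frames -> identical features -> fusion is a fixed point
        frame = rng.random((32, 32)).astype(np.float32)
        x = np.broadcast_to(frame, (4, 20, 32, 32)).copy()
        _, trace = tiny_net.forward(x)
        v = trace.frame_features[0, 0]
        assert np.allclose(trace.spatial_summaries, v, atol=1e-5)
        assert np.allclose(trace.temporal_summaries, v, atol=1e-5)
        assert np.allclose(trace.final_feature, v, atol=1e-5)

    def test_every_weight_group_sums_to_one(self, tiny_net, rng):
        x = rng.random((4, 20, 32, 32)).astype(np.float32)
        _, trace = tiny_net.forward(x)
        for w in (*trace.view_weights, *trace.phase_weights, trace.stage2_weights):
            assert np.all(w.normalized >= 0)
            assert w.normalized.sum() == pytest.approx(1.0, abs=1e-6)
        assert len(trace.view_weights) == 20
        assert len(trace.phase_weights) == 4
        assert trace.stage2_weights.normalized.shape == (24,)

    def test_dimension_preserved_through_all_fusions(self, tiny_net, rng):
        x = rng.random((2, 4, 20, 32, 32)).astype(np.float32)
        _, bt = tiny_net.forward_trace(x)
        d = tiny_net.config.feature_dim
        assert bt.frame_features.shape[-1] == d
        assert bt.spatial_summaries.shape[-1] == d
        assert bt.temporal_summaries.shape[-1] == d
        assert bt.final_feature.shape[-1] == d

    def test_strict_mode_rejects_incomplete_grid(self, tiny_net, rng):
        with pytest.raises(ValueError, match="strict"):
            tiny_net.predict(rng.random((1, 3, 20, 32, 32)).astype(np.float32))

    def test_tolerant_mode_accepts_variable_grid(self, tiny_config, rng):
        tiny_config.strict = False
        net = MultiViewCineNet(tiny_config, seed=0)
        out = net.predict(rng.random((2, 2, 7, 32, 32)).astype(np.float32))
        assert out.shape == (2,) and np.all(np.isfinite(out))


class TestSharedComponents:
    def test_encoder_deterministic_and_shared(self, tiny_net, rng):
        frame = rng.random((32, 32)).astype(np.float32)
        a = tiny_net.encode_frame(frame)
        b = tiny_net.encode_frame(frame)
        assert np.array_equal(a, b)
        assert a.shape == (tiny_net.config.feature_dim,)
        assert np.all(np.isfinite(a))

    def test_encode_frame_rejects_wrong_size(self, tiny_net, rng):
        with pytest.raises(ValueError):
            tiny_net.encode_frame(rng.random((16, 16)))

    def test_parameter_count_independent_of_views_and_phases(self):
        base = dict(input_size=32, encoder_pool=1, feature_dim=8,
                    encoder_channels=(4, 8))
        n4 = MultiViewCineNet(ModelConfig(**base), seed=0).n_parameters()
        n2 = MultiViewCineNet(ModelConfig(views=("2CH", "SAX"), n_phases=5, **base),
                              seed=0).n_parameters()
        assert n4 == n2

    def test_regression_layer_is_affine_and_shared(self, tiny_net, rng):
        # zero weights, bias b -> every feature predicts b
        tiny_net.head.weight.data[:] = 0.0
        tiny_net.head.bias.data[:] = 3.5
        feats = rng.normal(size=(7, tiny_net.config.feature_dim)).astype(np.float32)
        assert np.allclose(tiny_net.regress(feats), 3.5, atol=1e-6)

    def test_identical_exams_identical_predictions(self, tiny_net, rng):
        x = rng.random((1, 4, 20, 32, 32)).astype(np.float32)
        p1 = tiny_net.predict(x)
        p2 = tiny_net.predict(x.copy())
        assert np.array_equal(p1, p2)


def test_checkpoint_roundtrip(tmp_path, tiny_net, rng):
    x = rng.random((2, 4, 20, 32, 32)).astype(np.float32)
    before = tiny_net.predict(x)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, tiny_net, {"target": "mPAP", "note": 1})
    net2, meta = load_checkpoint(path)
    assert meta["target"] == "mPAP"
    assert np.array_equal(net2.predict(x), before)
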