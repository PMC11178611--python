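"""Channel weightings, map assembly, aggregation, and the explain pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xrelcam import cammethods
from xrelcam.cammethods import (CAMExplainer, ChannelWeights, aggregate_layers,
                                assemble_cam, explain, gradient_weights,
                                relevance_weights, xrelevance_weights)
from xrelcam.lrpcore import clrp_init, propagate
from xrelcam.netkit import forward_capture


def _cw(w, stage="layer4"):
    w = np.asarray(w, dtype=float)
    return ChannelWeights(stage, 0, w, np.zeros(len(w), dtype=bool))


class TestWeightings:
    def test_xrelevance_is_relevance_over_activation(self):
        acts = np.full((1, 2, 2), 3 / 4)       # sums to 3
        rels = np.full((1, 2, 2), 6 / 4)       # sums to 6
        w = xrelevance_weights(acts, rels)
        assert w.weights[0] == pytest.approx(2.0)

    def test_dead_channel_guarded_to_zero(self):
        acts = np.zeros((1, 2, 2))
        rels = np.full((1, 2, 2), 0.3 / 4)
        w = xrelevance_weights(acts, rels)
        assert w.weights[0] == 0.0
        assert w.guarded[0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            xrelevance_weights(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_weighted_activation_sum_equals_total_relevance(self, seed):
        """Identity of the weighting: sum_k w_k*(sum A) == sum_k sum R."""
        rng = np.random.default_rng(seed)
        acts = rng.normal(size=(5, 4, 4)) + 0.5
        rels = rng.normal(size=(5, 4, 4))
        w = xrelevance_weights(acts, rels)
        free = ~w.guarded
        lhs = (w.weights[free]
               * acts.reshape(5, -1).sum(axis=1)[free]).sum()
        rhs = rels.reshape(5, -1).sum(axis=1)[free].sum()
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_relevance_weights_are_channel_means(self):
        rels = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        assert relevance_weights(rels).weights[0] == pytest.approx(4.0)
        assert np.all(relevance_weights(np.zeros((3, 2, 2))).weights == 0)

    def test_relevance_weights_linear_in_relevance(self):
        rng = np.random.default_rng(0)
        rels = rng.normal(size=(4, 3, 3))
        assert np.allclose(relevance_weights(5.0 * rels).weights,
                           5.0 * relevance_weights(rels).weights)

    def test_gradcam_weight_is_mean_gradient(self):
        grads = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        acts = np.ones_like(grads)
        w = gradient_weights(acts, grads, "gradcam")
        assert w.weights[0] == pytest.approx(4.0)

    def test_xgradcam_weight_is_activation_weighted(self):
        acts = np.array([[[1.0, 2.0], [3.0, 4.0]]])       # sum 10
        grads = acts.copy()                               # sum(A*A) = 30
        w = gradient_weights(acts, grads, "xgradcam")
        assert w.weights[0] == pytest.approx(3.0)

    def test_zero_gradient_gives_zero_weights(self):
        acts = np.ones((2, 3, 3))
        grads = np.zeros_like(acts)
        for variant in ("gradcam", "xgradcam"):
            assert np.all(gradient_weights(acts, grads, variant).weights == 0)


class TestAssembleAndAggregate:
    def test_weighted_sum_and_normalization(self):
        acts = np.stack([[[0.0, 2.0], [4.0, 8.0]],
                         [[9.0, 9.0], [9.0, 9.0]]])
        sm = assemble_cam(acts, _cw([1.0, 0.0]), (2, 2))
        assert np.allclose(sm.values, [[0.0, 0.25], [0.5, 1.0]])

    def test_constant_raw_map_normalizes_to_zeros(self):
        acts = np.full((1, 2, 2), 5.0)
        sm = assemble_cam(acts, _cw([1.0]), (2, 2))
        assert np.all(sm.values == 0.0)

    def test_negative_values_clipped_by_default(self):
        acts = np.array([[[-4.0, 1.0], [2.0, 3.0]]])
        clipped = assemble_cam(acts, _cw([1.0]), (2, 2))
        assert clipped.values[0, 0] == 0.0
        raw = assemble_cam(acts, _cw([1.0]), (2, 2), clip_negative=False)
        assert raw.values[0, 0] == 0.0 and raw.values.max() == 1.0
        assert not np.allclose(clipped.values, raw.values)

    @pytest.mark.parametrize("t", [0.5, 3.0, 100.0])
    def test_uniform_weight_scaling_leaves_map_invariant(self, t):
        rng = np.random.default_rng(1)
        acts = rng.random((6, 8, 8))
        w = rng.normal(size=6)
        base = assemble_cam(acts, _cw(w), (32, 32))
        scaled = assemble_cam(acts, _cw(t * w), (32, 32))
        if t == 0.5:  # power-of-two scaling is exact in floating point
            assert np.array_equal(base.values, scaled.values)
        assert np.abs(base.values - scaled.values).max() < 1e-12

    def test_upsampling_to_input_resolution(self):
        acts = np.random.default_rng(0).random((3, 4, 4))
        sm = assemble_cam(acts, _cw([1.0, -0.5, 2.0]), (64, 64))
        assert sm.values.shape == (64, 64)
        assert sm.values.min() == 0.0 and sm.values.max() == 1.0

    def test_aggregate_single_stage_is_identity(self):
        rng = np.random.default_rng(2)
        sm = assemble_cam(rng.random((2, 4, 4)), _cw([1.0, 1.0]), (8, 8))
        agg = aggregate_layers({"layer4": sm}, ("layer4",))
        assert np.allclose(agg.values, sm.values)

    def test_aggregate_identical_maps_is_identity(self):
        rng = np.random.default_rng(3)
        sm = assemble_cam(rng.random((2, 4, 4)), _cw([1.0, 0.5]), (8, 8))
        agg = aggregate_layers({"layer3": sm, "layer4": sm},
                               ("layer3", "layer4"))
        assert np.allclose(agg.values, sm.values)

    def test_aggregate_constant_mean_goes_to_zeros(self):
        from xrelcam.cammethods import SaliencyMap
        m1 = SaliencyMap(np.array([[0.0, 1.0]]), frozenset({"layer1"}), 0)
        m2 = SaliencyMap(np.array([[1.0, 0.0]]), frozenset({"layer2"}), 0)
        agg = aggregate_layers({"layer1": m1, "layer2": m2},
                               ("layer1", "layer2"))
        assert np.all(agg.values == 0.0)

    def test_empty_stage_selection_rejected(self):
        with pytest.raises(ValueError):
            aggregate_layers({}, ())


class TestExplain:
    def test_unknown_method_rejected(self, small_model, small_image):
        with pytest.raises(ValueError, match="unknown method"):
            explain(small_model, small_image, 0, method="bogus")

    @pytest.mark.parametrize("method", cammethods.METHODS)
    def test_maps_are_normalized_at_input_resolution(self, small_model,
                                                     small_image, method):
        maps = explain(small_model, small_image, 0, method=method)
        assert set(maps) == {"layer1", "layer2", "layer3", "layer4",
                             "aggregate"}
        for m in maps.values():
            assert m.values.shape == small_image.shape
            assert m.values.min() >= 0.0 and m.values.max() <= 1.0
            assert m.values.max() in (0.0, 1.0)

    def test_deterministic_without_dropout(self, small_model, small_image):
        a = explain(small_model, small_image, 0)
        b = explain(small_model, small_image, 0)
        for k in a:
            assert np.array_equal(a[k].values, b[k].values)

    def test_gradcam_weights_match_finite_difference_oracle(self, small_model,
                                                            small_image):
        """Backprop stage gradients agree with resume-forward differences."""
        acts = forward_capture(small_model, small_image)
        c = 0
        grads = cammethods._gradients_for(small_model, acts, c)
        rng = np.random.default_rng(0)
        for stage in ("layer3", "layer4"):
            a = acts.activations[stage]
            g = grads[stage]
            eps = 1e-5
            for _ in range(5):
                k = rng.integers(a.shape[0])
                i = rng.integers(a.shape[1])
                j = rng.integers(a.shape[2])
                ap, am = a.copy(), a.copy()
                ap[k, i, j] += eps
                am[k, i, j] -= eps
                lp = small_model.forward_from(stage, ap[None])[0, c]
                lm = small_model.forward_from(stage, am[None])[0, c]
                assert (lp - lm) / (2 * eps) == pytest.approx(
                    g[k, i, j], rel=1e-3, abs=1e-6)

    def test_both_relevance_methods_share_one_relevance_stack(
            self, small_model, small_image):
        """Only the weighting differs between the two relevance methods."""
        acts = forward_capture(small_model, small_image)
        init = clrp_init(acts.logits, 0)
        rels = propagate(small_model, acts, init)
        for stage in ("layer2", "layer4"):
            wx = cammethods.compute_weights("xrelevancecam", acts, stage,
                                            rels=rels)
            wr = cammethods.compute_weights("relevancecam", acts, stage,
                                            rels=rels)
            a = acts.activations[stage]
            r = rels.relevances[stage]
            a_sum = a.reshape(a.shape[0], -1).sum(axis=1)
            free = ~wx.guarded
            assert np.allclose(wx.weights[free],
                               r.reshape(r.shape[0], -1).sum(axis=1)[free]
                               / a_sum[free])
            assert np.allclose(wr.weights,
                               r.reshape(r.shape[0], -1).mean(axis=1))


class TestExplainerEstimator:
    def test_transform_shapes_and_range(self, small_model):
        rng = np.random.default_rng(0)
        X = rng.random((3, 32, 32))
        expl = CAMExplainer(small_model).fit()
        out = expl.transform(X)
        assert out.shape == (3, 32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unfitted_estimator_rejected(self):
        from xrelcam.netkit import CNNClassifier
        with pytest.raises(ValueError, match="fitted"):
            CAMExplainer(CNNClassifier()).fit()

    def test_get_set_params_roundtrip(self, small_model):
        expl = CAMExplainer(small_model, method="gradcam")
        assert expl.get_params()["method"] == "gradcam"
        expl.set_params(method="xrelevancecam")
        assert expl.method == "xrelevancecam"
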