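import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from tumorgrade.bcnn import (
    FCLayer,
    NormState,
    conv_forward,
    fc_forward,
    hard_sigmoid,
    maxpool,
    minmax_normalize,
    sign_binarize,
    softmax,
    softmax_predict,
    stochastic_binarize,
)

from .oracles import conv_loops, maxpool_loops


class TestBinarization:
    def test_sign_zero_maps_to_plus_one(self):
        assert sign_binarize(0.0) == 1.0
        assert sign_binarize(-0.3) == -1.0
        np.testing.assert_array_equal(sign_binarize([-2.0, 0.0, 5.0]), [-1, 1, 1])

    def test_hard_sigmoid_saturation_and_midpoint(self):
        assert hard_sigmoid(1.0) == 1.0
        assert hard_sigmoid(-1.0) == 0.0
        assert hard_sigmoid(0.0) == 0.5
        assert hard_sigmoid(100.0) == 1.0

    def test_stochastic_saturates_at_extremes(self):
        x = np.full(1000, 3.0)
        assert (stochastic_binarize(x, 0) == 1.0).all()
        assert (stochastic_binarize(-x, 0) == -1.0).all()

    def test_stochastic_mean_at_zero_is_unbiased(self):
        draws = stochastic_binarize(np.zeros(10_000), np.random.default_rng(4))
        assert abs(draws.mean()) <= 0.03  # 3 sigma of a fair +-1 coin

    def test_stochastic_reproducible_under_seed(self):
        x = np.linspace(-1, 1, 50)
        np.testing.assert_array_equal(stochastic_binarize(x, 8),
                                      stochastic_binarize(x, 8))

    def test_stochastic_plus_one_rate_tracks_hard_sigmoid(self):
        rng = np.random.default_rng(2)
        for v in (-0.6, -0.2, 0.4, 0.8):
            draws = stochastic_binarize(np.full(20_000, v), rng)
            rate = (draws == 1.0).mean()
            assert abs(rate - hard_sigmoid(v)) < 0.02


class TestConvForward:
    def test_identity_kernel(self, rng):
        x = rng.normal(size=(5, 5, 1))
        k = np.ones((1, 1, 1, 1))
        np.testing.assert_allclose(conv_forward(x, k), x)

    def test_output_dimension_formula(self):
        out = conv_forward(np.zeros((64, 64, 1)), np.zeros((3, 3, 1, 8)))
        assert out.shape == (62, 62, 8)

    def test_matches_loop_oracle(self, rng):
        for _ in range(15):
            x = rng.normal(size=(6, 6, 2))
            k = rng.normal(size=(3, 3, 2, 4))
            stride = int(rng.integers(1, 3))
            pad = int(rng.integers(0, 3))
            np.testing.assert_allclose(conv_forward(x, k, stride, pad),
                                       conv_loops(x, k, stride, pad), atol=1e-9)

    def test_depth_mismatch_and_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            conv_forward(np.zeros((4, 4, 2)), np.zeros((3, 3, 1, 1)))
        with pytest.raises(ValueError):
            conv_forward(np.zeros((2, 2, 1)), np.zeros((5, 5, 1, 1)))


class TestMaxPool:
    def test_single_window(self):
        out = maxpool(np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None])
        assert out.shape == (1, 1, 1) and out[0, 0, 0] == 4.0

    def test_4x4_to_2x2(self):
        assert maxpool(np.zeros((4, 4, 3))).shape == (2, 2, 3)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(8, 8, 3))
        np.testing.assert_allclose(maxpool(x), maxpool_loops(x), atol=1e-12)

    def test_indivisible_and_oversized_rejected(self):
        with pytest.raises(ValueError):
            maxpool(np.zeros((5, 4, 1)))
        with pytest.raises(ValueError):
            maxpool(np.zeros((1, 1, 1)), window=2, stride=2)


class TestMinMaxNormalize:
    def test_two_point_example(self):
        x = np.array([0.0, 10.0])[:, None]
        out = minmax_normalize(x, NormState())
        np.testing.assert_allclose(out.ravel(), [-0.5, 0.5])

    def test_constant_channel_maps_to_zeros(self):
        out = minmax_normalize(np.full((4, 3, 2), 7.0), NormState())
        np.testing.assert_array_equal(out, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(x=hnp.arrays(np.float64, (6, 3),
                        elements=st.floats(-100, 100, allow_nan=False)))
    def test_output_bounded_in_unit_interval(self, x):
        out = minmax_normalize(x, NormState())
        assert (np.abs(out) <= 1.0 + 1e-12).all()

    def test_minmax01_mode_range(self, rng):
        x = rng.normal(size=(10, 4))
        out = minmax_normalize(x, NormState(), mode="minmax01")
        assert out.min() >= -1e-12 and out.max() <= 1 + 1e-12

    def test_running_state_momentum_update(self):
        state = NormState()
        x1 = np.array([0.0, 10.0])[:, None]
        minmax_normalize(x1, state, training=True)
        np.testing.assert_allclose(state.running_mean, [5.0])
        x2 = np.array([0.0, 20.0])[:, None]
        minmax_normalize(x2, state, training=True)
        np.testing.assert_allclose(state.running_mean, [0.9 * 5 + 0.1 * 10])
        np.testing.assert_allclose(state.running_max, [0.9 * 10 + 0.1 * 20])

    def test_inference_uses_running_state(self):
        state = NormState()
        minmax_normalize(np.array([0.0, 10.0])[:, None], state, training=True)
        out = minmax_normalize(np.array([5.0])[:, None], state, training=False)
        np.testing.assert_allclose(out.ravel(), [0.0])  # (5 - 5)/10


class TestFCLayer:
    def test_identity_layer(self):
        layer = FCLayer(np.eye(3), np.zeros(3), activation="identity")
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(fc_forward(x, layer), x)

    def test_relu_clips_negative_preactivations(self):
        layer = FCLayer(np.array([[1.0, 0.0], [0.0, 1.0]]),
                        np.array([-3.0, 1.0]), activation="relu")
        np.testing.assert_allclose(fc_forward(np.array([1.0, 2.0]), layer), [0.0, 3.0])

    def test_small_matrix_against_hand_computation(self):
        w = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        b = np.array([1.0, -1.0, 0.0])
        layer = FCLayer(w, b, activation="identity")
        out = fc_forward(np.array([1.0, 1.0]), layer)
        np.testing.assert_allclose(out, [4.0, 6.0, 11.0])

    def test_shape_mismatch_rejected(self):
        layer = FCLayer(np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            fc_forward(np.zeros(4), layer)


class TestSoftmax:
    def test_equal_logits_give_uniform_probabilities(self):
        probs, label = softmax_predict(np.zeros(5))
        np.testing.assert_allclose(probs, 0.2)
        assert label == 0  # tie broken toward the lowest index

    def test_closed_form_two_class(self):
        probs, label = softmax_predict(np.array([0.0, np.log(3.0)]))
        np.testing.assert_allclose(probs, [0.25, 0.75], atol=1e-12)
        assert label == 1

    @settings(deadline=None, max_examples=40)
    @given(logits=hnp.arrays(np.float64, st.integers(2, 7),
                             elements=st.floats(-500, 500, allow_nan=False)))
    def test_probabilities_form_a_simplex_point(self, logits):
        probs, label = softmax_predict(logits)
        assert abs(probs.sum() - 1.0) < 1e-9
        assert (probs >= 0).all()
        assert label == int(np.argmax(probs))

    def test_stable_for_large_logits(self):
        probs = softmax(np.array([1000.0, 1000.0]))
        np.testing.assert_allclose(probs, [0.5, 0.5])
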