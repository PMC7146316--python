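"""Layer formulas against hand-worked values and brute-force oracles,
architecture shape arithmetic, gradients, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hsicnn.cnn_core import (
    BatchNormState,
    Network,
    TrainConfig,
    TrainedModel,
    _cross_entropy,
    batch_norm_forward,
    build_spec_1d,
    build_spec_2d,
    conv1d_forward,
    conv2d_forward,
    load_model,
    maxpool,
    predict_labels,
    predict_proba,
    relu,
    save_model,
    softmax,
    train,
)
from hsicnn.preprocess import Preprocessor
from hsicnn.hsi_io import HSICube


# --------------------------------------------------------------------------
# elementwise pieces
# --------------------------------------------------------------------------

def test_relu_definition():
    np.testing.assert_array_equal(relu(np.array([-3.0, 0.0, 2.5])), [0.0, 0.0, 2.5])


class TestSoftmax:
    def test_closed_form(self):
        np.testing.assert_allclose(softmax(np.array([0.0, np.log(3)])), [0.25, 0.75], atol=1e-12)

    def test_uniform_input(self):
        np.testing.assert_allclose(softmax(np.full(7, 3.3)), np.full(7, 1 / 7), atol=1e-12)

    def test_simplex_for_extreme_inputs(self, rng):
        x = rng.normal(scale=300, size=(20, 9))
        p = softmax(x, axis=1)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8), st.floats(-100, 100))
    def test_shift_invariance(self, xs, shift):
        x = np.array(xs)
        np.testing.assert_allclose(softmax(x), softmax(x + shift), atol=1e-9)


class TestBatchNorm:
    def test_hand_worked_pair(self):
        state = BatchNormState.create(1)
        out = batch_norm_forward(np.array([[1.0], [3.0]]), state, mode="train")
        np.testing.assert_allclose(out[:, 0], [-1.0, 1.0], atol=1e-4)

    def test_constant_batch_guarded_by_eps(self):
        state = BatchNormState.create(3)
        out = batch_norm_forward(np.full((4, 3), 2.0), state, mode="train")
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_affine_scale_and_offset(self):
        state = BatchNormState.create(1)
        state.gamma[:] = 2.0
        state.beta[:] = 5.0
        out = batch_norm_forward(np.array([[1.0], [3.0]]), state, mode="train")
        np.testing.assert_allclose(out[:, 0], [3.0, 7.0], atol=1e-3)

    def test_single_sample_train_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_norm_forward(np.ones((1, 4)), BatchNormState.create(4), mode="train")

    def test_infer_mode_uses_running_statistics(self):
        state = BatchNormState.create(2)
        state.running_mean = np.array([1.0, -1.0])
        state.running_var = np.array([4.0, 0.25])
        out = batch_norm_forward(np.array([[3.0, 0.0]]), state, mode="infer")
        np.testing.assert_allclose(out[0], [1.0, 2.0], atol=1e-4)

    def test_normalizes_random_batches(self, rng):
        # vector batch: one statistic per feature
        x = rng.normal(3, 5, size=(32, 6))
        out = batch_norm_forward(x, BatchNormState.create(6), mode="train")
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=0), 1, atol=1e-3)
        # conv feature maps: one statistic per channel
        xc = rng.normal(-2, 0.5, size=(8, 3, 10))
        outc = batch_norm_forward(xc, BatchNormState.create(3), mode="train")
        np.testing.assert_allclose(outc.mean(axis=(0, 2)), 0, atol=1e-10)
        np.testing.assert_allclose(outc.var(axis=(0, 2)), 1, atol=1e-3)


class TestMaxpool:
    def test_1d_definition(self):
        np.testing.assert_array_equal(maxpool(np.array([3, 1, 4, 1, 5, 9.0]), 2), [3, 4, 9])

    def test_floor_truncation(self):
        assert maxpool(np.arange(7.0), 2).shape == (3,)

    def test_2d_window_maxima(self):
        grid = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(maxpool(grid, 2), [[5, 7], [13, 15]])

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            maxpool(np.arange(4.0), 1)

    def test_input_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            maxpool(np.array([1.0]), 2)

    @given(st.integers(4, 30), st.integers(2, 4))
    def test_output_length_floor_rule(self, n, ell):
        x = np.arange(float(n))
        assert maxpool(x, ell).shape == (n // ell,)


# --------------------------------------------------------------------------
# convolution against brute-force oracles
# --------------------------------------------------------------------------

def _brute_conv1d(x, w, b):
    """Nested-loop cross-correlation with edge-replicate right padding."""
    C, L = x.shape
    n = w.shape[0]
    xp = np.concatenate([x, x[:, -1:]], axis=1)
    out = np.zeros((n, L))
    for f in range(n):
        for i in range(L):
            acc = 0.0
            for c in range(C):
                for k in range(2):
                    acc += w[f, c, k] * xp[c, i + k]
            out[f, i] = acc + b[f]
    return out


def _brute_conv2d(x, w, b):
    C, H, W = x.shape
    n = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 1), (0, 1)), mode="edge")
    out = np.zeros((n, H, W))
    for f in range(n):
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for c in range(C):
                    for ki in range(2):
                        for kj in range(2):
                            acc += w[f, c, ki, kj] * xp[c, i + ki, j + kj]
                out[f, i, j] = acc + b[f]
    return out


class TestConv:
    def test_identity_kernel(self):
        out = conv1d_forward(np.array([[1.0, 2.0, 3.0]]), np.array([[[1.0, 0.0]]]), np.zeros(1))
        np.testing.assert_array_equal(out, [[1, 2, 3]])

    def test_sliding_sum_kernel(self):
        out = conv1d_forward(np.array([[1.0, 2.0, 3.0]]), np.array([[[1.0, 1.0]]]), np.zeros(1))
        # last window sums the replicated edge
        np.testing.assert_array_equal(out, [[3, 5, 6]])

    def test_twenty_filters_make_twenty_maps(self, rng):
        out = conv1d_forward(
            rng.normal(size=(1, 12)), rng.normal(size=(20, 1, 2)), rng.normal(size=20)
        )
        assert out.shape == (20, 12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv1d_forward(rng.normal(size=(2, 5)), rng.normal(size=(4, 3, 2)), np.zeros(4))

    def test_1d_matches_brute_force(self, rng):
        for _ in range(10):
            C = int(rng.integers(1, 4))
            L = int(rng.integers(2, 9))
            n = int(rng.integers(1, 5))
            x = rng.normal(size=(C, L))
            w = rng.normal(size=(n, C, 2))
            b = rng.normal(size=n)
            np.testing.assert_allclose(
                conv1d_forward(x, w, b), _brute_conv1d(x, w, b), atol=1e-10
            )

    def test_2d_matches_brute_force(self, rng):
        for _ in range(8):
            C = int(rng.integers(1, 4))
            H = int(rng.integers(2, 8))
            W = int(rng.integers(2, 8))
            n = int(rng.integers(1, 4))
            x = rng.normal(size=(C, H, W))
            w = rng.normal(size=(n, C, 2, 2))
            b = rng.normal(size=n)
            np.testing.assert_allclose(
                conv2d_forward(x, w, b), _brute_conv2d(x, w, b), atol=1e-10
            )


# --------------------------------------------------------------------------
# architecture builders and shape recursion
# --------------------------------------------------------------------------

class TestSpecBuilders:
    @pytest.mark.parametrize(
        "n,feature,fc_in",
        [(204, 12, 240), (645, 40, 800), (641, 40, 800), (16, 1, 20), (1964, 122, 2440)],
    )
    def test_1d_shape_recursion(self, n, feature, fc_in):
        spec = build_spec_1d(n, 16, depth=4)
        assert spec.feature_size == feature and spec.fc_in == fc_in

    def test_2d_benchmark_window(self):
        spec = build_spec_2d(21, 1, 16, depth=4)
        assert spec.feature_size == 1 and spec.fc_in == 20
        spec4 = build_spec_2d(21, 4, 16, depth=4)
        assert spec4.blocks[0].in_channels == 4

    def test_collapse_error_names_block(self):
        with pytest.raises(ValueError, match="block"):
            build_spec_2d(3, 1, 16, depth=4)
        with pytest.raises(ValueError, match="block"):
            build_spec_1d(8, 4, depth=4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_spec_1d(64, 1)

    @given(st.integers(16, 700))
    def test_forward_matches_declared_fc_size(self, n):
        spec = build_spec_1d(n, 3, depth=4, filters=4)
        net = Network(spec, seed=0)
        logits = net.forward(np.zeros((2, n)) + 0.5, train=False)
        assert logits.shape == (2, 3)

    @given(st.sampled_from([17, 21, 25, 31, 41]), st.integers(1, 3))
    def test_2d_forward_shape(self, r, q):
        spec = build_spec_2d(r, q, 4, depth=4, filters=3)
        net = Network(spec, seed=0)
        logits = net.forward(np.ones((2, r, r, q)), train=False)
        assert logits.shape == (2, 4)


# --------------------------------------------------------------------------
# gradients
# --------------------------------------------------------------------------

def _check_gradients(spec, X, y, seed=7, eps=1e-6, tol=1e-4):
    net = Network(spec, seed=seed)
    net.zero_grad()
    loss, g = _cross_entropy(net.forward(X, train=True), y)
    net.backward(g)
    rng = np.random.default_rng(0)
    for p in net.parameters():
        flat, gflat = p.value.ravel(), p.grad.ravel()
        for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            l1, _ = _cross_entropy(net.forward(X, train=True), y)
            flat[i] = orig - eps
            l2, _ = _cross_entropy(net.forward(X, train=True), y)
            flat[i] = orig
            numeric = (l1 - l2) / (2 * eps)
            assert abs(numeric - gflat[i]) <= tol * max(1.0, abs(numeric), abs(gflat[i]))


class TestGradients:
    def test_numeric_vs_analytic_1d(self, rng):
        spec = build_spec_1d(12, 3, depth=2, filters=3)
        _check_gradients(spec, rng.normal(size=(6, 12)), rng.integers(0, 3, size=6))

    def test_numeric_vs_analytic_2d(self, rng):
        spec = build_spec_2d(7, 2, 3, depth=2, filters=3)
        _check_gradients(spec, rng.normal(size=(6, 7, 7, 2)), rng.integers(0, 3, size=6))


# --------------------------------------------------------------------------
# training and prediction
# --------------------------------------------------------------------------

def _separable_toy(rng, n_per_class=30, n=16):
    base = rng.uniform(0.2, 1.0, size=n)
    X = np.vstack(
        [
            base + rng.normal(0, 0.05, size=(n_per_class, n)),
            base + 1.0 + rng.normal(0, 0.05, size=(n_per_class, n)),
        ]
    )
    y = np.repeat([1, 2], n_per_class)
    return X, y


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self, rng):
        X, y = _separable_toy(rng)
        spec = build_spec_1d(16, 2, depth=4)
        net, history = train(spec, X, y, TrainConfig(epochs=50, seed=1))
        assert history[-1] < history[0]
        assert (predict_labels(net, X) == y).mean() == 1.0

    def test_same_seed_is_deterministic(self, rng):
        X, y = _separable_toy(rng, n_per_class=12)
        spec = build_spec_1d(16, 2, depth=3)
        cfg = TrainConfig(epochs=5, seed=9)
        net_a, hist_a = train(spec, X, y, cfg)
        net_b, hist_b = train(spec, X, y, cfg)
        assert hist_a == hist_b
        for pa, pb in zip(net_a.parameters(), net_b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_single_class_rejected(self, rng):
        spec = build_spec_1d(16, 2, depth=2)
        with pytest.raises(ValueError):
            train(spec, rng.normal(size=(10, 16)), np.ones(10, dtype=int))

    def test_zero_epoch_budget_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=1)

    def test_prediction_rows_are_probabilities_with_low_index_ties(self):
        spec = build_spec_1d(16, 3, depth=2)
        net = Network(spec, seed=0)
        for p in net.parameters():
            p.value[...] = 0.0  # all logits equal -> exact three-way tie
        X = np.ones((5, 16))
        proba = predict_proba(net, X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(proba, 1 / 3, atol=1e-12)
        assert (predict_labels(net, X) == 1).all()


class TestSerialization:
    def test_round_trip_reproduces_predictions_bit_exactly(self, rng, tmp_path):
        cube = HSICube(rng.uniform(size=(8, 8, 12)))
        pixels = np.column_stack(
            [rng.integers(0, 8, 40), rng.integers(0, 8, 40), rng.integers(1, 3, 40)]
        )
        pp = Preprocessor(mode="spectral").fit(cube, pixels)
        X = pp.transform(cube, pixels)
        spec = build_spec_1d(12, 2, depth=2)
        net, hist = train(spec, X, pixels[:, 2], TrainConfig(epochs=3, seed=2))
        model = TrainedModel(spec, net, pp, ["a", "b"], hist)
        ref_labels, ref_proba = model.predict_pixels(cube, pixels)
        path = save_model(model, tmp_path / "model.npz")
        loaded = load_model(path)
        new_labels, new_proba = loaded.predict_pixels(cube, pixels)
        np.testing.assert_array_equal(ref_labels, new_labels)
        np.testing.assert_array_equal(ref_proba, new_proba)
        assert loaded.class_names == ["a", "b"]

    def test_band_count_mismatch_rejected_at_predict(self, rng, tmp_path):
        cube = HSICube(rng.uniform(size=(6, 6, 10)))
        pixels = np.column_stack(
            [rng.integers(0, 6, 30), rng.integers(0, 6, 30), rng.integers(1, 3, 30)]
        )
        pp = Preprocessor(mode="spectral").fit(cube, pixels)
        X = pp.transform(cube, pixels)
        spec = build_spec_1d(10, 2, depth=2)
        net, _ = train(spec, X, pixels[:, 2], TrainConfig(epochs=2, seed=0))
        model = TrainedModel(spec, net, pp, ["a", "b"])
        other = HSICube(rng.uniform(size=(6, 6, 7)))
        with pytest.raises(ValueError):
            model.predict_pixels(other, pixels)
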