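import numpy as np
import pytest

from respmotion.model import (
    attention,
    autoencode_head,
    backward_batch,
    forward_batch,
    init_params,
    lstm_step,
    lstm_unroll,
    predict,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def zero_params(d=3, d_latent=2, head="attention_ae"):
    p = init_params(d=d, d_latent=d_latent, seed=0, head=head)
    for k, v in p.as_dict().items():
        v[...] = 0.0
    return p


class TestLstmStep:
    def test_zero_parameters_give_zero_state(self):
        p = zero_params(d=4)
        h, c = lstm_step(1.7, np.zeros(4), np.zeros(4), p)
        np.testing.assert_array_equal(h, np.zeros(4))
        np.testing.assert_array_equal(c, np.zeros(4))

    def test_scalar_hand_computation(self):
        # d=1, all pre-activations equal 1, zero previous state:
        # c = sigma(1) * tanh(1), h = sigma(1) * tanh(c)
        p = zero_params(d=1)
        x = 1.0
        for g in ("i", "f", "o", "c"):
            getattr(p, f"W_{g}x")[...] = 1.0
        h, c = lstm_step(x, np.zeros(1), np.zeros(1), p)
        c_expect = sigmoid(1.0) * np.tanh(1.0)
        assert c[0] == pytest.approx(c_expect, abs=1e-12)
        assert c[0] == pytest.approx(0.5568, abs=1e-4)
        assert h[0] == pytest.approx(sigmoid(1.0) * np.tanh(c_expect), abs=1e-12)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        p = init_params(d=5, seed=1)
        h, c = lstm_step(3.0, rng.normal(size=5), rng.normal(size=5), p)
        # h = o * tanh(c) with o in (0,1): |h| < |tanh(c)| <= 1
        assert np.all(np.abs(h) < 1.0)

    def test_dimension_mismatch_rejected(self):
        p = init_params(d=3, seed=0)
        with pytest.raises(ValueError):
            lstm_step(0.0, np.zeros(2), np.zeros(3), p)


class TestLstmUnroll:
    def test_single_step_window(self):
        p = init_params(d=3, seed=2)
        H, H_l = lstm_unroll([0.4], p)
        h, _ = lstm_step(0.4, np.zeros(3), np.zeros(3), p)
        np.testing.assert_allclose(H[0], h, atol=1e-15)
        np.testing.assert_allclose(H_l, h, atol=1e-15)

    def test_zero_parameter_model_gives_all_zero_states(self):
        p = zero_params(d=3)
        H, _ = lstm_unroll(np.linspace(-1, 1, 10), p)
        np.testing.assert_array_equal(H, np.zeros((10, 3)))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            lstm_unroll([], init_params(d=2, seed=0))


class TestBatchedEquivalence:
    def test_vectorized_forward_matches_step_loop_oracle(self):
        # the per-step reference path is entirely independent of the
        # batched/jitted implementation
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = int(rng.integers(1, 5))
            L = int(rng.integers(1, 11))
            head = "linear" if seed % 3 == 0 else "attention_ae"
            p = init_params(d=d, d_latent=max(1, d - 1), seed=seed, head=head)
            X = rng.normal(size=(3, L))
            y_batch, _ = forward_batch(X, p)
            y_loop = np.array([predict(x, p) for x in X])
            np.testing.assert_allclose(y_batch, y_loop, atol=1e-10)


class TestAttention:
    def test_identical_rows_give_uniform_weights(self):
        row = np.array([0.3, -0.2, 0.5])
        H = np.tile(row, (4, 1))
        A, s = attention(H, row)
        np.testing.assert_allclose(A, np.full(4, 0.25), atol=1e-12)
        np.testing.assert_allclose(s, row, atol=1e-12)

    def test_single_step_degenerate_softmax(self):
        H = np.array([[1.0, 2.0]])
        A, s = attention(H, H[0])
        np.testing.assert_array_equal(A, [1.0])
        np.testing.assert_array_equal(s, H[0])

    def test_orthogonal_rows_closed_form(self):
        # rows orthogonal; row j equals H_l with norm g -> score_j = g^2,
        # other scores 0; A_j = e^{g^2} / (e^{g^2} + L - 1)
        g = 1.5
        H = np.diag([g, 1.0, 2.0])  # rows orthogonal
        H_l = H[0]
        A, s = attention(H, H_l)
        expect = np.exp(g * g) / (np.exp(g * g) + 2)
        assert A[0] == pytest.approx(expect, abs=1e-12)
        np.testing.assert_allclose(A[1:], (1 - expect) / 2, atol=1e-12)

    def test_weights_form_probability_vector(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            H = rng.normal(size=(6, 4)) * 3
            A, s = attention(H, H[-1])
            assert np.all(A >= 0)
            assert A.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(s, A @ H, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention(np.zeros((3, 4)), np.zeros(5))


class TestAutoencodeHead:
    def test_zero_weights_constant_decoder_bias(self):
        p = zero_params(d=3, d_latent=2)
        p.b_dec[...] = 0.3
        assert autoencode_head(np.array([5.0, -2.0, 1.0]), p) == pytest.approx(0.3)

    def test_hand_computed_latent_and_output(self):
        p = zero_params(d=3, d_latent=1)
        p.W_enc[0, 0] = 1.0
        p.b_enc[0] = -0.5
        p.W_dec[0] = 2.0
        out = autoencode_head(np.array([0.75, 9.0, -9.0]), p)
        assert out == pytest.approx(0.5)  # latent = ReLU(0.75 - 0.5) = 0.25

    def test_latent_non_negative(self):
        rng = np.random.default_rng(4)
        p = init_params(d=6, d_latent=3, seed=5)
        for _ in range(10):
            s = rng.normal(size=6) * 5
            z = p.W_enc @ s + p.b_enc
            assert np.all(np.maximum(z, 0.0) >= 0)


class TestPredict:
    def test_deterministic(self):
        p = init_params(d=4, d_latent=2, seed=6)
        w = np.linspace(-1, 1, 8)
        assert predict(w, p) == predict(w, p)

    def test_zero_lstm_params_output_independent_of_window(self):
        p = zero_params(d=3, d_latent=2)
        p.b_dec[...] = 0.7
        rng = np.random.default_rng(7)
        outs = [predict(rng.normal(size=5), p) for _ in range(5)]
        np.testing.assert_allclose(outs, 0.7, atol=1e-12)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """BPTT gradients of the batch-L2 loss vs central differences.

        Comparison is per parameter group by relative error of the gradient
        vectors (finite differences are unreliable elementwise on
        near-zero components).
        """
        for head in ("attention_ae", "linear"):
            p = init_params(d=3, d_latent=2, seed=0, head=head)
            rng = np.random.default_rng(1)
            X = rng.normal(size=(4, 5))
            y = rng.normal(size=4)
            y_pred, cache = forward_batch(X, p, want_cache=True)
            e = y_pred - y
            norm = np.linalg.norm(e)
            grads = backward_batch(e / norm, cache, p)
            eps = 1e-6
            for k, arr in p.as_dict().items():
                num = np.empty_like(arr)
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp = np.linalg.norm(forward_batch(X, p)[0] - y)
                    arr[idx] = orig - eps
                    lm = np.linalg.norm(forward_batch(X, p)[0] - y)
                    arr[idx] = orig
                    num[idx] = (lp - lm) / (2 * eps)
                denom = max(np.linalg.norm(num), np.linalg.norm(grads[k]), 1e-12)
                rel = np.linalg.norm(num - grads[k]) / denom
                assert rel < 1e-4, f"{head}/{k}: rel {rel:.2e}"
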