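"""Forward-pass correctness of the composite network.

The scalar-dimension oracles below re-derive the cell, attention and
decoder recursions by hand with plain numpy scalars, independently of the
package's tape implementation, and require agreement to 1e-10.
"""

import numpy as np
import pytest

from trackseq import (
    ModelConfig,
    ModelParams,
    TrajectoryAutoencoder,
    attend,
    decode,
    encode,
    forward,
    loss,
    lstm_cell_step,
)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def set_cell(params, prefix, W, b):
    """Assign identical scalar weights W=(wf,wi,wo,wc) applied to [h, x]."""
    wf, wi, wo, wc = W
    bf, bi, bo, bc = b
    t = params.tensors
    for g, w, bias in zip(("Wf", "Wi", "Wo", "Wc"), (wf, wi, wo, wc), (bf, bi, bo, bc)):
        t[f"{prefix}_{g}"].data = np.asarray(w, dtype=float)
        t[f"{prefix}_{'b' + g[1].lower()}"].data = np.atleast_1d(np.asarray(bias, dtype=float))


def hand_cell(x, h, c, W, b):
    """Hand evaluation of the six cell equations, scalar M=1, width 1."""
    wf, wi, wo, wc = W
    bf, bi, bo, bc = b
    z = np.array([h, x])
    f = sigmoid(z @ np.asarray(wf).reshape(2, 1) + bf)[0]
    i = sigmoid(z @ np.asarray(wi).reshape(2, 1) + bi)[0]
    o = sigmoid(z @ np.asarray(wo).reshape(2, 1) + bo)[0]
    ct = np.tanh(z @ np.asarray(wc).reshape(2, 1) + bc)[0]
    c_new = f * c + i * ct
    h_new = o * np.tanh(c_new)
    return f, i, o, ct, c_new, h_new


SCALAR_W = ([[0.3], [-0.5]], [[0.8], [0.1]], [[-0.2], [0.7]], [[0.4], [0.9]])
SCALAR_B = (0.1, -0.3, 0.2, 0.05)


class TestCellStep:
    def test_zero_parameters_closed_form(self):
        cfg = ModelConfig(t_in=3, t_out=1, n_features=3, hidden_size=4)
        p = ModelParams.zeros(cfg)
        s = lstm_cell_step(np.zeros(3), np.zeros(4), np.zeros(4), p)
        assert np.allclose(s.f, 0.5) and np.allclose(s.i, 0.5) and np.allclose(s.o, 0.5)
        assert np.allclose(s.c_tilde, 0.0) and np.allclose(s.c, 0.0) and np.allclose(s.h, 0.0)

    def test_saturated_gates_preserve_memory(self):
        cfg = ModelConfig(t_in=3, t_out=1, n_features=2, hidden_size=3)
        p = ModelParams.zeros(cfg)
        p.tensors["enc0_bf"].data = np.full(3, 20.0)  # f -> 1
        p.tensors["enc0_bi"].data = np.full(3, -20.0)  # i -> 0
        c_prev = np.array([0.7, -0.4, 1.3])
        s = lstm_cell_step(np.ones(2), np.zeros(3), c_prev, p)
        assert np.allclose(s.c, c_prev, atol=1e-8)

    def test_scalar_hand_oracle(self):
        cfg = ModelConfig(t_in=2, t_out=1, n_features=1, hidden_size=1)
        p = ModelParams.zeros(cfg)
        set_cell(p, "enc0", SCALAR_W, SCALAR_B)
        x, h, c = 0.6, -0.2, 0.4
        s = lstm_cell_step([x], [h], [c], p)
        f, i, o, ct, c_new, h_new = hand_cell(x, h, c, SCALAR_W, SCALAR_B)
        for got, want in [(s.f, f), (s.i, i), (s.o, o), (s.c_tilde, ct), (s.c, c_new), (s.h, h_new)]:
            assert got[0] == pytest.approx(want, abs=1e-10)

    def test_nonfinite_input_rejected(self):
        cfg = ModelConfig(t_in=2, t_out=1, n_features=1, hidden_size=1)
        p = ModelParams.zeros(cfg)
        with pytest.raises(ValueError):
            lstm_cell_step([np.nan], [0.0], [0.0], p)


class TestEncoder:
    def test_zero_parameters_all_zero(self):
        cfg = ModelConfig(t_in=4, t_out=1, n_features=3, hidden_size=5, n_layers=2)
        st = encode(np.random.default_rng(0).normal(size=(4, 3)), ModelParams.zeros(cfg))
        assert all(np.allclose(layer, 0.0) for layer in st.hen)
        assert np.allclose(st.hl, 0.0)

    def test_scalar_unrolled_two_steps(self):
        cfg = ModelConfig(t_in=2, t_out=1, n_features=1, hidden_size=1)
        p = ModelParams.zeros(cfg)
        set_cell(p, "enc0", SCALAR_W, SCALAR_B)
        x = np.array([[0.5], [-0.8]])
        st = encode(x, p)
        h = c = 0.0
        expected = []
        for xt in x[:, 0]:
            *_, c, h = hand_cell(xt, h, c, SCALAR_W, SCALAR_B)
            expected.append(h)
        assert np.allclose(st.hen[0][:, 0], expected, atol=1e-10)
        assert st.hl[0] == pytest.approx(expected[-1], abs=1e-10)

    @pytest.mark.parametrize("T,F,M,K", [(3, 3, 4, 1), (5, 2, 3, 2), (2, 4, 6, 3)])
    def test_shapes_contract(self, T, F, M, K, rng):
        cfg = ModelConfig(t_in=T, t_out=1, n_features=F, hidden_size=M, n_layers=K)
        st = encode(rng.normal(size=(T, F)), ModelParams(cfg, seed=3))
        assert len(st.hen) == K
        assert all(layer.shape == (T, M) for layer in st.hen)
        assert np.array_equal(st.hl, st.hen[-1][-1])


class TestAttention:
    def _params(self, M=2, seed=5):
        cfg = ModelConfig(t_in=3, t_out=1, n_features=3, hidden_size=M)
        return ModelParams(cfg, seed=seed)

    def test_singleton_softmax(self, rng):
        p = self._params()
        res = attend(rng.normal(size=(1, 2)), rng.normal(size=2), p)
        assert res.aw == pytest.approx([1.0])
        assert np.allclose(res.av, res.h_bar[0])

    def test_identical_rows_uniform_weights(self, rng):
        p = self._params()
        row = rng.normal(size=2)
        res = attend(np.tile(row, (4, 1)), rng.normal(size=2), p)
        assert np.allclose(res.aw, 0.25, atol=1e-12)

    def test_hand_softmax_oracle(self):
        # identity transform so h_bar == hen, then softmax of 3 dot products
        p = self._params(M=2)
        p.tensors["att_Wh"].data = np.eye(2)
        p.tensors["att_bh"].data = np.zeros(2)
        hen = np.array([[1.0, 0.0], [0.0, 2.0], [-1.0, 1.0]])
        hl = np.array([0.5, -0.3])
        res = attend(hen, hl, p)
        scores = hen @ hl
        e = np.exp(scores - scores.max())
        aw = e / e.sum()
        assert np.allclose(res.aw, aw, atol=1e-10)
        assert np.allclose(res.av, aw @ hen, atol=1e-10)
        # ha is the affine map of [av, hl]
        expected_ha = np.concatenate([aw @ hen, hl]) @ p.tensors["att_Wo"].data + p.tensors["att_bo"].data
        assert np.allclose(res.ha, expected_ha, atol=1e-10)

    def test_weights_on_simplex_av_in_hull(self, rng):
        for seed in range(5):
            p = self._params(M=3, seed=seed)
            hen = rng.normal(size=(6, 3))
            res = attend(hen, rng.normal(size=3), p)
            assert np.all(res.aw >= 0)
            assert res.aw.sum() == pytest.approx(1.0, abs=1e-9)
            # av is the aw-weighted combination of h_bar rows
            assert np.allclose(res.av, res.aw @ res.h_bar, atol=1e-12)


class TestDecoder:
    def test_zero_parameters_zero_states(self):
        cfg = ModelConfig(t_in=3, t_out=2, n_features=3, hidden_size=4)
        states = decode(np.ones(8), 5, ModelParams.zeros(cfg), which=1)
        assert states.shape == (5, 4)
        assert np.allclose(states, 0.0)

    def test_single_step_equals_cell_step(self, rng):
        cfg = ModelConfig(t_in=3, t_out=1, n_features=3, hidden_size=3)
        p = ModelParams(cfg, seed=9)
        ha = rng.normal(size=6)
        states = decode(ha, 1, p, which=2)
        s = lstm_cell_step(ha, np.zeros(3), np.zeros(3), p, prefix="dec2_0")
        assert np.allclose(states[0], s.h, atol=1e-12)

    def test_scalar_unrolled_recursion(self):
        cfg = ModelConfig(t_in=2, t_out=2, n_features=1, hidden_size=1)
        p = ModelParams.zeros(cfg)
        # decoder layer-1 input width is 2M = 2: weights rows [h, ha0, ha1]
        W = ([[0.2], [-0.4], [0.6]], [[0.5], [0.3], [-0.1]], [[0.7], [0.2], [0.4]], [[-0.3], [0.8], [0.1]])
        b = (0.05, -0.15, 0.25, 0.0)
        set_cell(p, "dec1_0", W, b)
        ha = np.array([0.4, -0.9])
        states = decode(ha, 2, p, which=1)

        def hand_wide(z, W_, b_):
            return (
                sigmoid(z @ np.asarray(W_[0]) + b_[0])[0],
                sigmoid(z @ np.asarray(W_[1]) + b_[1])[0],
                sigmoid(z @ np.asarray(W_[2]) + b_[2])[0],
                np.tanh(z @ np.asarray(W_[3]) + b_[3])[0],
            )

        h = c = 0.0
        expected = []
        for _ in range(2):  # ha repeated at every step
            z = np.array([h, ha[0], ha[1]])
            f, i, o, ct = hand_wide(z, W, b)
            c = f * c + i * ct
            h = o * np.tanh(c)
            expected.append(h)
        assert np.allclose(states[:, 0], expected, atol=1e-10)

    def test_invalid_steps_rejected(self):
        cfg = ModelConfig(t_in=2, t_out=1, n_features=1, hidden_size=1)
        with pytest.raises(ValueError):
            decode(np.zeros(2), 0, ModelParams.zeros(cfg))


class TestForward:
    def test_zero_parameters_zero_outputs(self):
        cfg = ModelConfig(t_in=4, t_out=2, n_features=3, hidden_size=3)
        out = forward(np.random.default_rng(2).normal(size=(4, 3)), 2, ModelParams.zeros(cfg))
        assert np.allclose(out.x_hat, 0.0) and np.allclose(out.y_hat, 0.0)

    @pytest.mark.parametrize("variant", ["ATDD", "DD"])
    def test_output_shapes(self, variant, rng):
        cfg = ModelConfig(t_in=7, t_out=4, n_features=3, hidden_size=5, variant=variant)
        out = forward(rng.normal(size=(7, 3)), 4, ModelParams(cfg, seed=1), variant)
        assert out.x_hat.shape == (7, 3)
        assert out.y_hat.shape == (4, 2)
        assert out.hd1.shape == (7, 5) and out.hd2.shape == (4, 5)

    def test_determinism_bitwise(self, rng):
        cfg = ModelConfig(t_in=5, t_out=2, n_features=3, hidden_size=8)
        x = rng.normal(size=(5, 3))
        a = forward(x, 2, ModelParams(cfg, seed=42))
        b = forward(x, 2, ModelParams(cfg, seed=42))
        assert np.array_equal(a.x_hat, b.x_hat) and np.array_equal(a.y_hat, b.y_hat)

    def test_end_to_end_scalar_oracle(self):
        """T=2, F=1, M=1, K=1: full hand-unrolled composition of the cell,
        attention and decoder recursions reproduces forward() to 1e-10."""
        cfg = ModelConfig(t_in=2, t_out=1, n_features=1, hidden_size=1, variant="ATDD")
        p = ModelParams.zeros(cfg)
        set_cell(p, "enc0", SCALAR_W, SCALAR_B)
        p.tensors["att_Wh"].data = np.array([[0.9]])
        p.tensors["att_bh"].data = np.array([0.2])
        p.tensors["att_Wo"].data = np.array([[0.5, -0.3], [0.1, 0.8]])
        p.tensors["att_bo"].data = np.array([0.05, -0.05])
        decW = ([[0.2], [-0.4], [0.6]], [[0.5], [0.3], [-0.1]], [[0.7], [0.2], [0.4]], [[-0.3], [0.8], [0.1]])
        decB = (0.05, -0.15, 0.25, 0.0)
        set_cell(p, "dec1_0", decW, decB)
        dec2W = ([[0.1], [0.5], [-0.2]], [[-0.6], [0.4], [0.3]], [[0.2], [-0.7], [0.5]], [[0.9], [0.1], [-0.4]])
        dec2B = (-0.1, 0.2, 0.0, 0.3)
        set_cell(p, "dec2_0", dec2W, dec2B)
        p.tensors["head1_W"].data = np.array([[1.4]])
        p.tensors["head1_b"].data = np.array([-0.2])
        p.tensors["head2_W"].data = np.array([[0.6], [-0.8]]).T.reshape(1, 2)
        p.tensors["head2_b"].data = np.array([0.1, 0.3])

        x = np.array([[0.7], [-0.5]])
        out = forward(x, 1, p, "ATDD")

        # --- hand computation ---
        h = c = 0.0
        hs = []
        for xt in x[:, 0]:
            *_, c, h = hand_cell(xt, h, c, SCALAR_W, SCALAR_B)
            hs.append(h)
        hl = hs[-1]
        h_bar = np.array(hs) * 0.9 + 0.2
        scores = h_bar * hl
        e = np.exp(scores - scores.max())
        aw = e / e.sum()
        av = float(aw @ h_bar)
        ha = np.array([av, hl]) @ np.array([[0.5, -0.3], [0.1, 0.8]]) + np.array([0.05, -0.05])

        def run_dec(W_, b_, steps):
            h = c = 0.0
            out_states = []
            for _ in range(steps):
                z = np.array([h, ha[0], ha[1]])
                f = sigmoid(z @ np.asarray(W_[0]) + b_[0])[0]
                i = sigmoid(z @ np.asarray(W_[1]) + b_[1])[0]
                o = sigmoid(z @ np.asarray(W_[2]) + b_[2])[0]
                ct = np.tanh(z @ np.asarray(W_[3]) + b_[3])[0]
                c = f * c + i * ct
                h = o * np.tanh(c)
                out_states.append(h)
            return np.array(out_states)

        hd1 = run_dec(decW, decB, 2)
        hd2 = run_dec(dec2W, dec2B, 1)
        x_hat = hd1[:, None] * 1.4 - 0.2
        y_hat = hd2[:, None] * np.array([[0.6, -0.8]]) + np.array([0.1, 0.3])
        assert np.allclose(out.x_hat, x_hat, atol=1e-10)
        assert np.allclose(out.y_hat, y_hat, atol=1e-10)

    def test_dd_bypasses_attention(self, rng):
        # with zeroed attention weights ATDD and DD still differ unless the
        # DD context [hl, hl] is what reaches the decoders
        cfg = ModelConfig(t_in=3, t_out=1, n_features=2, hidden_size=2, variant="DD")
        p = ModelParams(cfg, seed=8)
        x = rng.normal(size=(3, 2))
        out_dd = forward(x, 1, p, "DD")
        st = encode(x, p)
        ha = np.concatenate([st.hl, st.hl])
        manual = decode(ha, 1, p, which=2)
        y_manual = manual @ p.tensors["head2_W"].data + p.tensors["head2_b"].data
        assert np.allclose(out_dd.y_hat, y_manual, atol=1e-12)


class TestLoss:
    def test_perfect_fit_zero(self, rng):
        x = rng.normal(size=(7, 3))
        y = rng.normal(size=(1, 2))
        assert loss(x, x, y, y) == 0.0

    def test_direct_sum_of_squares(self):
        x = np.zeros((7, 3))
        y = np.zeros((1, 2))
        assert loss(x, x + 1.0, y, y + 2.0) == pytest.approx(21.0 + 8.0)

    def test_matches_brute_force_accumulation(self, rng):
        x, x_hat = rng.normal(size=(5, 7, 3)), rng.normal(size=(5, 7, 3))
        y, y_hat = rng.normal(size=(5, 4, 2)), rng.normal(size=(5, 4, 2))
        acc = 0.0
        for j in range(5):
            for t in range(7):
                for f in range(3):
                    acc += (x[j, t, f] - x_hat[j, t, f]) ** 2
            for t in range(4):
                for f in range(2):
                    acc += (y[j, t, f] - y_hat[j, t, f]) ** 2
        assert loss(x, x_hat, y, y_hat) == pytest.approx(acc, abs=1e-12)
        assert loss(x, x_hat, y, y_hat, reduction="mean") == pytest.approx(acc / (5 * 21 + 5 * 8), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.zeros((3, 3)), np.zeros((4, 3)), np.zeros((1, 2)), np.zeros((1, 2)))


class TestEstimator:
    def test_seeded_init_reproducible(self):
        a = TrajectoryAutoencoder(7, 1, seed=3)
        b = TrajectoryAutoencoder(7, 1, seed=3)
        for k in a.params.tensors:
            assert np.array_equal(a.params.tensors[k].data, b.params.tensors[k].data)

    def test_checkpoint_round_trip(self, tmp_path, small_pairs):
        m = TrajectoryAutoencoder(7, 1, hidden_size=6, seed=0)
        m.fit(small_pairs[:64], epochs=2)
        path = tmp_path / "ck.npz"
        m.save(path)
        m2 = TrajectoryAutoencoder.load(path)
        assert np.allclose(m.predict(small_pairs[:10]), m2.predict(small_pairs[:10]), atol=0)

    def test_parameter_count_reproducible(self):
        cfg = ModelConfig(t_in=7, t_out=1, n_features=3, hidden_size=4, n_layers=2)
        n1 = ModelParams(cfg, seed=0).n_parameters()
        n2 = ModelParams(cfg, seed=99).n_parameters()
        assert n1 == n2 > 0
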