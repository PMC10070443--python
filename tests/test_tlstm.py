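import math

import numpy as np
import pytest

from myoprog.tlstm import (
    LSTMParams,
    PredictorParams,
    TLSTMParams,
    decay,
    forward,
    gradients,
    init_predictor,
    load_predictor,
    lstm_step,
    save_predictor,
    tlstm_step,
)


def zero_params(hidden, input_dim, cell_type="lstm"):
    z = lambda *shape: np.zeros(shape)
    kwargs = {}
    for g in "fico":
        kwargs[f"W_{g}"] = z(hidden, input_dim)
        kwargs[f"U_{g}"] = z(hidden, hidden)
        kwargs[f"b_{g}"] = z(hidden)
    if cell_type == "tlstm":
        return TLSTMParams(**kwargs, W_d=z(hidden, hidden), b_d=z(hidden))
    return LSTMParams(**kwargs)


def scalar_lstm_step(params, x, h_prev, C_prev):
    """Element-by-element oracle of the gate equations (pure Python loops)."""
    H, D = params.hidden_size, params.input_dim
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    out_h, out_C = [], []
    for j in range(H):
        zf = params.b_f[j] + sum(params.W_f[j, k] * x[k] for k in range(D)) \
            + sum(params.U_f[j, k] * h_prev[k] for k in range(H))
        zi = params.b_i[j] + sum(params.W_i[j, k] * x[k] for k in range(D)) \
            + sum(params.U_i[j, k] * h_prev[k] for k in range(H))
        zc = params.b_c[j] + sum(params.W_c[j, k] * x[k] for k in range(D)) \
            + sum(params.U_c[j, k] * h_prev[k] for k in range(H))
        zo = params.b_o[j] + sum(params.W_o[j, k] * x[k] for k in range(D)) \
            + sum(params.U_o[j, k] * h_prev[k] for k in range(H))
        C_j = sig(zf) * C_prev[j] + sig(zi) * math.tanh(zc)
        out_C.append(C_j)
        out_h.append(sig(zo) * math.tanh(C_j))
    return np.array(out_h), np.array(out_C)


def scalar_tlstm_step(params, x, delta, h_prev, C_prev):
    """Scalar oracle: subspace decomposition + decay, then gate equations."""
    H = params.hidden_size
    g = 1.0 / math.log(math.e + delta)
    CS = np.array([
        math.tanh(params.b_d[j]
                  + sum(params.W_d[j, k] * C_prev[k] for k in range(H)))
        for j in range(H)
    ])
    C_star = (C_prev - CS) + g * CS
    return scalar_lstm_step(params, x, h_prev, C_star)


class TestDecay:
    def test_log_anchor_points(self):
        assert decay(0.0) == pytest.approx(1.0)
        # solve 1/log(e + d) = 0.5  =>  d = e^2 - e
        assert decay(math.e ** 2 - math.e) == pytest.approx(0.5)

    def test_monotone_non_increasing(self):
        grid = np.linspace(0, 50, 500)
        g = decay(grid)
        assert np.all(np.diff(g) <= 0)
        assert np.all((g > 0) & (g <= 1))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            decay(-0.1)

    def test_alternative_registry(self):
        assert decay(4.0, kind="inverse") == pytest.approx(0.25)
        assert decay(7.0, kind="none") == 1.0


class TestCellSteps:
    def test_zero_params_zero_state(self):
        p = zero_params(3, 16)
        out = lstm_step(p, np.zeros(16), np.zeros(3), np.zeros(3))
        assert np.allclose(out["h"], 0.0)
        assert np.allclose(out["C"], 0.0)

    def test_zero_params_nonzero_memory(self):
        # gates all sigmoid(0)=0.5 and C~=0: C_t = 0.5 c, h = 0.5 tanh(0.5 c)
        p = zero_params(3, 16)
        c = np.array([1.0, -2.0, 0.5])
        out = lstm_step(p, np.ones(16), np.zeros(3), c)
        assert np.allclose(out["C"], 0.5 * c)
        assert np.allclose(out["h"], 0.5 * np.tanh(0.5 * c))

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        pred = init_predictor(16, 3, cell_type="tlstm", seed=5)
        p = pred.cell
        x = rng.normal(size=16)
        h0 = rng.normal(size=3) * 0.5
        C0 = rng.normal(size=3)
        out = lstm_step(p, x, h0, C0)
        oh, oC = scalar_lstm_step(p, x, h0, C0)
        assert np.allclose(out["h"][0], oh, atol=1e-10)
        assert np.allclose(out["C"][0], oC, atol=1e-10)
        for delta in (0.0, 1.0, 7.0):
            out = tlstm_step(p, x, delta, h0, C0)
            oh, oC = scalar_tlstm_step(p, x, delta, h0, C0)
            assert np.allclose(out["h"][0], oh, atol=1e-10)
            assert np.allclose(out["C"][0], oC, atol=1e-10)

    def test_decay_one_reduces_to_lstm(self):
        """With g == 1 the decomposition cancels: (C - C^S) + 1 * C^S = C."""
        pred = init_predictor(16, 4, cell_type="tlstm", decay_kind="none",
                              seed=2)
        p = pred.cell
        rng = np.random.default_rng(0)
        x = rng.normal(size=16)
        h0, C0 = rng.normal(size=4), rng.normal(size=4)
        t_out = tlstm_step(p, x, 9.0, h0, C0)
        l_out = lstm_step(p, x, h0, C0)
        assert np.allclose(t_out["h"], l_out["h"], atol=1e-12)
        assert np.allclose(t_out["C"], l_out["C"], atol=1e-12)

    def test_large_delta_limit(self):
        """As g -> 0 the adjusted memory tends to C - C^S (long-term only)."""
        pred = init_predictor(16, 4, cell_type="tlstm", decay_kind="inverse",
                              seed=2)
        p = pred.cell
        rng = np.random.default_rng(1)
        x, h0, C0 = rng.normal(size=16), rng.normal(size=4), rng.normal(size=4)
        out = tlstm_step(p, x, 1e12, h0, C0)
        CS = np.tanh(C0 @ p.W_d.T + p.b_d)
        assert np.allclose(out["C_star"][0], C0 - CS, atol=1e-4)

    def test_gate_boundedness(self):
        rng = np.random.default_rng(8)
        pred = init_predictor(16, 8, seed=8)
        for _ in range(20):
            x = rng.normal(size=(6, 16)) * 3
            h = rng.normal(size=(6, 8))
            C = rng.normal(size=(6, 8)) * 2
            out = tlstm_step(pred.cell, x, 4.0, h, C)
            for gate in ("f", "i", "o"):
                assert np.all((out[gate] > 0) & (out[gate] < 1))
            assert np.all(np.abs(out["ctil"]) < 1)
            assert np.all(np.abs(out["CS"]) < 1)

    def test_shape_mismatch_rejected(self):
        pred = init_predictor(16, 4, seed=0)
        with pytest.raises(ValueError):
            lstm_step(pred.cell, np.zeros(15), np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError):
            tlstm_step(pred.cell, np.zeros(16), 1.0, np.zeros(3), np.zeros(3))


class TestForward:
    def test_zero_weights_predicts_head_bias(self):
        cell = zero_params(4, 16, cell_type="tlstm")
        params = PredictorParams(cell, w_out=np.zeros(4),
                                 b_out=np.array([0.75]))
        X = np.random.default_rng(0).normal(size=(3, 2, 16))
        D = np.ones((3, 2))
        assert np.allclose(forward(params, X, D), 0.75)

    def test_single_record_single_step(self):
        """n = 1: one cell step; the only interval is the horizon."""
        params = init_predictor(16, 4, seed=3)
        x = np.random.default_rng(1).normal(size=(1, 16))
        val = forward(params, x, np.array([3.0]))
        assert np.isscalar(val) or np.asarray(val).shape == ()

    def test_horizon_sensitivity(self):
        """Changing only the final interval changes the prediction."""
        params = init_predictor(16, 8, seed=4)
        rng = np.random.default_rng(2)
        for T in (1, 3):
            X = rng.normal(size=(T, 16))
            d1 = np.ones(T); d1[-1] = 1.0
            d2 = np.ones(T); d2[-1] = 9.0
            assert forward(params, X, d1) != pytest.approx(
                forward(params, X, d2), abs=1e-9)

    def test_empty_input_rejected(self):
        params = init_predictor(16, 4, seed=0)
        with pytest.raises(ValueError):
            forward(params, np.zeros((1, 0, 16)), np.zeros((1, 0)))

    def test_g_one_reduction_full_sequence(self):
        """With decay disabled the time-aware runner and a plain LSTM with
        the same shared weights produce identical predictions."""
        t_params = init_predictor(16, 6, cell_type="tlstm",
                                  decay_kind="none", seed=9)
        l_cell = zero_params(6, 16)
        for name in l_cell.array_names():
            setattr(l_cell, name, getattr(t_params.cell, name).copy())
        l_params = PredictorParams(l_cell, t_params.w_out.copy(),
                                   t_params.b_out.copy())
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 3, 16))
        D = rng.integers(1, 10, size=(5, 3)).astype(float)
        assert np.allclose(forward(t_params, X, D), forward(l_params, X, D),
                           atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("cell_type,T", [("tlstm", 1), ("tlstm", 3),
                                             ("lstm", 2)])
    def test_finite_difference_agreement(self, cell_type, T):
        """Backprop matches central finite differences (hidden size 4)."""
        rng = np.random.default_rng(3)
        params = init_predictor(16, 4, cell_type=cell_type, seed=7)
        X = rng.normal(size=(5, T, 16))
        D = rng.integers(1, 10, size=(5, T)).astype(float)
        y = rng.normal(size=5)
        loss, grads = gradients(params, X, D, y)
        arrays = dict(params.array_items())
        for name, arr in arrays.items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                eps = 1e-5
                arr[idx] = orig + eps
                lp = np.mean((forward(params, X, D) - y) ** 2)
                arr[idx] = orig - eps
                lm = np.mean((forward(params, X, D) - y) ** 2)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name][idx]
                denom = max(abs(fd), abs(an), 1e-6)
                assert abs(fd - an) / denom < 1e-4, (name, idx, fd, an)

    def test_zero_error_batch_zero_head_gradient(self):
        params = init_predictor(16, 4, seed=1)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 2, 16))
        D = np.ones((4, 2))
        y = forward(params, X, D)   # labels equal predictions
        loss, grads = gradients(params, X, D, y)
        assert loss == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(grads["w_out"], 0.0)
        assert np.allclose(grads["b_out"], 0.0)

    def test_duplicated_batch_mean_invariance(self):
        params = init_predictor(16, 4, seed=2)
        rng = np.random.default_rng(5)
        X = rng.normal(size=(3, 2, 16))
        D = rng.integers(1, 10, size=(3, 2)).astype(float)
        y = rng.normal(size=3)
        loss1, g1 = gradients(params, X, D, y)
        loss2, g2 = gradients(params, np.concatenate([X, X]),
                              np.concatenate([D, D]), np.concatenate([y, y]))
        assert loss1 == pytest.approx(loss2)
        for k in g1:
            assert np.allclose(g1[k], g2[k], atol=1e-12)


def test_checkpoint_roundtrip(tmp_path):
    params = init_predictor(16, 5, seed=6)
    path = tmp_path / "model.json"
    save_predictor(params, path)
    back = load_predictor(path)
    rng = np.random.default_rng(6)
    X = rng.normal(size=(4, 2, 16))
    D = rng.integers(1, 10, size=(4, 2)).astype(float)
    assert np.array_equal(forward(params, X, D), forward(back, X, D))
    assert back.cell.decay_kind == "log"
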