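"""Time-aware LSTM: cells, decay, sequence runner, head, and gradients.

The standard LSTM cell gates information flow through forget/input/output
gates but implicitly assumes evenly spaced observations. The time-aware
variant (T-LSTM) decomposes the previous cell memory into a short-term
subspace C^S = tanh(W_d C + b_d) and its complement C^T = C - C^S, discounts
only the short-term part by a decay g(dt) of the elapsed time, and
recombines C* = C^T + g(dt) * C^S before running the ordinary gate
equations. With g == 1 the decomposition cancels algebraically and the cell
reduces exactly to a standard LSTM.

Everything here is plain NumPy with hand-derived backpropagation through
time; gradients are validated against central finite differences in the
test suite. Batches are (B, T, D) arrays of equal-length sequences with a
(B, T) matrix of interval values; entry [b, t] is the gap between check t
and the NEXT element, so the last column holds the prediction horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Callable

import numpy as np


# ---------------------------------------------------------------------------
# decay functions

def _decay_log(delta: np.ndarray) -> np.ndarray:
    return 1.0 / np.log(np.e + delta)


def _decay_inverse(delta: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(delta, 1.0)


DECAY_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "log": _decay_log,
    "inverse": _decay_inverse,
    "none": lambda delta: np.ones_like(np.asarray(delta, float)),
}


def decay(delta, kind: str = "log"):
    """Elapsed-time discount g(dt) in (0, 1], non-increasing, g(0) = 1.

    The default ``log`` form is 1/log(e + dt). ``dt`` is the quarter-bin
    value (the data's native time unit); scalars and arrays are accepted.
    """
    arr = np.asarray(delta, dtype=float)
    if np.any(arr < 0):
        raise ValueError("elapsed time must be non-negative")
    out = DECAY_FUNCTIONS[kind](arr)
    return float(out) if np.isscalar(delta) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# parameters

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMParams:
    """Gate weights of a standard LSTM cell (hidden H, input D)."""

    W_f: np.ndarray; U_f: np.ndarray; b_f: np.ndarray
    W_i: np.ndarray; U_i: np.ndarray; b_i: np.ndarray
    W_c: np.ndarray; U_c: np.ndarray; b_c: np.ndarray
    W_o: np.ndarray; U_o: np.ndarray; b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[1]

    def array_names(self) -> list[str]:
        return [f.name for f in _dc_fields(self) if f.name not in ("decay_kind",)]


@dataclass
class TLSTMParams(LSTMParams):
    """LSTM weights plus the memory-decomposition map and decay choice."""

    W_d: np.ndarray = None
    b_d: np.ndarray = None
    decay_kind: str = "log"


@dataclass
class PredictorParams:
    """A recurrent cell plus an affine head mapping h_n -> SE (diopters)."""

    cell: LSTMParams
    w_out: np.ndarray   # (H,)
    b_out: np.ndarray   # (1,)

    def array_items(self) -> list[tuple[str, np.ndarray]]:
        items = [(n, getattr(self.cell, n)) for n in self.cell.array_names()]
        items += [("w_out", self.w_out), ("b_out", self.b_out)]
        return items

    def copy(self) -> "PredictorParams":
        cell_kwargs = {n: getattr(self.cell, n).copy()
                       for n in self.cell.array_names()}
        if isinstance(self.cell, TLSTMParams):
            cell = TLSTMParams(**cell_kwargs, decay_kind=self.cell.decay_kind)
        else:
            cell = LSTMParams(**cell_kwargs)
        return PredictorParams(cell, self.w_out.copy(), self.b_out.copy())


def init_cell(
    input_dim: int, hidden_size: int,
    cell_type: str = "tlstm", decay_kind: str = "log",
    rng: np.random.Generator | None = None,
) -> LSTMParams:
    """Fan-in-scaled uniform initialization of all cell weights."""
    rng = rng or np.random.default_rng(0)

    def u(rows, cols):
        bound = 1.0 / np.sqrt(cols)
        return rng.uniform(-bound, bound, size=(rows, cols))

    H, D = hidden_size, input_dim
    kwargs = {}
    for g in "fico":
        kwargs[f"W_{g}"] = u(H, D)
        kwargs[f"U_{g}"] = u(H, H)
        # forget gate biased open at init (standard LSTM practice: keeps
        # early gradients flowing through the memory path)
        kwargs[f"b_{g}"] = np.ones(H) if g == "f" else np.zeros(H)
    if cell_type == "tlstm":
        # b_d starts away from zero: with C_0 = 0 and b_d = 0 the decayed
        # subspace tanh(W_d C + b_d) vanishes at the first step, leaving the
        # elapsed-time signal of single-record histories with no influence
        # at initialization.
        return TLSTMParams(**kwargs, W_d=u(H, H), b_d=np.full(H, 0.5),
                           decay_kind=decay_kind)
    if cell_type == "lstm":
        return LSTMParams(**kwargs)
    raise ValueError(f"unknown cell type {cell_type!r}")


def init_predictor(
    input_dim: int, hidden_size: int,
    cell_type: str = "tlstm", decay_kind: str = "log", seed: int = 0,
) -> PredictorParams:
    rng = np.random.default_rng(seed)
    cell = init_cell(input_dim, hidden_size, cell_type, decay_kind, rng)
    bound = 1.0 / np.sqrt(hidden_size)
    return PredictorParams(
        cell=cell,
        w_out=rng.uniform(-bound, bound, size=hidden_size),
        b_out=np.zeros(1),
    )


# ---------------------------------------------------------------------------
# cell steps

def _check_shapes(params: LSTMParams, x: np.ndarray, h: np.ndarray,
                  C: np.ndarray) -> None:
    if x.shape[-1] != params.input_dim:
        raise ValueError(
            f"input dim {x.shape[-1]} != expected {params.input_dim}")
    if h.shape[-1] != params.hidden_size or C.shape[-1] != params.hidden_size:
        raise ValueError("state dim mismatch with hidden size")


def lstm_step(params: LSTMParams, x: np.ndarray, h: np.ndarray,
              C: np.ndarray) -> dict:
    """One standard LSTM step on a batch; returns state + intermediates.

    f = sig(W_f x + U_f h + b_f), i likewise, C~ = tanh(W_c x + U_c h + b_c),
    C_t = f*C + i*C~, o = sig(W_o x + U_o h + b_o), h_t = o*tanh(C_t).
    """
    x = np.atleast_2d(np.asarray(x, float))
    h = np.atleast_2d(np.asarray(h, float))
    C = np.atleast_2d(np.asarray(C, float))
    _check_shapes(params, x, h, C)
    f = _sigmoid(x @ params.W_f.T + h @ params.U_f.T + params.b_f)
    i = _sigmoid(x @ params.W_i.T + h @ params.U_i.T + params.b_i)
    ctil = np.tanh(x @ params.W_c.T + h @ params.U_c.T + params.b_c)
    o = _sigmoid(x @ params.W_o.T + h @ params.U_o.T + params.b_o)
    C_new = f * C + i * ctil
    tanh_C = np.tanh(C_new)
    h_new = o * tanh_C
    return {"h": h_new, "C": C_new, "f": f, "i": i, "o": o, "ctil": ctil,
            "tanh_C": tanh_C, "x": x, "h_prev": h, "C_prev": C,
            "C_star": C}


def tlstm_step(params: TLSTMParams, x: np.ndarray, delta, h: np.ndarray,
               C: np.ndarray) -> dict:
    """One time-aware step: decay the short-term memory subspace, then gate.

    C^S = tanh(W_d C + b_d); C* = (C - C^S) + g(dt) * C^S; then the
    ordinary LSTM equations run with C replaced by C*.
    """
    x = np.atleast_2d(np.asarray(x, float))
    h = np.atleast_2d(np.asarray(h, float))
    C = np.atleast_2d(np.asarray(C, float))
    _check_shapes(params, x, h, C)
    g = np.asarray(decay(delta, params.decay_kind), float).reshape(-1, 1)
    CS = np.tanh(C @ params.W_d.T + params.b_d)
    C_star = C + (g - 1.0) * CS
    out = lstm_step(params, x, h, C_star)
    out.update({"C_prev": C, "C_star": C_star, "CS": CS, "g": g})
    return out


def _run_sequence(params: PredictorParams, X: np.ndarray,
                  deltas: np.ndarray) -> tuple[np.ndarray, list[dict]]:
    """Run the cell over a batch; returns (yhat, per-step caches).

    Time-aware composition: ``deltas[:, t]`` is the gap between check t and
    the NEXT element of the sequence, so the memory holding checks 0..t is
    the memory that gap ages. Step t therefore gates x_t first and the
    aging by g(deltas[:, t]) is applied when that memory is next used: for
    t < T-1 inside the following cell step, and for the last step — whose
    gap is the prediction horizon — in a final projection of the cell
    state, from which the readout state is recomputed as o_T * tanh(C*).
    The head maps that horizon-projected state to SE.
    """
    B, T, _ = X.shape
    H = params.cell.hidden_size
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    caches = []
    time_aware = isinstance(params.cell, TLSTMParams)
    for t in range(T):
        if time_aware:
            # age the memory by the gap that just elapsed (none before x_0)
            delta_prev = deltas[:, t - 1] if t > 0 else np.zeros(B)
            cache = tlstm_step(params.cell, X[:, t, :], delta_prev, h, C)
        else:
            cache = lstm_step(params.cell, X[:, t, :], h, C)
        h, C = cache["h"], cache["C"]
        caches.append(cache)
    if time_aware:
        p = params.cell
        g = np.asarray(decay(deltas[:, T - 1], p.decay_kind)).reshape(-1, 1)
        CS = np.tanh(C @ p.W_d.T + p.b_d)
        C_proj = C + (g - 1.0) * CS
        tanh_proj = np.tanh(C_proj)
        h_out = caches[-1]["o"] * tanh_proj
        caches.append({"readout": True, "g": g, "CS": CS, "C_proj": C_proj,
                       "tanh_proj": tanh_proj, "C_in": C, "h_out": h_out})
        yhat = h_out @ params.w_out + params.b_out[0]
    else:
        yhat = h @ params.w_out + params.b_out[0]
    return yhat, caches


def forward(params: PredictorParams, X: np.ndarray,
            deltas: np.ndarray | None = None) -> np.ndarray:
    """Predict SE for a batch of equal-length histories.

    ``X`` is (B, T, D) encoded checks; ``deltas`` is (B, T) with the
    interval fed at step t being the gap to the NEXT element, the last
    column the prediction horizon. Returns (B,) predictions in diopters
    (head applied to the final hidden state). A single sample may be
    passed as (T, D) / (T,).
    """
    X = np.asarray(X, float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1] == 0:
        raise ValueError("empty input sequence")
    if deltas is None:
        deltas = np.zeros(X.shape[:2])
    deltas = np.asarray(deltas, float).reshape(X.shape[0], X.shape[1])
    yhat, _ = _run_sequence(params, X, deltas)
    return float(yhat[0]) if single else yhat


def gradients(params: PredictorParams, X: np.ndarray, deltas: np.ndarray,
              y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
    """Mean-squared-error loss and its gradient w.r.t. every parameter.

    Backpropagation through time over the batch; the loss is the MSE of
    the head output against ``y``, so gradients are averaged over the
    batch (duplicating the batch leaves them unchanged).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValueError("batch must be non-empty (B, T, D)")
    deltas = np.asarray(deltas, float).reshape(X.shape[0], X.shape[1])
    B, T, _ = X.shape
    yhat, caches = _run_sequence(params, X, deltas)
    resid = yhat - y
    loss = float(np.mean(resid ** 2))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")

    p = params.cell
    time_aware = isinstance(p, TLSTMParams)
    grads = {name: np.zeros_like(arr) for name, arr in params.array_items()}

    dyhat = 2.0 * resid / B                      # (B,)
    do_extra = None
    if time_aware:
        ro = caches.pop()                        # readout projection cache
        grads["w_out"] = ro["h_out"].T @ dyhat
        grads["b_out"] = np.array([dyhat.sum()])
        dh_out = np.outer(dyhat, params.w_out)
        o_last = caches[-1]["o"]
        do_extra = dh_out * ro["tanh_proj"]
        dC_proj = dh_out * o_last * (1.0 - ro["tanh_proj"] ** 2)
        dCS = dC_proj * (ro["g"] - 1.0)
        dz_d = dCS * (1.0 - ro["CS"] ** 2)
        grads["W_d"] += dz_d.T @ ro["C_in"]
        grads["b_d"] += dz_d.sum(axis=0)
        dh = np.zeros_like(dh_out)               # h_T itself feeds nothing
        dC = dC_proj + dz_d @ p.W_d
    else:
        h_final = caches[-1]["h"]
        grads["w_out"] = h_final.T @ dyhat
        grads["b_out"] = np.array([dyhat.sum()])
        dh = np.outer(dyhat, params.w_out)       # (B, H)
        dC = np.zeros_like(dh)

    for t in range(T - 1, -1, -1):
        c = caches[t]
        do = dh * c["tanh_C"]
        if do_extra is not None and t == T - 1:
            do = do + do_extra
        dC = dC + dh * c["o"] * (1.0 - c["tanh_C"] ** 2)
        df = dC * c["C_star"]
        dC_star = dC * c["f"]
        di = dC * c["ctil"]
        dctil = dC * c["i"]

        dz_f = df * c["f"] * (1.0 - c["f"])
        dz_i = di * c["i"] * (1.0 - c["i"])
        dz_c = dctil * (1.0 - c["ctil"] ** 2)
        dz_o = do * c["o"] * (1.0 - c["o"])

        x_t, h_prev = c["x"], c["h_prev"]
        for g, dz in (("f", dz_f), ("i", dz_i), ("c", dz_c), ("o", dz_o)):
            grads[f"W_{g}"] += dz.T @ x_t
            grads[f"U_{g}"] += dz.T @ h_prev
            grads[f"b_{g}"] += dz.sum(axis=0)
        dh = (dz_f @ p.U_f + dz_i @ p.U_i + dz_c @ p.U_c + dz_o @ p.U_o)

        if time_aware:
            dCS = dC_star * (c["g"] - 1.0)
            dz_d = dCS * (1.0 - c["CS"] ** 2)
            grads["W_d"] += dz_d.T @ c["C_prev"]
            grads["b_d"] += dz_d.sum(axis=0)
            dC = dC_star + dz_d @ p.W_d
        else:
            dC = dC_star
    return loss, grads


# ---------------------------------------------------------------------------
# checkpoint IO

def save_predictor(params: PredictorParams, path: str | Path) -> None:
    """Write a versioned JSON checkpoint (text, deterministic reload)."""
    cell_type = "tlstm" if isinstance(params.cell, TLSTMParams) else "lstm"
    payload = {
        "format": "myoprog-checkpoint-v1",
        "cell_type": cell_type,
        "decay_kind": getattr(params.cell, "decay_kind", None),
        "hidden_size": params.cell.hidden_size,
        "input_dim": params.cell.input_dim,
        "arrays": {name: arr.tolist() for name, arr in params.array_items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_predictor(path: str | Path) -> PredictorParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "myoprog-checkpoint-v1":
        raise ValueError("unrecognized checkpoint format")
    arrays = {k: np.asarray(v, float) for k, v in payload["arrays"].items()}
    w_out = arrays.pop("w_out")
    b_out = arrays.pop("b_out")
    if payload["cell_type"] == "tlstm":
        cell = TLSTMParams(**arrays, decay_kind=payload["decay_kind"])
    else:
        cell = LSTMParams(**arrays)
    return PredictorParams(cell=cell, w_out=w_out, b_out=b_out)
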