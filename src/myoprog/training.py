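"""Model fitting: MSE loss, Adam, length-grouped batching, early stopping.

Samples are grouped by input length (the split is already length-
stratified), so every batch is a dense (B, T, 16) array — no padding or
masking. Batches from different length groups are interleaved in a seeded
random order each epoch. Early stopping monitors validation MSE and
returns the best-validation checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from myoprog.preprocessing import TrainingSample
from myoprog.tlstm import PredictorParams, forward, gradients, init_predictor


def mse(y, yhat) -> float:
    """Mean squared error (the training loss)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    if y.size == 0:
        raise ValueError("empty batch")
    return float(np.mean((y - yhat) ** 2))


def mae(y, yhat) -> tuple[float, float]:
    """Mean and SD of the absolute errors |y - yhat| (reported in diopters)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    if y.size == 0:
        raise ValueError("empty batch")
    abs_err = np.abs(y - yhat)
    return float(abs_err.mean()), float(abs_err.std())


@dataclass
class TrainConfig:
    """Optimization settings (published defaults; tests use smaller nets)."""

    learning_rate: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 500
    early_stopping_patience: int = 10
    hidden_size: int = 1024
    cell_type: str = "tlstm"
    decay_kind: str = "log"
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.early_stopping_patience, self.hidden_size) <= 0:
            raise ValueError("all TrainConfig values must be positive")


def pack_by_length(
    samples: list[TrainingSample],
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group samples by input length into dense (X, deltas, y) arrays."""
    groups: dict[int, list[TrainingSample]] = {}
    for s in samples:
        groups.setdefault(s.n, []).append(s)
    packed = {}
    for n, group in sorted(groups.items()):
        X = np.stack([s.inputs for s in group])
        D = np.stack([s.intervals for s in group]).astype(float)
        y = np.array([s.label for s in group], float)
        packed[n] = (X, D, y)
    return packed


def predict_samples(params: PredictorParams,
                    samples: list[TrainingSample]) -> np.ndarray:
    """Predicted SE for arbitrary-length samples (batched per length)."""
    out = np.empty(len(samples))
    index: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        index.setdefault(s.n, []).append(i)
    for n, idxs in index.items():
        X = np.stack([samples[i].inputs for i in idxs])
        D = np.stack([samples[i].intervals for i in idxs]).astype(float)
        out[idxs] = forward(params, X, D)
    return out


class _Adam:
    def __init__(self, shapes: dict, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros(v) for k, v in shapes.items()}
        self.v = {k: np.zeros(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, arrays: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            arrays[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps)


def _eval_mse(params: PredictorParams, packed: dict) -> float:
    se_sum, count = 0.0, 0
    for X, D, y in packed.values():
        yhat = forward(params, X, D)
        se_sum += float(np.sum((y - yhat) ** 2))
        count += len(y)
    return se_sum / count


def train(
    train_samples: list[TrainingSample],
    val_samples: list[TrainingSample],
    config: TrainConfig,
    params: PredictorParams | None = None,
) -> tuple[PredictorParams, list[dict]]:
    """Fit the predictor by Adam on MSE with validation early stopping.

    Stops when validation loss has not improved for
    ``early_stopping_patience`` consecutive epochs, or at ``max_epochs``;
    returns the parameters of the best validation epoch plus a per-epoch
    history of train/validation loss. Deterministic given the seed.
    """
    config.validate()
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be non-empty")
    input_dim = train_samples[0].inputs.shape[1]
    if params is None:
        params = init_predictor(input_dim, config.hidden_size,
                                config.cell_type, config.decay_kind,
                                seed=config.seed)
    arrays = dict(params.array_items())
    opt = _Adam({k: v.shape for k, v in arrays.items()}, config.learning_rate)
    rng = np.random.default_rng(config.seed)

    packed_train = pack_by_length(train_samples)
    packed_val = pack_by_length(val_samples)

    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    history: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        batches = []
        for n, (X, D, y) in packed_train.items():
            order = rng.permutation(len(y))
            for lo in range(0, len(y), config.batch_size):
                idx = order[lo:lo + config.batch_size]
                batches.append((X[idx], D[idx], y[idx]))
        rng.shuffle(batches)
        epoch_loss, n_seen = 0.0, 0
        for Xb, Db, yb in batches:
            loss, grads = gradients(params, Xb, Db, yb)
            opt.step(arrays, grads)
            epoch_loss += loss * len(yb)
            n_seen += len(yb)
        val_loss = _eval_mse(params, packed_val)
        history.append({"epoch": epoch, "train_mse": epoch_loss / n_seen,
                        "val_mse": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = params.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stopping_patience:
            break
    return best_params, history
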