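"""Comparison models: standard LSTM, random forest, linear regression.

None of these treats elapsed time structurally, so the interval (with the
prediction horizon in the last position) is appended to each check as a
17th feature. The LSTM baseline consumes n x 17 sequences with the same
from-scratch cell and training loop as the time-aware model; random forest
and linear regression need fixed-length inputs, so one model is fitted per
sequence length on the flattened 17n-vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from myoprog.preprocessing import TrainingSample
from myoprog.training import TrainConfig, mae, predict_samples, train

N_AUGMENTED_FEATURES = 17


@dataclass
class FlatSample:
    """A training sample flattened to a fixed-length 17n feature vector."""

    features: np.ndarray   # (17 * n,)
    label: float
    n: int


def to_flat(sample: TrainingSample) -> FlatSample:
    """Append each check's interval as feature 17 and flatten row-major."""
    aug = np.concatenate(
        [sample.inputs, sample.intervals[:, None].astype(float)], axis=1)
    return FlatSample(features=aug.ravel(), label=sample.label, n=sample.n)


def unflatten(flat: FlatSample) -> tuple[np.ndarray, np.ndarray]:
    """Recover the (n, 16) inputs and (n,) intervals from a flat sample."""
    aug = flat.features.reshape(flat.n, N_AUGMENTED_FEATURES)
    return aug[:, :-1], aug[:, -1].astype(int)


def _with_interval_feature(sample: TrainingSample) -> TrainingSample:
    aug = np.concatenate(
        [sample.inputs, sample.intervals[:, None].astype(float)], axis=1)
    return TrainingSample(
        inputs=aug, intervals=sample.intervals.copy(), label=sample.label,
        subject_id=sample.subject_id, eye=sample.eye,
        label_myopia_level=sample.label_myopia_level,
        label_age=sample.label_age,
    )


class PerLengthModel:
    """One sklearn regressor per input length, on flattened features."""

    def __init__(self, models: dict[int, object]):
        self.models = models

    def predict(self, samples: list[TrainingSample]) -> np.ndarray:
        out = np.full(len(samples), np.nan)
        index: dict[int, list[int]] = {}
        for i, s in enumerate(samples):
            index.setdefault(s.n, []).append(i)
        for n, idxs in index.items():
            if n not in self.models:
                continue
            X = np.stack([to_flat(samples[i]).features for i in idxs])
            out[idxs] = self.models[n].predict(X)
        return out


class SequenceModel:
    """LSTM/T-LSTM predictor wrapper with a uniform predict() surface."""

    def __init__(self, params, use_interval_feature: bool):
        self.params = params
        self.use_interval_feature = use_interval_feature

    def predict(self, samples: list[TrainingSample]) -> np.ndarray:
        if self.use_interval_feature:
            samples = [_with_interval_feature(s) for s in samples]
        return predict_samples(self.params, samples)


def fit_baseline(
    kind: str,
    train_samples: list[TrainingSample],
    val_samples: list[TrainingSample],
    config: TrainConfig | None = None,
    rf_trees: int = 500,
):
    """Fit one of the comparison models ("lstm", "rf", "lr").

    The LSTM baseline mirrors the time-aware model's training protocol on
    17-dimensional inputs; RF (seeded, ``rf_trees`` trees) and LR
    (ordinary least squares) are fitted per input length. Lengths with no
    training data are skipped with a warning-level absence (the per-length
    model is simply missing).
    """
    if kind == "lstm":
        config = config or TrainConfig(hidden_size=32, max_epochs=50)
        aug_train = [_with_interval_feature(s) for s in train_samples]
        aug_val = [_with_interval_feature(s) for s in val_samples]
        cfg = TrainConfig(**{**config.__dict__, "cell_type": "lstm"})
        params, _history = train(aug_train, aug_val, cfg)
        return SequenceModel(params, use_interval_feature=True)
    if kind not in ("rf", "lr"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    seed = config.seed if config is not None else 0
    by_length: dict[int, list[TrainingSample]] = {}
    for s in train_samples:
        by_length.setdefault(s.n, []).append(s)
    models: dict[int, object] = {}
    for n, group in sorted(by_length.items()):
        X = np.stack([to_flat(s).features for s in group])
        y = np.array([s.label for s in group])
        if kind == "rf":
            model = RandomForestRegressor(
                n_estimators=rf_trees, random_state=seed, n_jobs=1)
        else:
            model = LinearRegression()
        model.fit(X, y)
        models[n] = model
    return PerLengthModel(models)


def compare_models(
    models: dict[str, object], test_samples: list[TrainingSample]
) -> pd.DataFrame:
    """MAE mean +/- SD per model x input length, plus the overall column.

    Rows are models, columns input lengths and "overall"; each cell is
    (mae, sd, n). Lengths a model cannot score (no per-length submodel)
    are marked absent with n = 0.
    """
    y = np.array([s.label for s in test_samples])
    lengths = np.array([s.n for s in test_samples])
    uniq = sorted(set(lengths.tolist()))
    rows = []
    for name, model in models.items():
        yhat = np.asarray(model.predict(test_samples), float)
        row: dict = {"model": name}
        for n in uniq:
            m = (lengths == n) & np.isfinite(yhat)
            if m.sum() == 0:
                row[f"mae_len{n}"], row[f"sd_len{n}"], row[f"n_len{n}"] = (
                    np.nan, np.nan, 0)
            else:
                mean, sd = mae(y[m], yhat[m])
                row[f"mae_len{n}"], row[f"sd_len{n}"], row[f"n_len{n}"] = (
                    mean, sd, int(m.sum()))
        m = np.isfinite(yhat)
        mean, sd = mae(y[m], yhat[m])
        row["mae_overall"], row["sd_overall"], row["n_overall"] = (
            mean, sd, int(m.sum()))
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
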