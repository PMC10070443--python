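"""From eye series to model-ready samples.

Pipeline: one-hot encode the unordered categoricals (gender, correction
method) so each check becomes a 16-vector; enumerate every chronological
subsequence of >= 2 checks as a (history, label) training sample, the last
chosen check supplying the SE label and the final interval entry the
prediction horizon; standardize continuous features with training-split
statistics; split 80/10/10 stratified by sequence length at eye level.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np

from myoprog.records import EyeSeries, VisionRecord, quarter_bin

#: Encoded feature layout (16 values per check). Gender expands to the
#: unit vectors male=(1,0) / female=(0,1); correction method likewise.
ENCODED_FEATURES = [
    "school_group",
    "gender_male", "gender_female",
    "age",
    "correction_uncorrected", "correction_spectacles",
    "ucva", "sphere", "astigmatism", "axis", "k1", "k2", "axial_length",
    "myopia_flag", "myopia_level", "se",
]

#: Indices of the one-hot indicator columns; these pass through the scaler
#: unchanged (standardizing a 0/1 unit-vector component distorts scale).
ONE_HOT_INDICES = (1, 2, 4, 5)

_SCALED_MASK = np.array(
    [i not in ONE_HOT_INDICES for i in range(len(ENCODED_FEATURES))]
)

#: Age strata used in the evaluation report.
AGE_GROUPS = ["6-8", "9-11", "12-14", "15-17", "18-20"]


def age_group(age: int) -> str:
    if age <= 8:
        return "6-8"
    if age <= 11:
        return "9-11"
    if age <= 14:
        return "12-14"
    if age <= 17:
        return "15-17"
    return "18-20"


def one_hot_encode(record: VisionRecord) -> np.ndarray:
    """Encode one check as the 16-dimensional model input vector.

    Drops id and check date; expands gender and correction method into
    2-dimensional unit vectors each (male=(1,0), female=(0,1);
    uncorrected=(1,0), spectacles=(0,1)).
    """
    if record.gender not in (0, 1):
        raise ValueError(f"unknown gender code {record.gender!r}")
    if record.correction_method not in (0, 1):
        raise ValueError(f"unknown correction code {record.correction_method!r}")
    male = record.gender == 1
    spect = record.correction_method == 1
    return np.array([
        record.school_group,
        1.0 if male else 0.0, 0.0 if male else 1.0,
        record.age,
        0.0 if spect else 1.0, 1.0 if spect else 0.0,
        record.ucva, record.sphere, record.astigmatism, record.axis,
        record.k1, record.k2, record.axial_length,
        record.myopia_flag, record.myopia_level, record.se,
    ], dtype=float)


@dataclass
class TrainingSample:
    """(history, horizon) -> SE supervision unit.

    ``inputs`` is the n x 16 encoded history; ``intervals[t]`` is the
    quarter bin between check t and the next chosen element — for the last
    check that next element is the label, so ``intervals[-1]`` is the
    prediction horizon. All input checks precede the label's date.
    """

    inputs: np.ndarray            # (n, 16)
    intervals: np.ndarray         # (n,) ints
    label: float                  # SE, diopters
    subject_id: str = ""
    eye: str = ""
    label_myopia_level: int = 0
    label_age: int = 0

    @property
    def n(self) -> int:
        return int(self.inputs.shape[0])

    @property
    def horizon(self) -> int:
        return int(self.intervals[-1])

    def to_json(self) -> dict:
        return {
            "inputs": self.inputs.tolist(),
            "intervals": self.intervals.tolist(),
            "label": self.label,
            "subject_id": self.subject_id,
            "eye": self.eye,
            "label_myopia_level": self.label_myopia_level,
            "label_age": self.label_age,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TrainingSample":
        return cls(
            inputs=np.asarray(obj["inputs"], float),
            intervals=np.asarray(obj["intervals"], int),
            label=float(obj["label"]),
            subject_id=obj.get("subject_id", ""),
            eye=obj.get("eye", ""),
            label_myopia_level=int(obj.get("label_myopia_level", 0)),
            label_age=int(obj.get("label_age", 0)),
        )


def augment(series: EyeSeries) -> list[TrainingSample]:
    """Enumerate every chronological subsequence of >= 2 checks as a sample.

    For an eye with r checks this yields 2^r - r - 1 samples (all subsets
    of size >= 2; singletons and the empty set carry no supervision). The
    latest chosen check is the label; interval entries are the quarter
    bins between consecutive CHOSEN checks, recomputed from calendar
    dates, the final entry being the input-end -> label horizon.
    """
    r = len(series.records)
    samples: list[TrainingSample] = []
    for size in range(2, r + 1):
        for idx in itertools.combinations(range(r), size):
            chosen = [series.records[i] for i in idx]
            label_rec = chosen[-1]
            inputs = np.stack([one_hot_encode(rec) for rec in chosen[:-1]])
            intervals = np.array([
                quarter_bin(a.check_date, b.check_date)
                for a, b in zip(chosen, chosen[1:])
            ], dtype=int)
            samples.append(TrainingSample(
                inputs=inputs,
                intervals=intervals,
                label=label_rec.se,
                subject_id=series.subject_id,
                eye=series.eye,
                label_myopia_level=label_rec.myopia_level,
                label_age=label_rec.age,
            ))
    return samples


def augmentation_census(record_count_histogram: dict[int, int]) -> dict:
    """Expected sample counts per input length from a record-count histogram.

    An eye with r checks yields C(r, k+1) samples of input length k
    (choose the k inputs plus the label), hence 2^r - r - 1 samples in
    total. Returns ``{"by_length": {k: count}, "total": total}``.
    """
    by_length: dict[int, int] = {}
    total = 0
    for r, n_eyes in record_count_histogram.items():
        if r < 2:
            continue
        total += n_eyes * (2 ** r - r - 1)
        for k in range(1, r):
            by_length[k] = by_length.get(k, 0) + n_eyes * comb(r, k + 1)
    return {"by_length": by_length, "total": total}


@dataclass
class StandardScaler:
    """Per-feature standardization x' = (x - mu) / sigma (population sigma).

    One-hot indicator columns pass through unscaled; ``mask`` marks the
    scaled columns. Fit on the training split only.
    """

    mu: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray = field(default_factory=lambda: _SCALED_MASK.copy())

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        out = x.copy()
        out[..., self.mask] = (x[..., self.mask] - self.mu[self.mask]) / self.sigma[self.mask]
        return out

    def inverse(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        out = x.copy()
        out[..., self.mask] = x[..., self.mask] * self.sigma[self.mask] + self.mu[self.mask]
        return out

    def to_json(self) -> dict:
        return {"mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
                "mask": self.mask.astype(int).tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "StandardScaler":
        return cls(np.asarray(obj["mu"], float), np.asarray(obj["sigma"], float),
                   np.asarray(obj["mask"], int).astype(bool))


def fit_scaler(train_samples: list[TrainingSample]) -> StandardScaler:
    """Fit per-feature mean/SD over every input row of the training split."""
    if not train_samples:
        raise ValueError("cannot fit scaler on empty training split")
    rows = np.concatenate([s.inputs for s in train_samples], axis=0)
    mu = rows.mean(axis=0)
    sigma = rows.std(axis=0)
    bad = [ENCODED_FEATURES[i] for i in range(rows.shape[1])
           if _SCALED_MASK[i] and sigma[i] <= 0]
    if bad:
        raise ValueError(f"zero-variance continuous feature(s): {bad}")
    sigma = np.where(_SCALED_MASK, sigma, 1.0)
    return StandardScaler(mu=mu, sigma=sigma)


def apply_scaler(scaler: StandardScaler, sample: TrainingSample) -> TrainingSample:
    """Return a copy of the sample with standardized input features."""
    return TrainingSample(
        inputs=scaler.transform(sample.inputs),
        intervals=sample.intervals.copy(),
        label=sample.label,
        subject_id=sample.subject_id,
        eye=sample.eye,
        label_myopia_level=sample.label_myopia_level,
        label_age=sample.label_age,
    )


@dataclass
class SplitSpec:
    fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    max_train_length: int = 4   # longer histories are too scarce to train on

    def validate(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9 or len(self.fractions) != 3:
            raise ValueError("fractions must be three values summing to 1")


def stratified_split(
    samples: list[TrainingSample], spec: SplitSpec
) -> tuple[list[TrainingSample], list[TrainingSample], list[TrainingSample]]:
    """80/10/10 split stratified by sequence length, assigned at eye level.

    All augmented samples of one eye share a partition (siblings of a
    sample leak its label, so splitting at sample level would contaminate
    evaluation). Eyes are stratified by their record count, which fixes
    each eye's per-length sample profile, so per-length proportions track
    the fractions to within one eye per stratum. Samples with input length
    above ``max_train_length`` are dropped from the training partition
    only (too few to train on; they remain evaluable).
    """
    spec.validate()
    by_eye: dict[tuple[str, str], list[TrainingSample]] = {}
    for s in samples:
        by_eye.setdefault((s.subject_id, s.eye), []).append(s)

    # stratify eyes by record count r (max input length + 1)
    strata: dict[int, list[tuple[str, str]]] = {}
    for key, eye_samples in by_eye.items():
        r = max(s.n for s in eye_samples) + 1
        strata.setdefault(r, []).append(key)

    rng = np.random.default_rng(spec.seed)
    train: list[TrainingSample] = []
    val: list[TrainingSample] = []
    test: list[TrainingSample] = []
    for r in sorted(strata):
        keys = sorted(strata[r])
        rng.shuffle(keys)
        n = len(keys)
        n_train = round(n * spec.fractions[0])
        n_val = round(n * spec.fractions[1])
        for pos, key in enumerate(keys):
            if pos < n_train:
                train.extend(s for s in by_eye[key]
                             if s.n <= spec.max_train_length)
            elif pos < n_train + n_val:
                val.extend(by_eye[key])
            else:
                test.extend(by_eye[key])
    return train, val, test


def save_samples(samples: list[TrainingSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps(s.to_json()) + "\n")


def load_samples(path: str | Path) -> list[TrainingSample]:
    samples = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                samples.append(TrainingSample.from_json(json.loads(line)))
    return samples
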