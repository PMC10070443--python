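"""Synthetic vision-screening cohort generator.

Emulates the statistical structure of a school-screening refraction cohort:
each subject contributes two independent eyes, each eye 2-6 checks at
irregular intervals quantized to quarter bins, with spherical equivalent
drifting myopic over time at an eye-specific rate that decelerates with age.

The progression rate of an eye is tied to its (time-constant) corneal
steepness gap K2 - K1: steeper corneas progress faster in this generator.
That makes the latent rate identifiable from any single record, so with the
measurement noise switched off the future SE is a deterministic function of
one observed check plus the prediction horizon — the property the
time-aware model is meant to exploit. Real cohorts have unobserved
progression drivers; see the methods note for what this simplification
implies.

Visit gaps are drawn directly as quarter bins; the calendar gap for bin
``b`` is placed at ``91*b - 1`` days, i.e. just under ``b`` quarters, so
(i) re-binning the dates recovers ``b`` exactly and (ii) the binned gap
between ANY two checks of a series equals the sum of the intermediate bins.
The cumulative span of a series is capped at 10 quarters, the maximum the
bin scale can express.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from myoprog.records import (
    DAYS_PER_QUARTER,
    EyeSeries,
    VisionRecord,
    classify_myopia,
    derive_se,
)

#: Empirical per-eye record-count distribution over 2..6 checks.
RECORD_COUNT_HIST = {2: 27015, 3: 18732, 4: 25109, 5: 4314, 6: 2}

_TOTAL_EYES = sum(RECORD_COUNT_HIST.values())
_DEFAULT_RECORD_COUNT_PROBS = tuple(
    RECORD_COUNT_HIST[r] / _TOTAL_EYES for r in range(2, 7)
)

_DEFAULT_INTERVAL_PROBS = (
    0.10, 0.30, 0.25, 0.15, 0.08, 0.05, 0.03, 0.02, 0.01, 0.01,
)

_MAX_SPAN_QUARTERS = 10
_BASE_DATE = _dt.date(2019, 10, 1)


@dataclass
class CohortParams:
    """Generator settings; defaults mirror the published cohort marginals.

    ``progression_rate_mean`` is the average SE drift in D/quarter
    (-0.125 ~= -0.5 D/year, a typical school-age progression rate);
    ``progression_rate_sd`` is the between-eye spread of that rate after
    the age deceleration is factored out. ``measurement_noise_sd`` is
    per-check refraction noise on SE in diopters.
    """

    n_subjects: int = 1000
    record_count_probs: tuple = _DEFAULT_RECORD_COUNT_PROBS
    age_mean: float = 10.38
    age_sd: float = 2.90
    age_range: tuple = (6, 18)          # baseline age; grows during follow-up
    baseline_se_mean: float = -1.2
    baseline_se_sd: float = 1.6
    progression_rate_mean: float = -0.125   # D / quarter
    progression_rate_sd: float = 0.03       # D / quarter
    measurement_noise_sd: float = 0.1       # D
    interval_bin_probs: tuple = _DEFAULT_INTERVAL_PROBS
    decel_rate: float = 0.05     # per year of age beyond 6
    decel_floor: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name, probs, n in (
            ("record_count_probs", self.record_count_probs, 5),
            ("interval_bin_probs", self.interval_bin_probs, 10),
        ):
            p = np.asarray(probs, dtype=float)
            if p.shape != (n,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be {n} non-negative values summing to 1")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def age_deceleration(age: float, rate: float = 0.05, floor: float = 0.3) -> float:
    """Multiplicative slow-down of SE progression with age.

    Myopia progresses fastest in young children and slows through the
    teens; modelled as ``max(floor, 1 - rate * (age - 6))``.
    """
    return max(floor, 1.0 - rate * (max(age, 6.0) - 6.0))


def progression_activity(se: float) -> float:
    """State-dependent progression multiplier (dimensionless).

    SE trajectories are not linear in time: drift is fastest while an eye
    moves through the low/moderate-myopia band, slower before onset, and
    stabilizes toward high myopia. Modelled as a Gaussian bump over the
    current SE, 0.2 + 1.4 * exp(-((se + 2.5) / 2.5)^2): ~1.6 at -2.5 D,
    ~0.7 at 0 D, ~0.4 at -6 D. Because the next quarter's drift depends on
    the current SE, the trajectory is an iterated nonlinear map of the
    horizon — a signal a single linear fit in the interval cannot express.
    """
    return 0.2 + 1.4 * float(np.exp(-(((se + 2.5) / 2.5) ** 2)))


def advance_se(se: float, slope: float, base_age: int, cum_quarters: int,
               n_quarters: int, decel_rate: float = 0.05,
               decel_floor: float = 0.3) -> float:
    """Advance the latent SE by ``n_quarters``, one quarter at a time.

    Each quarter's drift is slope x age_deceleration x
    progression_activity evaluated at the state at the start of that
    quarter; ``cum_quarters`` is the eye's elapsed follow-up (sets the
    integer age along the path).
    """
    for q in range(n_quarters):
        age = min(base_age + (cum_quarters + q) // 4, 20)
        se = se + slope * age_deceleration(age, decel_rate, decel_floor) \
            * progression_activity(se)
    return float(np.clip(se, -11.0, 8.0))


def _school_group(age: int) -> int:
    if age <= 11:
        return 1
    if age <= 14:
        return 2
    return 3


def _draw_axis(rng: np.random.Generator) -> int:
    u = rng.random()
    if u < 0.875:   # with-the-rule
        return int(rng.integers(0, 30)) if rng.random() < 0.5 else int(rng.integers(151, 181))
    if u < 0.92:    # against-the-rule
        return int(rng.integers(60, 121))
    return int(rng.integers(30, 60)) if rng.random() < 0.5 else int(rng.integers(121, 151))


def _draw_gaps(rng: np.random.Generator, n_gaps: int, probs: np.ndarray) -> list[int]:
    """Draw quarter-bin gaps whose sum stays within the 10-quarter span cap."""
    gaps: list[int] = []
    used = 0
    for j in range(n_gaps):
        remaining_after = n_gaps - j - 1
        budget = _MAX_SPAN_QUARTERS - used - remaining_after
        p = probs[:budget].copy()
        total = p.sum()
        if total <= 0:
            b = 1
        else:
            b = int(rng.choice(np.arange(1, budget + 1), p=p / total))
        gaps.append(b)
        used += b
    return gaps


def _generate_eye(
    rng: np.random.Generator,
    params: CohortParams,
    subject_id: str,
    eye: str,
    gender: int,
    base_age: int,
) -> EyeSeries:
    probs_rc = np.asarray(params.record_count_probs, float)
    probs_iv = np.asarray(params.interval_bin_probs, float)
    n_records = int(rng.choice(np.arange(2, 7), p=probs_rc))
    gaps = _draw_gaps(rng, n_records - 1, probs_iv)

    baseline_se = float(np.clip(
        rng.normal(params.baseline_se_mean, params.baseline_se_sd), -11.0, 8.0,
    ))
    # corneal steepness gap encodes the progression-rate deviation (z)
    z = float(rng.standard_normal())
    slope = params.progression_rate_mean - params.progression_rate_sd * z
    k1 = float(np.clip(rng.normal(42.54, 1.2), 37.05, 48.63))
    k2 = float(np.clip(k1 + 1.33 + 0.5 * z, 37.58, 50.0))
    astig_base = float(np.clip(rng.normal(-0.71, 0.6), -6.0, 0.0))
    al_base = float(rng.normal(23.2 + 0.25 * (_school_group(base_age) - 1), 0.6))
    axis = _draw_axis(rng)
    start = _BASE_DATE + _dt.timedelta(days=int(rng.integers(0, 180)))

    records = []
    latent_se = baseline_se
    cum_quarters = 0
    date = start
    for t in range(n_records):
        age = min(base_age + cum_quarters // 4, 20)
        se = latent_se
        if params.measurement_noise_sd > 0:
            se += float(rng.normal(0.0, params.measurement_noise_sd))
        se = float(np.clip(se, -11.0, 8.0))
        astig = float(np.clip(
            astig_base + float(rng.normal(0.0, 0.05)), -6.75, 0.0,
        ))
        # keep sphere = SE - astig/2 inside its valid range
        sphere = se - astig / 2.0
        if sphere > 8.75:
            astig = max(astig, 2.0 * (se - 8.75))
            sphere = se - astig / 2.0
        sphere_r = round(sphere, 6)
        astig_r = round(astig, 6)
        se_rec = derive_se(sphere_r, astig_r)
        flag, level = classify_myopia(se_rec)
        ucva = float(np.clip(
            round(-0.05 - 0.25 * min(se, 0.0) + rng.normal(0.0, 0.08), 1),
            -0.3, 1.0,
        ))
        corr_p = 0.57 if flag else 0.10
        records.append(VisionRecord(
            subject_id=subject_id,
            eye=eye,
            check_date=date,
            school_group=_school_group(age),
            gender=gender,
            age=age,
            correction_method=int(rng.random() < corr_p),
            ucva=ucva,
            sphere=sphere_r,
            astigmatism=astig_r,
            axis=float(axis),
            k1=round(k1, 2),
            k2=round(k2, 2),
            axial_length=round(float(np.clip(al_base + 0.35 * (-se_rec), 18.59, 29.86)), 3),
            myopia_flag=flag,
            myopia_level=level,
            se=se_rec,
        ))
        if t < n_records - 1:
            b = gaps[t]
            latent_se = advance_se(latent_se, slope, base_age, cum_quarters,
                                   b, params.decel_rate, params.decel_floor)
            cum_quarters += b
            date = date + _dt.timedelta(days=DAYS_PER_QUARTER * b - 1)
    return EyeSeries(subject_id=subject_id, eye=eye, records=records)


def generate_cohort(params: CohortParams) -> list[EyeSeries]:
    """Generate a cohort of independent per-eye check series.

    Deterministic given ``params.seed``. Each subject contributes a left
    and a right eye with independent trajectories (eyes are treated as
    independent samples throughout the pipeline).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cohort: list[EyeSeries] = []
    for i in range(params.n_subjects):
        subject_id = f"S{i:06d}"
        gender = int(rng.random() < 0.515)
        base_age = int(np.clip(
            round(rng.normal(params.age_mean, params.age_sd)),
            params.age_range[0], params.age_range[1],
        ))
        for eye in ("R", "L"):
            cohort.append(
                _generate_eye(rng, params, subject_id, eye, gender, base_age)
            )
    return cohort


_CONTINUOUS = ["age", "ucva", "sphere", "astigmatism", "k1", "k2",
               "axial_length", "se"]
_CATEGORICAL = ["school_group", "gender", "correction_method",
                "myopia_flag", "myopia_level"]


def cohort_summary(cohort: list[EyeSeries]) -> pd.DataFrame:
    """Per-feature marginal summary over all records of a cohort.

    Continuous features: mean, SD (population), min, max. Categorical
    features: one row per category with its percentage. Layout matches the
    usual cohort-description table so it can be eyeballed against
    published marginals.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows = [
        {f: getattr(rec, f) for f in _CONTINUOUS + _CATEGORICAL}
        for series in cohort for rec in series.records
    ]
    df = pd.DataFrame(rows)
    out = []
    for f in _CONTINUOUS:
        v = df[f].to_numpy(float)
        out.append({
            "feature": f, "category": "",
            "mean": float(v.mean()), "sd": float(v.std()),
            "min": float(v.min()), "max": float(v.max()),
            "percent": float("nan"),
        })
    for f in _CATEGORICAL:
        counts = df[f].value_counts().sort_index()
        for cat, cnt in counts.items():
            out.append({
                "feature": f, "category": str(cat),
                "mean": float("nan"), "sd": float("nan"),
                "min": float("nan"), "max": float("nan"),
                "percent": 100.0 * cnt / len(df),
            })
    return pd.DataFrame(out)
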