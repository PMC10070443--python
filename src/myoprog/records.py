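"""Vision-check domain types and clinical derivations.

A vision record is one refraction/biometry check of one eye: demographic
fields, uncorrected visual acuity (logMAR-like), subjective refraction
(sphere, cylinder/astigmatism, axis), corneal curvature (K1 flattest / K2
steepest meridian, diopters), axial length (mm), and the derived spherical
equivalent (SE) with its myopia grading.

Checks of the same eye form an :class:`EyeSeries`; the elapsed time between
consecutive checks is quantized to quarter bins 1-10, bin ``i`` covering
``[i-1, i)`` quarters of 91 days.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

DAYS_PER_QUARTER = 91
MAX_INTERVAL_BIN = 10

#: CSV column order: id, check date, then the 14 clinical/demographic fields.
COLUMNS = [
    "id", "check_date", "school_group", "gender", "age", "correction_method",
    "ucva", "sphere", "astigmatism", "axis", "k1", "k2", "axial_length",
    "myopia_flag", "myopia_level", "se",
]

#: Inclusive valid ranges for the numeric fields (cohort-wide extrema).
FIELD_RANGES = {
    "age": (6, 20),
    "ucva": (-0.3, 1.0),
    "sphere": (-11.25, 8.75),
    "astigmatism": (-6.75, 0.0),
    "axis": (0.0, 180.0),
    "k1": (37.05, 48.63),
    "k2": (37.58, 50.0),
    "axial_length": (18.59, 29.86),
    "se": (-12.63, 8.25),
}

SE_CONSISTENCY_TOL = 0.005

AXIS_WITH_THE_RULE = "with-the-rule"
AXIS_AGAINST_THE_RULE = "against-the-rule"
AXIS_OBLIQUE = "oblique"


class ValidationError(ValueError):
    """Raised on invalid inputs; carries per-row diagnostics for files."""

    def __init__(self, message: str, row_errors: list[dict] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def derive_se(sphere: float, astigmatism: float) -> float:
    """Spherical equivalent in diopters: sphere + cylinder/2.

    The single-number refraction summary used for myopia screening;
    ``astigmatism`` is the (non-positive) cylinder power.
    """
    sphere = _require_finite("sphere", sphere)
    astigmatism = _require_finite("astigmatism", astigmatism)
    return sphere + astigmatism / 2.0


def classify_myopia(se: float) -> tuple[int, int]:
    """Myopia flag and severity level from spherical equivalent.

    Thresholds follow the Asia Optometric Management Academy consensus:
    myopia iff SE <= -0.5 D; low (-3, -0.5], moderate (-6, -3],
    high <= -6 D.
    """
    se = _require_finite("se", se)
    if se > -0.5:
        return 0, 0
    if se > -3.0:
        return 1, 1
    if se > -6.0:
        return 1, 2
    return 1, 3


def classify_axis(axis: float) -> str:
    """Astigmatism orientation class from the cylinder axis in degrees.

    With-the-rule (steep meridian near vertical): axis < 30 or > 150;
    against-the-rule: 60 <= axis <= 120; oblique otherwise.
    """
    axis = _require_finite("axis", axis)
    if not 0.0 <= axis <= 180.0:
        raise ValidationError(f"axis must be in [0, 180], got {axis}")
    if axis < 30.0 or axis > 150.0:
        return AXIS_WITH_THE_RULE
    if 60.0 <= axis <= 120.0:
        return AXIS_AGAINST_THE_RULE
    return AXIS_OBLIQUE


def quarter_bin(date_a: _dt.date, date_b: _dt.date) -> int:
    """Quantize the gap between two check dates to a quarter bin in [1, 10].

    Bin ``i`` covers an elapsed time of ``[i-1, i)`` quarters of 91 days;
    gaps of 10 or more quarters saturate at bin 10.
    """
    if date_b <= date_a:
        raise ValidationError(
            f"date_b must be after date_a, got {date_a} -> {date_b}"
        )
    days = (date_b - date_a).days
    return min(days // DAYS_PER_QUARTER + 1, MAX_INTERVAL_BIN)


@dataclass
class VisionRecord:
    """One vision check of one eye (the 16 tabulated features)."""

    subject_id: str
    eye: str                 # "L" / "R"
    check_date: _dt.date
    school_group: int        # 1 elementary, 2 middle, 3 high school
    gender: int              # 0 female, 1 male
    age: int                 # years
    correction_method: int   # 0 uncorrected, 1 spectacles
    ucva: float              # uncorrected visual acuity, logMAR-like
    sphere: float            # D
    astigmatism: float       # D, <= 0
    axis: float              # degrees in [0, 180]
    k1: float                # D
    k2: float                # D
    axial_length: float      # mm
    myopia_flag: int
    myopia_level: int
    se: float                # D

    def validate(self) -> tuple[list[str], list[str]]:
        """Return (hard errors, warnings) for this record.

        Range violations and bad categorical codes are errors; SE or
        myopia-grade inconsistency (within tolerance) is a warning only,
        since source tables occasionally carry rounding slop.
        """
        errors: list[str] = []
        warnings: list[str] = []
        for name, (lo, hi) in FIELD_RANGES.items():
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                errors.append(f"{name} not finite: {v!r}")
            elif not lo <= v <= hi:
                errors.append(f"{name}={v} outside [{lo}, {hi}]")
        if self.school_group not in (1, 2, 3):
            errors.append(f"school_group={self.school_group} not in {{1,2,3}}")
        if self.gender not in (0, 1):
            errors.append(f"gender={self.gender} not in {{0,1}}")
        if self.correction_method not in (0, 1):
            errors.append(f"correction_method={self.correction_method} not in {{0,1}}")
        if self.myopia_flag not in (0, 1):
            errors.append(f"myopia_flag={self.myopia_flag} not in {{0,1}}")
        if self.myopia_level not in (0, 1, 2, 3):
            errors.append(f"myopia_level={self.myopia_level} not in {{0..3}}")
        if not errors:
            expected_se = derive_se(self.sphere, self.astigmatism)
            if abs(expected_se - self.se) > SE_CONSISTENCY_TOL:
                warnings.append(
                    f"se={self.se} differs from sphere+astigmatism/2="
                    f"{expected_se} by more than {SE_CONSISTENCY_TOL}"
                )
            flag, level = classify_myopia(self.se)
            if (flag, level) != (self.myopia_flag, self.myopia_level):
                warnings.append(
                    f"myopia grade ({self.myopia_flag}, {self.myopia_level}) "
                    f"inconsistent with SE {self.se} -> ({flag}, {level})"
                )
        return errors, warnings


@dataclass
class EyeSeries:
    """Time-ordered vision checks of one eye with quarter-binned gaps."""

    subject_id: str
    eye: str
    records: list[VisionRecord]
    intervals: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.intervals and len(self.records) > 1:
            self.intervals = [
                quarter_bin(a.check_date, b.check_date)
                for a, b in zip(self.records, self.records[1:])
            ]

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.eye)

    def validate(self) -> list[str]:
        errors = []
        dates = [r.check_date for r in self.records]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            errors.append("check dates not strictly increasing")
        if len(self.intervals) != len(self.records) - 1:
            errors.append("len(intervals) != len(records) - 1")
        if any(not 1 <= b <= MAX_INTERVAL_BIN for b in self.intervals):
            errors.append("interval bin outside [1, 10]")
        return errors


def _record_to_row(rec: VisionRecord) -> dict:
    row = asdict(rec)
    row["id"] = row.pop("subject_id")
    row["check_date"] = rec.check_date.isoformat()
    return row


def _row_to_record(row: pd.Series, eye: str) -> VisionRecord:
    date = row["check_date"]
    if not isinstance(date, _dt.date) or isinstance(date, _dt.datetime):
        date = _dt.date.fromisoformat(str(date).strip()[:10])
    return VisionRecord(
        subject_id=str(row["id"]),
        eye=eye,
        check_date=date,
        school_group=int(row["school_group"]),
        gender=int(row["gender"]),
        age=int(row["age"]),
        correction_method=int(row["correction_method"]),
        ucva=float(row["ucva"]),
        sphere=float(row["sphere"]),
        astigmatism=float(row["astigmatism"]),
        axis=float(row["axis"]),
        k1=float(row["k1"]),
        k2=float(row["k2"]),
        axial_length=float(row["axial_length"]),
        myopia_flag=int(row["myopia_flag"]),
        myopia_level=int(row["myopia_level"]),
        se=float(row["se"]),
    )


def read_records(
    path: str | Path,
    report_path: str | Path | None = None,
) -> list[EyeSeries]:
    """Read a vision-record CSV and group rows into per-eye series.

    The file must carry the 16 canonical columns (see :data:`COLUMNS`);
    an optional ``eye`` column distinguishes the two eyes of a subject
    (defaults to "R" when absent, e.g. for single-eye extracts). Rows are
    grouped by (id, eye) and sorted by check date; quarter bins are
    recomputed from the dates.

    Any invalid row fails the whole file with a :class:`ValidationError`
    whose ``row_errors`` list one JSON-serializable diagnostic per rejected
    row; ``report_path`` additionally writes them as JSON lines.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty and len(df.columns) <= 1:
        return []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    if "eye" not in df.columns:
        df["eye"] = "R"

    row_errors: list[dict] = []
    records: list[VisionRecord] = []
    for idx, row in df.iterrows():
        try:
            rec = _row_to_record(row, str(row["eye"]))
        except (ValueError, TypeError) as exc:
            row_errors.append({"row": int(idx), "errors": [str(exc)]})
            continue
        errors, _warnings = rec.validate()
        if errors:
            row_errors.append({"row": int(idx), "errors": errors})
        else:
            records.append(rec)

    series_map: dict[tuple[str, str], list[VisionRecord]] = {}
    for rec in records:
        series_map.setdefault((rec.subject_id, rec.eye), []).append(rec)

    series_list = []
    for (sid, eye), recs in series_map.items():
        recs = sorted(recs, key=lambda r: r.check_date)
        dates = [r.check_date for r in recs]
        if len(set(dates)) != len(dates):
            row_errors.append(
                {"eye": [sid, eye], "errors": ["duplicated check_date"]}
            )
            continue
        series_list.append(EyeSeries(subject_id=sid, eye=eye, records=recs))

    if report_path is not None:
        with open(report_path, "w") as fh:
            for err in row_errors:
                fh.write(json.dumps(err) + "\n")
    if row_errors:
        raise ValidationError(
            f"{len(row_errors)} invalid rows/groups in {path}", row_errors
        )
    return series_list


def write_records(series_list: Iterable[EyeSeries], path: str | Path) -> None:
    """Write eye series back to the canonical CSV dialect (plus eye column)."""
    rows = []
    for series in series_list:
        for rec in series.records:
            rows.append(_record_to_row(rec))
    if rows:
        df = pd.DataFrame(rows)[COLUMNS + ["eye"]]
    else:
        df = pd.DataFrame(columns=COLUMNS + ["eye"])
    df.to_csv(path, index=False)
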