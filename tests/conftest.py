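import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from myoprog.cohort import CohortParams, generate_cohort
from myoprog.preprocessing import SplitSpec, augment, stratified_split
from myoprog.records import EyeSeries, VisionRecord, classify_myopia, derive_se


def make_record(**overrides) -> VisionRecord:
    """A valid record with sensible defaults; fields overridable."""
    base = dict(
        subject_id="S1", eye="R", check_date=dt.date(2020, 1, 15),
        school_group=1, gender=0, age=10, correction_method=0,
        ucva=0.2, sphere=-1.0, astigmatism=-0.5, axis=10.0,
        k1=42.5, k2=43.8, axial_length=23.9,
    )
    base.update(overrides)
    if "se" not in base:
        base["se"] = derive_se(base["sphere"], base["astigmatism"])
    if "myopia_flag" not in base:
        flag, level = classify_myopia(base["se"])
        base["myopia_flag"], base["myopia_level"] = flag, level
    return VisionRecord(**base)


# The published worked example: five checks of one adolescent eye (id 1).
TABLE2_ROWS = [
    # (date, school, gender, age, corr, ucva, sphere, astig, axis, k1, k2, al, flag, level, se)
    ("2019-10-21", 1, 0, 11, 0, -0.10, 0.0, -0.5, 159, 43.16, 45.06, 23.16, 0, 0, -0.25),
    ("2020-09-27", 2, 0, 11, 0, 0.1, -0.25, -0.75, 165, 43.32, 45.06, 23.38, 1, 1, -0.625),
    ("2021-04-28", 2, 0, 12, 0, 0.4, -1.25, -0.75, 164, 43.21, 45.24, 23.74, 1, 1, -1.625),
    ("2021-11-04", 2, 0, 13, 0, 0.2, -1.5, -0.5, 162, 43.53, 45.15, 23.91, 1, 1, -1.75),
    ("2022-03-09", 2, 0, 13, 0, 0.3, -1.25, -0.75, 170, 43.32, 45.0, 23.85, 1, 1, -1.625),
]

TABLE2_HEADER = ("id,check_date,school_group,gender,age,correction_method,"
                 "ucva,sphere,astigmatism,axis,k1,k2,axial_length,"
                 "myopia_flag,myopia_level,se")


def table2_csv_text() -> str:
    lines = [TABLE2_HEADER]
    for row in TABLE2_ROWS:
        lines.append("1," + ",".join(str(v) for v in row))
    return "\n".join(lines) + "\n"


@pytest.fixture
def table2_csv(tmp_path):
    path = tmp_path / "table2.csv"
    path.write_text(table2_csv_text())
    return path


@pytest.fixture
def table2_series(table2_csv):
    from myoprog.records import read_records
    (series,) = read_records(table2_csv)
    return series


def make_series(n_records: int, start=dt.date(2020, 1, 15),
                gap_days=(100, 200, 95, 120, 300), se_step=-0.25) -> EyeSeries:
    records = []
    date = start
    se = -0.5
    for t in range(n_records):
        sphere = se + 0.25  # astig fixed at -0.5
        records.append(make_record(check_date=date, sphere=sphere,
                                   astigmatism=-0.5, age=10 + t // 2))
        if t < n_records - 1:
            date = date + dt.timedelta(days=gap_days[t % len(gap_days)])
            se += se_step
    return EyeSeries(subject_id="S1", eye="R", records=records)


@pytest.fixture(scope="session")
def small_cohort():
    """200 eyes with default (noisy) generator settings."""
    return generate_cohort(CohortParams(n_subjects=100, seed=11))


@pytest.fixture(scope="session")
def small_splits(small_cohort):
    samples = [x for s in small_cohort for x in augment(s)]
    return stratified_split(samples, SplitSpec(seed=11))
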