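"""Stratified error reporting.

Prediction error (MAE of spherical equivalent, diopters) is broken down
three ways: by (prediction horizon x input length), by the label's myopia
level, and by the label's age group. Cells report mean, SD and count of the
absolute errors; cells with fewer than 100 samples are flagged as too small
to be a solid reference but never dropped. Marginals are recomputed from
the raw errors, not averaged from cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from myoprog.preprocessing import TrainingSample, age_group

SMALL_CELL_THRESHOLD = 100

_AXES = ("horizon_by_length", "myopia_level", "age_group")


@dataclass
class StratifiedReport:
    """MAE cells keyed by stratum; see :func:`stratify`.

    ``tables`` maps each stratification axis to a DataFrame with columns
    mean/sd/n/small; ``overall`` is the unstratified (mean, sd, n).
    """

    tables: dict[str, pd.DataFrame]
    overall: tuple[float, float, int]

    def flagged_cells(self) -> list[tuple[str, object]]:
        out = []
        for axis, table in self.tables.items():
            for key, row in table.iterrows():
                if row["small"]:
                    out.append((axis, key))
        return out


def _cells(keys: list, errors: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"key": keys, "err": errors})
    rows = []
    for key, grp in df.groupby("key", sort=True):
        e = grp["err"].to_numpy()
        rows.append({
            "key": key, "mean": float(e.mean()), "sd": float(e.std()),
            "n": int(len(e)), "small": bool(len(e) < SMALL_CELL_THRESHOLD),
        })
    return pd.DataFrame(rows).set_index("key")


def stratify(
    predictions: np.ndarray, samples: list[TrainingSample]
) -> StratifiedReport:
    """Stratified MAE report for predictions on the given samples.

    Every sample must carry its metadata (horizon, input length, label
    myopia level, label age). Cell SD is the SD of absolute errors within
    the cell, matching the "mean +/- SD" convention of stratified error
    tables.
    """
    predictions = np.asarray(predictions, float)
    if len(predictions) != len(samples):
        raise ValueError("predictions and samples length mismatch")
    if len(samples) == 0:
        raise ValueError("empty evaluation set")
    errors = np.abs(predictions - np.array([s.label for s in samples]))

    hl_keys = [(s.horizon, s.n) for s in samples]
    level_keys = [s.label_myopia_level for s in samples]
    age_keys = [age_group(s.label_age) for s in samples]

    tables = {
        "horizon_by_length": _cells(hl_keys, errors),
        "myopia_level": _cells(level_keys, errors),
        "age_group": _cells(age_keys, errors),
    }
    overall = (float(errors.mean()), float(errors.std()), int(len(errors)))
    return StratifiedReport(tables=tables, overall=overall)


def _horizon_length_grid(report: StratifiedReport) -> pd.DataFrame:
    """Pivot the horizon x length axis into the conventional table layout:

    rows = prediction horizon, columns = input length, plus summary row
    and column recomputed from raw cell contents (sample-weighted).
    """
    table = report.tables["horizon_by_length"]
    rows = {}
    for (h, n), row in table.iterrows():
        star = "*" if row["small"] else ""
        rows.setdefault(h, {})[n] = (
            f"{row['mean']:.3f} ± {row['sd']:.3f} ({row['n']}){star}"
        )
    grid = pd.DataFrame(rows).T.sort_index()
    grid.index.name = "horizon"
    return grid[sorted(grid.columns)]


def render_report(report: StratifiedReport, path: str | Path,
                  fmt: str = "json") -> None:
    """Write the report as "json" (full precision), "csv", or "txt".

    JSON round-trips exactly through :func:`parse_report`; the text format
    shows the horizon x length grid as "mean +/- sd (n)" cells with the
    small-sample marker.
    """
    path = Path(path)
    if fmt == "json":
        payload = {
            "overall": {"mean": report.overall[0], "sd": report.overall[1],
                        "n": report.overall[2]},
            "tables": {
                axis: [
                    {"key": list(k) if isinstance(k, tuple) else k,
                     **row.to_dict()}
                    for k, row in table.iterrows()
                ]
                for axis, table in report.tables.items()
            },
        }
        path.write_text(json.dumps(payload, indent=1))
    elif fmt == "csv":
        frames = []
        for axis, table in report.tables.items():
            t = table.reset_index()
            t.insert(0, "axis", axis)
            t["key"] = t["key"].astype(str)
            frames.append(t)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif fmt == "txt":
        mean, sd, n = report.overall
        lines = [f"Overall MAE: {mean:.3f} ± {sd:.3f} ({n})", ""]
        lines.append(_horizon_length_grid(report).to_string())
        lines.append("")
        lines.append("* sample size < 100, too small to be a solid reference")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def parse_report(path: str | Path) -> StratifiedReport:
    """Read back a JSON report written by :func:`render_report`."""
    payload = json.loads(Path(path).read_text())
    tables = {}
    for axis, rows in payload["tables"].items():
        recs = []
        for row in rows:
            key = row.pop("key")
            row["key"] = tuple(key) if isinstance(key, list) else key
            recs.append(row)
        df = pd.DataFrame(recs).set_index("key")
        df["n"] = df["n"].astype(int)
        df["small"] = df["small"].astype(bool)
        tables[axis] = df[["mean", "sd", "n", "small"]]
    ov = payload["overall"]
    return StratifiedReport(tables=tables,
                            overall=(ov["mean"], ov["sd"], int(ov["n"])))
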