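"""Reading and writing the long-format time-course CSV dialect.

One canonical long format holds every experiment type:

    cell_line,experiment,observable,time,time_unit,value,sd

``observable`` is one of PM, RE, LELY, intracellular_fraction; ``time_unit``
is ``min`` or ``h`` (hours are converted to minutes on ingest — all internal
times are minutes); ``sd`` may be empty.  Lines starting with ``#`` are
comments and carry generator provenance for synthetic datasets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import EXPERIMENTS, SERIES_NAMES, TimeCourseDataset, TimeSeries
from .errors import ParseError

__all__ = ["REQUIRED_COLUMNS", "read_timecourse", "write_timecourse"]

REQUIRED_COLUMNS = (
    "cell_line",
    "experiment",
    "observable",
    "time",
    "time_unit",
    "value",
)
_TIME_UNIT_TO_MIN = {"min": 1.0, "h": 60.0}


def _count_header_offset(path: Path) -> int:
    """Line number (1-based) of the header row, after leading comments."""
    offset = 1
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                offset += 1
            else:
                break
    return offset


def read_timecourse(path: "str | Path") -> list[TimeCourseDataset]:
    """Parse a time-course CSV into datasets grouped by (cell_line, experiment)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    header_line = _count_header_offset(path)
    try:
        frame = pd.read_csv(path, comment="#", dtype={"cell_line": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if "sd" not in frame.columns:
        frame["sd"] = np.nan

    def fail(idx: int, message: str) -> ParseError:
        return ParseError(f"{path}, line {header_line + 1 + idx}: {message}")

    for idx, row in frame.iterrows():
        if row["observable"] not in SERIES_NAMES:
            raise fail(idx, f"invalid observable {row['observable']!r}")
        if row["experiment"] not in EXPERIMENTS:
            raise fail(idx, f"invalid experiment {row['experiment']!r}")
        if row["time_unit"] not in _TIME_UNIT_TO_MIN:
            raise fail(idx, f"invalid time_unit {row['time_unit']!r} (use min or h)")
        for col in ("time", "value"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise fail(idx, f"non-numeric {col}: {row[col]!r}") from None
        if float(row["time"]) < 0:
            raise fail(idx, f"negative time {row['time']!r}")
        if float(row["value"]) < 0:
            raise fail(idx, f"negative value {row['value']!r}")

    frame["time_min"] = frame["time"].astype(float) * frame["time_unit"].map(
        _TIME_UNIT_TO_MIN
    )
    datasets: list[TimeCourseDataset] = []
    for (cell_line, experiment), block in frame.groupby(
        ["cell_line", "experiment"], sort=False
    ):
        if block["time_unit"].nunique() > 1:
            raise ParseError(
                f"{path}: mixed time units within block "
                f"({cell_line!r}, {experiment!r})"
            )
        series = {}
        for observable, sub in block.groupby("observable", sort=False):
            sub = sub.sort_values("time_min")
            sd = sub["sd"].astype(float).to_numpy()
            series[observable] = TimeSeries(
                time=sub["time_min"].to_numpy(),
                value=sub["value"].astype(float).to_numpy(),
                sd=None if np.isnan(sd).all() else sd,
            )
        datasets.append(
            TimeCourseDataset(cell_line=cell_line, experiment=experiment, series=series)
        )
    return datasets


def write_timecourse(
    datasets: "TimeCourseDataset | Iterable[TimeCourseDataset]",
    path: "str | Path",
    time_unit: str = "min",
    float_format: str = "%.12g",
) -> Path:
    """Write datasets to the canonical CSV; provenance goes into '#' comments.

    Values round-trip through :func:`read_timecourse` to 12 significant
    digits.  ``time_unit`` selects the on-disk unit (storage stays minutes).
    """
    if isinstance(datasets, TimeCourseDataset):
        datasets = [datasets]
    datasets = list(datasets)
    if time_unit not in _TIME_UNIT_TO_MIN:
        raise ParseError(f"invalid time_unit {time_unit!r} (use min or h)")
    scale = _TIME_UNIT_TO_MIN[time_unit]
    path = Path(path)
    rows = []
    for dataset in datasets:
        for observable, series in dataset.series.items():
            for i in range(len(series)):
                rows.append(
                    {
                        "cell_line": dataset.cell_line,
                        "experiment": dataset.experiment,
                        "observable": observable,
                        "time": series.time[i] / scale,
                        "time_unit": time_unit,
                        "value": series.value[i],
                        "sd": series.sd[i] if series.sd is not None else "",
                    }
                )
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["sd"])
    with open(path, "w") as fh:
        for dataset in datasets:
            if dataset.provenance:
                fh.write(
                    f"# provenance {dataset.cell_line}/{dataset.experiment}: "
                    + json.dumps(dataset.provenance)
                    + "\n"
                )
        frame.to_csv(fh, index=False, float_format=float_format)
    return path
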