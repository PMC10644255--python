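"""Observed time-course containers shared by the fitting, synthetic-data and
I/O layers.  Times are stored in minutes; values are fractional fluorescence
(dimensionless, typically in [0, 1])."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ParameterError

__all__ = ["SERIES_NAMES", "EXPERIMENTS", "TimeSeries", "TimeCourseDataset"]

#: Observable vocabulary accepted in datasets and CSV files.
SERIES_NAMES = ("PM", "RE", "LELY", "intracellular_fraction")
EXPERIMENTS = ("pulse_chase", "continuous_uptake", "efflux")


@dataclass(frozen=True)
class TimeSeries:
    """One observable's (time, value, optional sd) triples, sorted in time."""

    time: np.ndarray  # minutes
    value: np.ndarray
    sd: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        value = np.asarray(self.value, dtype=float)
        if time.ndim != 1 or time.shape != value.shape or time.size == 0:
            raise ParameterError("time and value must be equal-length 1-D arrays")
        if np.any(time < 0) or np.any(np.diff(time) < 0):
            raise ParameterError("times must be >= 0 and sorted")
        if np.any(value < 0):
            raise ParameterError("values must be >= 0")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "value", value)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != time.shape or np.any(sd <= 0):
                raise ParameterError("sd must match the series shape and be > 0")
            object.__setattr__(self, "sd", sd)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class TimeCourseDataset:
    """Fractional-fluorescence curves of one experiment on one cell line."""

    cell_line: str
    experiment: str
    series: Mapping[str, TimeSeries]
    provenance: "dict | None" = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ParameterError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if not self.series:
            raise ParameterError("dataset must contain at least one series")
        for name in self.series:
            if name not in SERIES_NAMES:
                raise ParameterError(
                    f"unknown observable {name!r}; choose from {SERIES_NAMES}"
                )
        object.__setattr__(self, "series", dict(self.series))

    @property
    def n_obs(self) -> int:
        return sum(len(s) for s in self.series.values())
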