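"""Spike-time and time-series I/O.

Spike times arrive as plain text / single-column CSV, one ascending
timestamp per line; ISI (interspike-interval) series as single-column CSV
with an optional header. Spike sorting is upstream of this package: the
input is assumed to be the spike times of a single, already isolated unit.

Units are carried as free-text tags only. ISI series are emitted in the
same unit as the spike times — scales in the structure function count
samples (intervals), so physical units matter only for labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InsufficientDataError, ParseError, ValidationError

__all__ = [
    "SpikeTrain",
    "TimeSeries",
    "read_spike_times",
    "spike_times_to_isi",
    "read_series",
    "write_series",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike timestamps of a single unit.

    Parameters
    ----------
    times
        Spike occurrence times, strictly increasing, finite, non-negative.
    unit
        Time unit tag (default ``"s"``); informational only.
    """

    times: np.ndarray
    unit: str = "s"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValidationError("spike times must be one-dimensional")
        if times.size and not np.all(np.isfinite(times)):
            raise ValidationError("spike times must be finite")
        if times.size and times[0] < 0:
            raise ValidationError("spike times must be non-negative")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ValidationError(
                f"spike times must be strictly increasing (violation at index {bad})"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TimeSeries:
    """Ordered real-valued samples I(t) = {I_t1, ..., I_tn}.

    For ISI series the values are interval durations and must be positive;
    a generic series only needs to be finite.
    """

    values: np.ndarray
    unit: str = ""
    label: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValidationError("series values must be one-dimensional")
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("series values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Copy of this series with new values, keeping metadata."""
        return replace(self, values=np.asarray(values, dtype=float))


def _numeric_lines(path: Path):
    """Yield (lineno, token) for non-blank, non-comment lines of a text file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_spike_times(path, unit: str = "s") -> SpikeTrain:
    """Read spike times from a plain-text / single-column CSV file.

    One timestamp per line; blank lines and ``#`` comments are skipped.
    An empty file yields a length-0 train. Non-numeric content raises
    :class:`ParseError` with the line number; non-increasing timestamps
    raise :class:`ValidationError`.
    """
    path = Path(path)
    times = []
    for lineno, token in _numeric_lines(path):
        try:
            times.append(float(token))
        except ValueError:
            raise ParseError(f"non-numeric spike time {token!r}", line=lineno) from None
    return SpikeTrain(times=np.asarray(times, dtype=float), unit=unit)


def spike_times_to_isi(train: SpikeTrain) -> TimeSeries:
    """Convert spike times to the series of interspike intervals.

    ISI_i = t_{i+1} - t_i: the time elapsed between a spike and the next.
    Requires at least two spikes; returns a series of length ``len(train)-1``
    in the train's time unit.
    """
    if len(train) < 2:
        raise InsufficientDataError(
            f"need at least 2 spikes to form an ISI series, got {len(train)}"
        )
    return TimeSeries(values=np.diff(train.times), unit=train.unit, label="isi")


def read_series(path, unit: str = "", label: str = "") -> TimeSeries:
    """Read a single-column CSV time series; an optional header row is skipped."""
    path = Path(path)
    values = []
    first = True
    for lineno, token in _numeric_lines(path):
        token = token.split(",")[0].strip()
        try:
            values.append(float(token))
        except ValueError:
            if first:
                first = False
                continue  # header row
            raise ParseError(f"non-numeric value {token!r}", line=lineno) from None
        first = False
    return TimeSeries(values=np.asarray(values, dtype=float), unit=unit,
                      label=label or path.stem)


def write_series(series: TimeSeries, path, header: str | None = None) -> None:
    """Write a series as single-column CSV at full double precision.

    Values are printed with ``repr``-grade precision (17 significant
    digits) so a write/read round trip is bit-identical.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for v in series.values:
            fh.write(f"{v:.17g}\n")
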