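"""Temporal variables of a call sequence: durations, IOIs, IPIs and the
within-bout ("short") subsets.

Three series are derived from the retained calls: call *durations*,
*inter-onset intervals* (IOI — time between the onsets of consecutive
calls) and *inter-peak intervals* (IPI — time between the
maximum-intensity peaks of consecutive calls). Two further series isolate
timing *within* vocalization bouts: intervals no longer than ``k`` times
the series minimum (default ``k = 4``), which separates the short
within-bout spacing from the long between-bout gaps.

All series values are positive milliseconds, ordered as the generating
call pairs occur in time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .textgrid import CallAnnotation

__all__ = [
    "CallRecord",
    "IntervalSeries",
    "SERIES_KINDS",
    "CSV_FILENAMES",
    "durations",
    "inter_onset_intervals",
    "inter_peak_intervals",
    "short_threshold",
    "filter_short",
    "write_series_csv",
    "read_series_csv",
]

SERIES_KINDS = ("duration", "IOI", "IPI", "IOI_short", "IPI_short")

#: canonical output file per series kind
CSV_FILENAMES = {
    "duration": "durations_all.csv",
    "IOI": "IOI_all.csv",
    "IPI": "IPI_all.csv",
    "IOI_short": "IOI_short.csv",
    "IPI_short": "IPI_short.csv",
}

_SHORT_KIND = {"IOI": "IOI_short", "IPI": "IPI_short"}


@dataclass(frozen=True)
class CallRecord:
    """A retained call with its located maximum-intensity peak."""

    annotation: CallAnnotation
    peak_time: float
    peak_level: float

    def __post_init__(self) -> None:
        a = self.annotation
        if not a.onset <= self.peak_time < a.offset:
            raise ValueError(
                f"peak_time {self.peak_time} outside call "
                f"[{a.onset}, {a.offset})"
            )

    @property
    def onset(self) -> float:
        return self.annotation.onset

    @property
    def offset(self) -> float:
        return self.annotation.offset


@dataclass
class IntervalSeries:
    """Ordered positive interval values (milliseconds) of one kind."""

    kind: str
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.kind not in SERIES_KINDS:
            raise ValueError(f"kind must be one of {SERIES_KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if len(self.values) and self.values.min() <= 0:
            raise ValueError(f"{self.kind} values must be positive milliseconds")

    def __len__(self) -> int:
        return len(self.values)


def _check_sorted(calls: Sequence[CallRecord]) -> None:
    onsets = [c.onset for c in calls]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("calls must be sorted by onset")


def durations(calls: Sequence[CallRecord]) -> IntervalSeries:
    """Call durations (offset - onset) in ms, one per call."""
    _check_sorted(calls)
    vals = [(c.offset - c.onset) * 1000.0 for c in calls]
    return IntervalSeries("duration", np.array(vals))


def inter_onset_intervals(calls: Sequence[CallRecord]) -> IntervalSeries:
    """IOIs between consecutive retained calls; n_calls - 1 values."""
    _check_sorted(calls)
    onsets = np.array([c.onset for c in calls])
    diffs = np.diff(onsets) * 1000.0
    if len(diffs) and diffs.min() <= 0:
        raise ValueError("duplicate call onsets yield a non-positive IOI")
    return IntervalSeries("IOI", diffs)


def inter_peak_intervals(calls: Sequence[CallRecord]) -> IntervalSeries:
    """IPIs between maximum-intensity peaks of consecutive calls."""
    _check_sorted(calls)
    peaks = np.array([c.peak_time for c in calls])
    diffs = np.diff(peaks) * 1000.0
    if len(diffs) and diffs.min() <= 0:
        raise ValueError("non-increasing consecutive peak times")
    return IntervalSeries("IPI", diffs)


def short_threshold(s: IntervalSeries, k: float = 4.0) -> float:
    """Within-bout cutoff: ``k`` times the series minimum, in ms."""
    if len(s) == 0:
        raise ValueError("cannot take a threshold from an empty series")
    if k <= 0:
        raise ValueError("k must be positive")
    return float(k * s.values.min())


def filter_short(
    s: IntervalSeries, threshold: float, *, inclusive: bool = True
) -> IntervalSeries:
    """Keep intervals within the bout threshold (``v <= threshold``).

    Order is preserved; the output kind maps IOI -> IOI_short and
    IPI -> IPI_short. ``inclusive=False`` switches to a strict ``<``
    boundary.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kind = _SHORT_KIND.get(s.kind)
    if kind is None:
        raise ValueError(f"cannot take short subset of kind {s.kind!r}")
    keep = s.values <= threshold if inclusive else s.values < threshold
    return IntervalSeries(kind, s.values[keep])


# ---------------------------------------------------------------------------
# CSV I/O — one value column in ms, header row names the series kind


def write_series_csv(
    s: IntervalSeries, path: str | Path, *, decimals: int = 1
) -> None:
    """Write one series as a single-column CSV, values rounded to 0.1 ms."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([s.kind])
        for v in s.values:
            writer.writerow([f"{v:.{decimals}f}"])


def read_series_csv(path: str | Path, kind: str | None = None) -> IntervalSeries:
    """Read a single-column interval CSV.

    The header row gives the series kind unless ``kind`` overrides it (so
    externally deposited files with arbitrary headers remain readable).
    Non-numeric data cells raise with their row number.
    """
    with open(path, newline="", encoding="utf-8-sig") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError(f"{path}: empty CSV")
    header = rows[0][0].strip()
    try:
        float(header)
    except ValueError:
        data_rows = rows[1:]
        if kind is None and header in SERIES_KINDS:
            kind = header
    else:
        data_rows = rows  # headerless file: all rows are data
    if kind is None:
        kind = "IOI"
    values = []
    for i, row in enumerate(data_rows, start=2 if data_rows is not rows else 1):
        try:
            values.append(float(row[0]))
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric value {row[0]!r} at row {i}"
            ) from None
    return IntervalSeries(kind, np.array(values))
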