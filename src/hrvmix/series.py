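"""Heartbeat point processes, RR intervals and beats-per-minute series.

The heartbeat sequence is treated as an unmarked point process: each QRS
complex is reduced to the time of its R-wave peak.  Successive differences of
those event times are the RR (interbeat) intervals, and ``60 / RR`` converts
an interval in seconds to an instantaneous rate in beats per minute (bpm).
These three representations — :class:`BeatEventSeries`, :class:`RRSeries`,
:class:`HeartRateSeries` — are the inputs to the mixture and spectral
analyses.

All internal times are in seconds and rates in bpm.  The time stamp attached
to an RR interval (and to the bpm sample derived from it) is the *onset* of
the interval, i.e. the earlier of the two beats that bound it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import numpy.typing as npt

__all__ = [
    "BeatEventSeries",
    "RRSeries",
    "HeartRateSeries",
    "LaggedHistogram",
    "beats_to_rr",
    "rr_to_bpm",
    "read_series",
    "write_series",
    "filter_artifacts",
    "lagged_histogram",
]

logger = logging.getLogger(__name__)

# Physiological plausibility window for a single RR interval, seconds.
# 0.2 s = 300 bpm (above any sinus rate), 4.0 s = 15 bpm (extreme pause).
ARTIFACT_RR_BOUNDS = (0.2, 4.0)


def _as_float_array(x) -> npt.NDArray[np.float64]:
    return np.asarray(x, dtype=np.float64)


@dataclass(frozen=True)
class BeatEventSeries:
    """Strictly increasing heartbeat (R-peak) times in seconds from record start."""

    times: npt.NDArray[np.float64]

    def __post_init__(self):
        times = _as_float_array(self.times)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("beat times must be one-dimensional")
        if times.size and times[0] < 0:
            raise ValueError("beat times must be non-negative")
        diffs = np.diff(times)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            raise ValueError(
                f"beat times must be strictly increasing; first violation at index {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


@dataclass(frozen=True)
class RRSeries:
    """Interbeat (RR) intervals in seconds, optionally with their onset times."""

    intervals: npt.NDArray[np.float64]
    onsets: Optional[npt.NDArray[np.float64]] = None

    def __post_init__(self):
        intervals = _as_float_array(self.intervals)
        object.__setattr__(self, "intervals", intervals)
        if intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        bad = np.flatnonzero(intervals <= 0)
        if bad.size:
            raise ValueError(f"RR intervals must be positive; first violation at index {bad[0]}")
        if self.onsets is not None:
            onsets = _as_float_array(self.onsets)
            object.__setattr__(self, "onsets", onsets)
            if onsets.shape != intervals.shape:
                raise ValueError("onsets and intervals must have equal length")

    def __len__(self) -> int:
        return self.intervals.size

    def onset_times(self) -> npt.NDArray[np.float64]:
        """Onset time of each interval; reconstructed by cumulative sum if absent."""
        if self.onsets is not None:
            return self.onsets
        return np.concatenate([[0.0], np.cumsum(self.intervals[:-1])])


@dataclass(frozen=True)
class HeartRateSeries:
    """Instantaneous heart rate samples (bpm) at strictly increasing times (s)."""

    times: npt.NDArray[np.float64]
    values: npt.NDArray[np.float64]

    def __post_init__(self):
        times = _as_float_array(self.times)
        values = _as_float_array(self.values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be one-dimensional and of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values <= 0):
            raise ValueError("heart rate values must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


@dataclass(frozen=True)
class LaggedHistogram:
    """Bivariate histogram of (y_i, y_{i+lag}) pairs on a shared square bin grid.

    Approximates the joint density of the series and its lagged copy; ridges
    off the diagonal reveal multimodal structure that a single global model
    cannot capture.
    """

    bin_edges: npt.NDArray[np.float64]
    counts: npt.NDArray[np.int64]
    lag: int

    def __post_init__(self):
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("count matrix must be square")
        if self.counts.shape[0] != self.bin_edges.size - 1:
            raise ValueError("bin grid and count matrix are inconsistent")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginal(self, axis: int = 0) -> npt.NDArray[np.int64]:
        """1-D histogram of the leading (axis=0) or lagged (axis=1) subsequence."""
        return self.counts.sum(axis=1 - axis)


def beats_to_rr(beats: BeatEventSeries) -> RRSeries:
    """Successive differences of beat times; onset of interval i is beat time i."""
    if len(beats) < 2:
        raise ValueError("need at least two beat times to form RR intervals")
    return RRSeries(intervals=np.diff(beats.times), onsets=beats.times[:-1])


def rr_to_bpm(rr: RRSeries) -> HeartRateSeries:
    """Convert RR intervals (s) to instantaneous rate: bpm[i] = 60 / RR[i]."""
    return HeartRateSeries(times=rr.onset_times(), values=60.0 / rr.intervals)


def filter_artifacts(
    rr: RRSeries, bounds: tuple[float, float] = ARTIFACT_RR_BOUNDS
) -> tuple[RRSeries, int]:
    """Drop physiologically implausible RR intervals (outside ``bounds`` seconds).

    Returns the filtered series and the number of intervals removed.  Off by
    default in every pipeline; ectopy screening in the source protocol was
    manual, so this is a coarse guard only.
    """
    lo, hi = bounds
    keep = (rr.intervals >= lo) & (rr.intervals <= hi)
    removed = int((~keep).sum())
    if removed:
        logger.info("artifact filter removed %d of %d intervals", removed, len(rr))
    onsets = rr.onsets[keep] if rr.onsets is not None else None
    return RRSeries(intervals=rr.intervals[keep], onsets=onsets), removed


def read_series(
    path: Union[str, Path],
    kind: Literal["beats", "rr"],
    units: Literal["s", "ms"] = "s",
) -> Union[BeatEventSeries, RRSeries]:
    """Read a plain-text series: one value per line, ``#`` comments, blank lines ok.

    ``kind='beats'`` yields cumulative event times, ``kind='rr'`` interbeat
    intervals.  Values are converted from ``units`` to seconds.  No unit
    autodetection is attempted: silent misparsing is worse than one flag.
    """
    path = Path(path)
    if kind not in ("beats", "rr"):
        raise ValueError(f"unknown series kind {kind!r}")
    if units not in ("s", "ms"):
        raise ValueError(f"units must be 's' or 'ms', got {units!r}")
    scale = 1.0 if units == "s" else 1e-3
    values = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse {line!r} as a number") from exc
    if not values:
        raise ValueError(f"{path}: no data lines found")
    arr = np.array(values) * scale
    if kind == "beats":
        return BeatEventSeries(times=arr)
    return RRSeries(intervals=arr)


def write_series(
    series: Union[BeatEventSeries, RRSeries],
    path: Union[str, Path],
    units: Literal["s", "ms"] = "s",
    header: Optional[str] = None,
) -> None:
    """Write beat times or RR intervals in the plain-text one-value-per-line format."""
    scale = 1.0 if units == "s" else 1e3
    values = series.times if isinstance(series, BeatEventSeries) else series.intervals
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for v in values * scale:
            fh.write(f"{v:.9f}\n")


def lagged_histogram(hr: HeartRateSeries, lag: int = 1, n_bins: int = 40) -> LaggedHistogram:
    """Bivariate histogram of (value[i], value[i+lag]) on a shared bin grid.

    The grid spans the full data range on both axes, so either marginal is the
    ordinary 1-D histogram of the corresponding subsequence and the total
    count is exactly N - lag.
    """
    n = len(hr)
    if lag < 1:
        raise ValueError("lag must be at least 1")
    if lag >= n:
        raise ValueError(f"lag {lag} must be smaller than series length {n}")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    v = hr.values
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:  # constant series: widen so the single value falls in one cell
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _, _ = np.histogram2d(v[:-lag], v[lag:], bins=[edges, edges])
    return LaggedHistogram(bin_edges=edges, counts=counts.astype(np.int64), lag=lag)
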