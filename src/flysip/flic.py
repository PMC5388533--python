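"""Feeding-contact event detection in FLIC sensor traces.

The Fly Liquid-Food Interaction Counter (FLIC) records, per well, a
capacitive signal that rises while the fly touches the liquid food.
This module turns such raw traces into discrete feeding-contact events:
a slowly drifting baseline is removed with a running median, samples
above a threshold (absolute, or a multiple of the robust noise scale)
are segmented into maximal supra-threshold runs, nearby runs are merged
and too-short runs dropped.  Detections can be validated against a list
of ground-truth contact intervals by greedy one-to-one interval
matching, yielding a detection rate and a false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import FormatError, ParameterError

__all__ = [
    "FlicTrace",
    "GroundTruth",
    "DetectionParams",
    "FeedingEvent",
    "FlySummary",
    "ValidationReport",
    "read_flic_csv",
    "write_flic_csv",
    "estimate_baseline",
    "detect_events",
    "summarize",
    "validate",
    "write_events_csv",
    "read_events_csv",
]


@dataclass(frozen=True)
class FlicTrace:
    """One well's sensor signal over a recording window.

    ``time_s`` must be strictly increasing and the same length as
    ``signal``; neither may contain non-finite values.
    """

    well_id: str
    time_s: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ParameterError("time_s and signal must be 1-d arrays of equal length")
        if t.size and not np.all(np.isfinite(t)) or not np.all(np.isfinite(s)):
            raise ParameterError("time_s/signal contain non-finite values")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ParameterError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def fs_hz(self) -> float:
        """Sampling rate estimated from the median inter-sample interval."""
        if len(self) < 2:
            raise ParameterError("trace too short to estimate a sampling rate")
        return 1.0 / float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class GroundTruth:
    """True contact intervals for one trace, as an (n, 2) array of [start_s, end_s)."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size and np.any(iv[:, 0] >= iv[:, 1]):
            raise ParameterError("ground-truth intervals must have start < end")
        iv = iv[np.argsort(iv[:, 0])] if iv.size else iv
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter([(float(a), float(b)) for a, b in self.intervals])


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings.

    Exactly one of ``threshold`` (absolute, a.u. above baseline) or
    ``threshold_mads`` (multiple of the scaled median absolute deviation
    of the baseline-subtracted residual) must be set.  ``merge_gap_s``
    bridges sub-sample dropouts within one contact; at the common 5 Hz
    sampling the 0.2 s default spans a single sample, so distinct bouts
    separated by two or more samples are never fused.
    """

    baseline_window_s: float = 120.0
    threshold: float | None = None
    threshold_mads: float | None = 6.0
    min_event_duration_s: float = 0.4
    merge_gap_s: float = 0.2
    match_tolerance_s: float = 0.5

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.threshold_mads is None):
            raise ParameterError(
                "exactly one of threshold / threshold_mads must be set"
            )
        for name in (
            "baseline_window_s",
            "min_event_duration_s",
            "merge_gap_s",
            "match_tolerance_s",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.threshold is not None and self.threshold <= 0:
            raise ParameterError("threshold must be positive")
        if self.threshold_mads is not None and self.threshold_mads <= 0:
            raise ParameterError("threshold_mads must be positive")

    def with_threshold(self, value: float) -> "DetectionParams":
        return replace(self, threshold=value, threshold_mads=None)


@dataclass(frozen=True)
class FeedingEvent:
    """One detected feeding contact: a maximal supra-threshold interval."""

    start_s: float
    end_s: float
    peak_amplitude: float

    def __post_init__(self) -> None:
        if self.start_s >= self.end_s:
            raise ParameterError("event start must precede end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FlySummary:
    """Per-fly contact statistics over an analysis window (cf. total contact
    time, contacts per fly, and time per contact in free-feeding assays)."""

    well_id: str
    n_contacts: int
    total_contact_time_s: float
    mean_contact_duration_s: float


@dataclass(frozen=True)
class ValidationReport:
    n_true: int
    n_detected: int
    n_matched: int
    detection_rate: float
    false_positive_rate: float


# ---------------------------------------------------------------------------
# I/O


def read_flic_csv(path: str | Path) -> list[FlicTrace]:
    """Read a wide-format FLIC CSV: a ``time_s`` column then one column per well.

    Lines beginning with ``#`` are treated as comments.  Raises
    :class:`FormatError` for a missing time column, non-numeric cells, or a
    non-increasing time axis (citing the offending data row, 1-based).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one well column")
    tcol = df.columns[0]
    if tcol.strip().lower() not in {"time_s", "time", "t_s"}:
        raise FormatError(f"{path}: first column must be time_s, got {tcol!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 1
            raise FormatError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    t = df[tcol].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FormatError(f"{path}: time not strictly increasing at data row {bad[0] + 2}")
    return [
        FlicTrace(well_id=str(col), time_s=t, signal=df[col].to_numpy(dtype=float))
        for col in df.columns[1:]
    ]


def write_flic_csv(path: str | Path, traces: Sequence[FlicTrace], *, seed: int | None = None) -> None:
    """Write traces sharing a time axis as a wide CSV (optionally recording the seed)."""
    if not traces:
        raise ParameterError("no traces to write")
    t0 = traces[0].time_s
    for tr in traces[1:]:
        if not np.array_equal(tr.time_s, t0):
            raise ParameterError("traces must share a time axis for wide-format output")
    df = pd.DataFrame({"time_s": t0})
    for tr in traces:
        df[tr.well_id] = tr.signal
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def write_events_csv(path: str | Path, events_by_well: dict[str, Sequence[FeedingEvent]]) -> None:
    rows = [
        {
            "well_id": well,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "duration_s": ev.duration_s,
            "peak_amplitude": ev.peak_amplitude,
        }
        for well, events in events_by_well.items()
        for ev in events
    ]
    pd.DataFrame(
        rows, columns=["well_id", "start_s", "end_s", "duration_s", "peak_amplitude"]
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> dict[str, list[FeedingEvent]]:
    df = pd.read_csv(path, comment="#")
    out: dict[str, list[FeedingEvent]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["well_id"]), []).append(
            FeedingEvent(
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                peak_amplitude=float(row.get("peak_amplitude", np.nan)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Detection


def estimate_baseline(trace: FlicTrace, params: DetectionParams) -> np.ndarray:
    """Running-median baseline with reflected edges.

    The window is ``baseline_window_s`` converted to an odd number of
    samples.  Medians are insensitive to brief supra-baseline contacts, so
    the estimate tracks slow drift without following feeding events.
    """
    n = len(trace)
    if n == 0:
        return np.empty(0)
    fs = trace.fs_hz
    w = int(round(params.baseline_window_s * fs))
    if w < 3:
        raise ParameterError("baseline_window_s must span at least 3 samples")
    if w > n:
        raise ParameterError("baseline_window_s longer than the trace")
    if w % 2 == 0:
        w += 1
    return median_filter(trace.signal, size=w, mode="reflect")


def _resolve_threshold(residual: np.ndarray, params: DetectionParams) -> float:
    if params.threshold is not None:
        return float(params.threshold)
    med = np.median(residual)
    mad = np.median(np.abs(residual - med))
    return float(params.threshold_mads * 1.4826 * mad)


def detect_events(trace: FlicTrace, params: DetectionParams | None = None) -> list[FeedingEvent]:
    """Segment a trace into feeding-contact events.

    Pipeline: subtract the running-median baseline; mark samples strictly
    above the threshold; take maximal supra-threshold runs as candidates;
    merge runs separated by gaps shorter than ``merge_gap_s``; drop events
    shorter than ``min_event_duration_s``.  Each sample represents the
    interval [t, t + 1/fs), so an event ends one sample interval after its
    last supra-threshold sample.  Returns events sorted by start,
    non-overlapping, with ``peak_amplitude`` the maximum baseline-subtracted
    signal within the event.
    """
    params = params or DetectionParams()
    if len(trace) == 0:
        return []
    residual = trace.signal - estimate_baseline(trace, params)
    thr = _resolve_threshold(residual, params)
    mask = residual > thr
    if not mask.any():
        return []
    # maximal runs of True
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0] - 1  # inclusive sample index
    t = trace.time_s
    dt = 1.0 / trace.fs_hz
    runs: list[list[int]] = [[int(a), int(b)] for a, b in zip(starts, ends)]
    merged: list[list[int]] = [runs[0]]
    for a, b in runs[1:]:
        if t[a] - (t[merged[-1][1]] + dt) < params.merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events = []
    for a, b in merged:
        start, end = float(t[a]), float(t[b] + dt)
        if end - start < params.min_event_duration_s:
            continue
        events.append(
            FeedingEvent(start_s=start, end_s=end, peak_amplitude=float(residual[a : b + 1].max()))
        )
    return events


def summarize(
    events: Sequence[FeedingEvent],
    window: tuple[float, float],
    well_id: str = "",
) -> FlySummary:
    """Count contacts and total contact time within an analysis window.

    Events are clipped at the window edges before durations are summed; an
    event must overlap the window by a positive amount to count.
    """
    start, end = window
    if start >= end:
        raise ParameterError("window must satisfy start < end")
    durations = []
    for ev in events:
        lo, hi = max(ev.start_s, start), min(ev.end_s, end)
        if hi > lo:
            durations.append(hi - lo)
    n = len(durations)
    total = float(sum(durations))
    return FlySummary(
        well_id=well_id,
        n_contacts=n,
        total_contact_time_s=total,
        mean_contact_duration_s=total / n if n else 0.0,
    )


def _as_intervals(obj: GroundTruth | Iterable) -> np.ndarray:
    if isinstance(obj, GroundTruth):
        return obj.intervals
    rows = []
    for item in obj:
        if isinstance(item, FeedingEvent):
            rows.append((item.start_s, item.end_s))
        else:
            a, b = item[0], item[1]
            rows.append((float(a), float(b)))
    iv = np.asarray(rows, dtype=float).reshape(-1, 2)
    return iv[np.argsort(iv[:, 0])] if iv.size else iv


def validate(
    detected: Sequence[FeedingEvent],
    truth: GroundTruth | Iterable,
    tol: float = 0.5,
) -> ValidationReport:
    """Match detections to ground truth one-to-one and score the detector.

    Both lists are walked in time order; a detection and a true interval
    match if they overlap or their boundary gap is at most ``tol`` seconds.
    When a pair does not match, the interval that ends earlier is advanced
    (earliest-first, deterministic).  Detection rate is matched/true;
    false-positive rate is unmatched detections over all detections.  Both
    ratios are defined as 0 on an empty denominator except that the
    detection rate of an empty truth set is 1 (nothing was missed).
    """
    if tol < 0:
        raise ParameterError("match tolerance must be non-negative")
    det = _as_intervals(detected)
    tru = _as_intervals(truth)
    i = j = matched = 0
    while i < tru.shape[0] and j < det.shape[0]:
        ts, te = tru[i]
        ds, de = det[j]
        gap = max(ts - de, ds - te)  # negative iff overlapping
        if gap <= tol:
            matched += 1
            i += 1
            j += 1
        elif te < de:
            i += 1
        else:
            j += 1
    n_true, n_det = tru.shape[0], det.shape[0]
    return ValidationReport(
        n_true=n_true,
        n_detected=n_det,
        n_matched=matched,
        detection_rate=matched / n_true if n_true else 1.0,
        false_positive_rate=(n_det - matched) / n_det if n_det else 0.0,
    )
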