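"""Binned ΔF/F analysis of ROI fluorescence time series.

Single-cell GCaMP recordings of pharyngeal taste neurons are acquired at
nominally one frame per second; frames taken while the preparation was
being refocused are flagged and excluded.  Baseline fluorescence F0 is
the mean of the 10 usable frames immediately preceding stimulus
delivery, and the response is summarized per 30-s bin as the maximum
fractional change (max F − F0)/F0 within the bin, counted from stimulus
application (bin 0 covers 0–29 s after delivery, bin 30 covers 30–59 s,
and so on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    InsufficientBaselineError,
    ParameterError,
)

__all__ = [
    "RoiTrace",
    "StimulusInfo",
    "BinnedResponse",
    "read_roi_csv",
    "write_roi_csv",
    "compute_f0",
    "bin_dff",
    "response_timecourse",
]

#: bins keeping fewer than this fraction of their nominal frames are flagged;
#: refocusing episodes are 5-10 s, well under a third of a 30-s bin.
MIN_USABLE_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class RoiTrace:
    """Per-frame mean ROI intensity with exclusion flags."""

    frame_index: np.ndarray
    time_s: np.ndarray
    intensity: np.ndarray
    excluded: np.ndarray

    def __post_init__(self) -> None:
        fi = np.asarray(self.frame_index, dtype=int)
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        ex = np.asarray(self.excluded, dtype=bool)
        if not (fi.shape == t.shape == f.shape == ex.shape) or t.ndim != 1:
            raise ParameterError("all RoiTrace fields must be 1-d arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ParameterError("time_s must be strictly increasing")
        if np.any(f < 0):
            raise DataError("intensity must be non-negative")
        for name, arr in (("frame_index", fi), ("time_s", t), ("intensity", f), ("excluded", ex)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def frame_interval_s(self) -> float:
        if len(self) < 2:
            raise ParameterError("trace too short to estimate a frame interval")
        return float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class StimulusInfo:
    """Stimulus delivery time and identity (e.g. '900 mM sucrose')."""

    onset_s: float
    label: str = ""


@dataclass(frozen=True)
class BinnedResponse:
    """Maximum ΔF/F in one post-stimulus bin.

    ``bin_start_s`` is relative to stimulus onset (0, 30, 60, ...).  ``dff``
    is NaN when the bin has no usable frame; ``low_coverage`` marks bins
    that kept fewer than the minimum usable-frame fraction.
    """

    bin_start_s: float
    dff: float
    n_frames_used: int
    low_coverage: bool = False


def read_roi_csv(path: str | Path) -> RoiTrace:
    """Read an ROI export with columns frame, time_s, intensity, excluded (0/1)."""
    df = pd.read_csv(path, comment="#")
    required = {"frame", "time_s", "intensity", "excluded"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing columns {sorted(missing)}")
    return RoiTrace(
        frame_index=df["frame"].to_numpy(dtype=int),
        time_s=df["time_s"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
        excluded=df["excluded"].to_numpy(dtype=int).astype(bool),
    )


def write_roi_csv(path: str | Path, trace: RoiTrace, *, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "frame": trace.frame_index,
            "time_s": trace.time_s,
            "intensity": trace.intensity,
            "excluded": trace.excluded.astype(int),
        }
    )
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def compute_f0(trace: RoiTrace, stim: StimulusInfo, n_baseline_frames: int = 10) -> float:
    """Baseline fluorescence: mean of the nearest usable frames before onset.

    Uses the ``n_baseline_frames`` non-excluded frames whose times are
    strictly before ``stim.onset_s``; when flagged frames fall in that
    window it slides earlier until enough usable frames are collected.
    """
    eligible = (trace.time_s < stim.onset_s) & ~trace.excluded
    idx = np.nonzero(eligible)[0]
    if idx.size < n_baseline_frames:
        raise InsufficientBaselineError(
            f"need {n_baseline_frames} usable pre-stimulus frames, have {idx.size}"
        )
    f0 = float(trace.intensity[idx[-n_baseline_frames:]].mean())
    if f0 <= 0:
        raise DataError("baseline fluorescence must be positive")
    return f0


def bin_dff(
    trace: RoiTrace,
    stim: StimulusInfo,
    bin_width_s: float = 30.0,
    min_usable_fraction: float = MIN_USABLE_FRACTION,
) -> list[BinnedResponse]:
    """Per-bin maximum ΔF/F after stimulus onset.

    Bins are aligned to the stimulus application time and only complete
    bins (fully covered by the recording) are reported.  Excluded frames
    are dropped before taking the bin maximum; a bin with no usable frame
    reports ``dff=NaN`` and ``n_frames_used=0``.
    """
    if bin_width_s <= 0:
        raise ParameterError("bin_width_s must be positive")
    f0 = compute_f0(trace, stim)
    dt = trace.frame_interval_s
    span = trace.time_s[-1] + dt - stim.onset_s
    n_bins = int(math.floor(span / bin_width_s + 1e-9))
    nominal = max(1, int(round(bin_width_s / dt)))
    out = []
    for k in range(n_bins):
        lo = stim.onset_s + k * bin_width_s
        hi = lo + bin_width_s
        in_bin = (trace.time_s >= lo) & (trace.time_s < hi) & ~trace.excluded
        n_used = int(in_bin.sum())
        dff = (
            float((trace.intensity[in_bin].max() - f0) / f0) if n_used else float("nan")
        )
        out.append(
            BinnedResponse(
                bin_start_s=k * bin_width_s,
                dff=dff,
                n_frames_used=n_used,
                low_coverage=n_used < min_usable_fraction * nominal,
            )
        )
    return out


def response_timecourse(
    responses: Sequence[Sequence[BinnedResponse]],
) -> pd.DataFrame:
    """Aggregate per-fly binned responses into a group time course.

    Returns a table with columns ``bin_start_s``, ``mean_dff``, ``sem_dff``
    and ``n`` (flies contributing a finite ΔF/F to the bin).  All flies must
    be binned at the same width; missing bins are simply absent from that
    fly's contribution.
    """
    if not responses:
        raise ParameterError("no responses to aggregate")
    widths = set()
    rows = []
    for fly_idx, bins in enumerate(responses):
        starts = sorted(b.bin_start_s for b in bins)
        widths.update(round(b - a, 9) for a, b in zip(starts, starts[1:]))
        for b in bins:
            rows.append({"fly": fly_idx, "bin_start_s": b.bin_start_s, "dff": b.dff})
    if len(widths) > 1:
        raise ParameterError(f"mixed bin widths across flies: {sorted(widths)}")
    df = pd.DataFrame(rows).dropna(subset=["dff"])
    grouped = df.groupby("bin_start_s")["dff"]
    out = grouped.agg(mean_dff="mean", n="count")
    out["sem_dff"] = grouped.sem()
    return out.reset_index()[["bin_start_s", "mean_dff", "sem_dff", "n"]]
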