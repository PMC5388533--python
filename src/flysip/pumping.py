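"""Bookkeeping for the immobilized-fly pharyngeal pumping assay.

Each session records one starved fly offered liquid food: a water
pre-test (flies drinking water for more than 10 s are discarded as
over-desiccated), a sequence of up to four food presentations (a fly
initiating none of the first four is discarded as a non-responder), and
the accepted feeding bouts with their durations and manually scored
swallow counts.  Included sessions yield total feeding time, total
swallows, and the pumping (swallowing) rate; pooled cohorts support the
swallow-count-versus-feeding-time correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateFitError, ParameterError, UsageError

__all__ = [
    "ExclusionReason",
    "SessionRecord",
    "SessionSummary",
    "apply_inclusion_rules",
    "summarize_session",
    "summarize_cohort",
    "pooled_correlation",
    "read_sessions_csv",
    "write_sessions_csv",
]

#: water pre-test limit; strictly longer drinking excludes the fly
WATER_TEST_LIMIT_S = 10.0
#: number of failed presentations after which a fly is a non-responder
MAX_PRESENTATIONS = 4

_INITIATED = {"I", "Y", "1"}
_NOT_INITIATED = {"N", "0"}


class ExclusionReason(str, Enum):
    NONE = "none"
    WATER_OVER_10S = "water_over_10s"
    NON_RESPONDER = "non_responder"


@dataclass(frozen=True)
class SessionRecord:
    """One fly's pumping-assay session.

    ``presentations`` encodes the ordered presentation outcomes as a string
    of 'I' (initiated a bout) / 'N' (no response), e.g. ``"NIN"``.
    ``bouts`` lists (duration_s, swallow_count) for each accepted bout.
    """

    fly_id: str
    genotype: str
    stimulus: str
    water_test_s: float
    presentations: str
    bouts: tuple[tuple[float, int], ...] = ()

    def __post_init__(self) -> None:
        if self.water_test_s < 0:
            raise DataError(f"{self.fly_id}: negative water-test duration")
        if not self.presentations:
            raise DataError(f"{self.fly_id}: presentation list is empty")
        for ch in self.presentations.upper():
            if ch not in _INITIATED | _NOT_INITIATED:
                raise DataError(f"{self.fly_id}: bad presentation outcome {ch!r}")
        bouts = tuple((float(d), int(c)) for d, c in self.bouts)
        for d, c in bouts:
            if d <= 0:
                raise DataError(f"{self.fly_id}: bout duration must be positive")
            if c < 1:
                raise DataError(f"{self.fly_id}: accepted bouts must have ≥1 swallow")
        object.__setattr__(self, "bouts", bouts)

    def initiated_flags(self) -> list[bool]:
        return [ch in _INITIATED for ch in self.presentations.upper()]


@dataclass(frozen=True)
class SessionSummary:
    fly_id: str
    genotype: str
    included: bool
    exclusion_reason: ExclusionReason
    total_feeding_time_s: float | None
    total_swallows: int | None
    pumping_rate_hz: float | None


def apply_inclusion_rules(session: SessionRecord) -> tuple[bool, ExclusionReason]:
    """Decide whether a session enters analysis.

    Checks in chronological order: the water pre-test (strictly more than
    10 s of water drinking excludes the fly) and responsiveness (no bout
    initiated within the first four presentations excludes it).
    """
    if session.water_test_s > WATER_TEST_LIMIT_S:
        return False, ExclusionReason.WATER_OVER_10S
    if not any(session.initiated_flags()[:MAX_PRESENTATIONS]):
        return False, ExclusionReason.NON_RESPONDER
    return True, ExclusionReason.NONE


def summarize_session(session: SessionRecord) -> SessionSummary:
    """Total feeding time, swallow count, and pumping rate for an included session."""
    included, reason = apply_inclusion_rules(session)
    if not included:
        raise UsageError(f"{session.fly_id}: session excluded ({reason.value})")
    if not session.bouts:
        raise UsageError(f"{session.fly_id}: included session has no bouts")
    total_time = sum(d for d, _ in session.bouts)
    total_swallows = sum(c for _, c in session.bouts)
    return SessionSummary(
        fly_id=session.fly_id,
        genotype=session.genotype,
        included=True,
        exclusion_reason=ExclusionReason.NONE,
        total_feeding_time_s=total_time,
        total_swallows=total_swallows,
        pumping_rate_hz=total_swallows / total_time,
    )


def summarize_cohort(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    """Summarize every session; excluded flies keep their reason and NaN metrics."""
    rows = []
    for s in sessions:
        included, reason = apply_inclusion_rules(s)
        if included and s.bouts:
            summ = summarize_session(s)
            rows.append(
                {
                    "fly_id": summ.fly_id,
                    "genotype": summ.genotype,
                    "included": True,
                    "exclusion_reason": ExclusionReason.NONE.value,
                    "total_feeding_time_s": summ.total_feeding_time_s,
                    "total_swallows": summ.total_swallows,
                    "pumping_rate_hz": summ.pumping_rate_hz,
                }
            )
        else:
            rows.append(
                {
                    "fly_id": s.fly_id,
                    "genotype": s.genotype,
                    "included": False,
                    "exclusion_reason": reason.value,
                    "total_feeding_time_s": np.nan,
                    "total_swallows": np.nan,
                    "pumping_rate_hz": np.nan,
                }
            )
    return pd.DataFrame(rows)


def pooled_correlation(
    summaries: pd.DataFrame | Sequence[SessionSummary],
    x: str = "total_feeding_time_s",
    y: str = "total_swallows",
) -> tuple[float, int]:
    """Squared Pearson correlation between two per-fly metrics, included flies only."""
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame(
            [
                {
                    "included": s.included,
                    "total_feeding_time_s": s.total_feeding_time_s,
                    "total_swallows": s.total_swallows,
                    "pumping_rate_hz": s.pumping_rate_hz,
                }
                for s in summaries
            ]
        )
    sub = df[df["included"]].dropna(subset=[x, y])
    if len(sub) < 3:
        raise ParameterError("pooled correlation needs at least 3 included flies")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateFitError("zero variance in pooled correlation input")
    r, _ = stats.pearsonr(xv, yv)
    return float(r**2), int(len(sub))


# ---------------------------------------------------------------------------
# I/O: tidy long format, one row per bout (bout fields empty for boutless flies)


def write_sessions_csv(path: str | Path, sessions: Sequence[SessionRecord]) -> None:
    rows = []
    for s in sessions:
        meta = {
            "fly_id": s.fly_id,
            "genotype": s.genotype,
            "stimulus": s.stimulus,
            "water_test_s": s.water_test_s,
            "presentations": s.presentations,
        }
        if s.bouts:
            for i, (d, c) in enumerate(s.bouts):
                rows.append({**meta, "bout_index": i, "bout_duration_s": d, "swallow_count": c})
        else:
            rows.append({**meta, "bout_index": np.nan, "bout_duration_s": np.nan, "swallow_count": np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sessions_csv(path: str | Path) -> list[SessionRecord]:
    df = pd.read_csv(path, comment="#", dtype={"presentations": str})
    sessions = []
    for fly_id, grp in df.groupby("fly_id", sort=False):
        first = grp.iloc[0]
        bouts = [
            (float(r["bout_duration_s"]), int(r["swallow_count"]))
            for _, r in grp.iterrows()
            if pd.notna(r["bout_duration_s"])
        ]
        sessions.append(
            SessionRecord(
                fly_id=str(fly_id),
                genotype=str(first["genotype"]),
                stimulus=str(first["stimulus"]),
                water_test_s=float(first["water_test_s"]),
                presentations=str(first["presentations"]),
                bouts=tuple(bouts),
            )
        )
    return sessions
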