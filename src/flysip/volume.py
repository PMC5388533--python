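"""Dye-based quantification of ingested volume.

Erioglaucine blue dye added to liquid food absorbs at 630 nm; the OD630
of a fly extract therefore reports how much dyed food the fly ingested.
A standard line fitted through serial two-fold dilutions of the
reference dye solution converts OD into microliter-equivalents, after
subtracting the endogenous absorbance of extracts from flies fed
undyed food.  Ingestion rate is then estimated by ordinary least
squares regression of per-fly volume on total feeding time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, ParameterError

__all__ = [
    "DilutionStandard",
    "StandardCurve",
    "ExtractReading",
    "VolumeEstimate",
    "RateFit",
    "fit_standard_curve",
    "background_od",
    "od_to_volume",
    "fit_rate",
]


@dataclass(frozen=True)
class DilutionStandard:
    """A two-fold dilution series of the reference dye solution.

    ``levels`` are expressed in μl-equivalents of the undiluted reference
    (1.0, 0.5, 0.25, ...); ``replicate_ods`` holds the OD630 readings per
    level.  The bench protocol reads each level at least in triplicate;
    smaller replicate counts are accepted for re-analysis of partial data.
    """

    levels: np.ndarray
    replicate_ods: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        reps = tuple(np.asarray(r, dtype=float).ravel() for r in self.replicate_ods)
        if lv.ndim != 1 or lv.size != len(reps):
            raise ParameterError("levels and replicate_ods must align one-to-one")
        if lv.size == 0:
            raise ParameterError("dilution standard is empty")
        if np.any(lv <= 0):
            raise ParameterError("levels must be positive")
        ratios = lv[1:] / lv[:-1]
        if ratios.size and not np.allclose(ratios, 0.5, rtol=1e-3):
            raise ParameterError("levels must decrease strictly by factor 2")
        for i, r in enumerate(reps):
            if r.size < 1:
                raise ParameterError(f"level {lv[i]} has no OD replicate")
            if np.any(r < 0):
                raise ParameterError("OD readings must be non-negative")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "replicate_ods", reps)

    @property
    def mean_ods(self) -> np.ndarray:
        return np.array([r.mean() for r in self.replicate_ods])


@dataclass(frozen=True)
class StandardCurve:
    """Through-origin calibration line: OD = slope × μl-equivalents."""

    slope: float
    fit_residual: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ParameterError("standard-curve slope must be positive")


@dataclass(frozen=True)
class ExtractReading:
    """Replicate OD630 readings of one fly extract (protocol: n ≥ 4 per fly)."""

    fly_id: str
    replicate_ods: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.replicate_ods, dtype=float).ravel()
        if r.size == 0:
            raise ParameterError("reading has no OD replicate")
        if np.any(r < 0):
            raise ParameterError("OD readings must be non-negative")
        object.__setattr__(self, "replicate_ods", r)

    @property
    def mean_od(self) -> float:
        return float(self.replicate_ods.mean())


@dataclass(frozen=True)
class VolumeEstimate:
    fly_id: str
    volume_ul: float
    below_background: bool = False

    @property
    def volume_nl(self) -> float:
        return self.volume_ul * 1000.0


@dataclass(frozen=True)
class RateFit:
    """Ingestion-rate regression: volume (nl) against feeding time (s)."""

    slope_nl_per_s: float
    intercept_nl: float
    r_squared: float
    n: int


def fit_standard_curve(standard: DilutionStandard) -> StandardCurve:
    """Least-squares slope of mean OD versus level, constrained through the origin.

    The conversion uses the slope alone, so an intercept would be unused;
    ``fit_residual`` (RMS deviation of the mean ODs from the line) lets the
    through-origin choice be audited.
    """
    x = standard.levels
    y = standard.mean_ods
    if np.all(y == 0):
        raise DegenerateFitError("all ODs are zero; no standard line can be fitted")
    slope = float(np.dot(x, y) / np.dot(x, x))
    residual = float(np.sqrt(np.mean((y - slope * x) ** 2)))
    return StandardCurve(slope=slope, fit_residual=residual)


def background_od(control_readings: Sequence[ExtractReading]) -> float:
    """Endogenous extract absorbance: mean OD of flies fed food without dye."""
    if not control_readings:
        raise ParameterError("at least one dye-free control fly is required")
    return float(np.mean([r.mean_od for r in control_readings]))


def od_to_volume(
    reading: ExtractReading, curve: StandardCurve, background: float
) -> VolumeEstimate:
    """Convert one fly's mean OD into an ingested volume (μl).

    volume = (mean OD − background)/slope, clamped at zero — a reading
    below the dye-free background is unphysical as a volume and is flagged
    rather than reported negative.
    """
    if curve.slope <= 0:
        raise ParameterError("standard-curve slope must be positive")
    raw = (reading.mean_od - background) / curve.slope
    return VolumeEstimate(
        fly_id=reading.fly_id,
        volume_ul=max(0.0, raw),
        below_background=raw < 0,
    )


def fit_rate(
    feeding_time_s: Sequence[float], volume_nl: Sequence[float]
) -> RateFit:
    """OLS regression of ingested volume (nl) on total feeding time (s)."""
    t = np.asarray(feeding_time_s, dtype=float)
    v = np.asarray(volume_nl, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ParameterError("feeding_time_s and volume_nl must align")
    if t.size < 3:
        raise ParameterError("rate fit needs at least 3 flies")
    if np.any(t <= 0):
        raise ParameterError("feeding times must be positive")
    if np.ptp(t) == 0:
        raise DegenerateFitError("feeding times have zero variance")
    res = stats.linregress(t, v)
    return RateFit(
        slope_nl_per_s=float(res.slope),
        intercept_nl=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(t.size),
    )
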