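"""Erythemal UVB dosimetry and minimum sun-exposure recommendations.

Hourly broadband UVB intensity (W/m²) is converted to a dose rate in
minimal erythema doses (MED) per hour: ``rate = intensity * 3600 /
med_threshold`` where ``med_threshold`` is the energy per unit area (J/m²)
defining 1 MED for the population's skin type.  Dose over an exposure
window is the piecewise-constant integral of the rate over the overlapped
hour bins, with partial hours weighted proportionally.

The MED threshold has no package default: published thresholds for the
relevant skin types are mutually inconsistent across unit conventions, so
dose computations require it explicitly.  Recommendation operations accept
a direct MED/hour rate instead (``med_rate_override``), which makes the
headline durations reproducible from a measured median rate without
settling the threshold units.

Hour bins are half-open ``[h, h+1)`` labelled by their start hour, local
time.  Hours absent from a series are treated as zero intensity (night
bins); strict mode raises on gaps instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "IntensityRecord",
    "IntensitySeries",
    "MedParameters",
    "RecommendationParameters",
    "DoseResult",
    "MissingDataError",
    "watt_to_med_rate",
    "accumulate_dose",
    "peak_window",
    "lowest_month",
    "time_to_one_med",
    "minimum_exposure_duration",
    "adjusted_duration_for_clothing",
]

DAYTIME_HOURS = range(6, 18)


class MissingDataError(LookupError):
    """A requested month or hour bin is absent from the intensity series."""


@dataclass(frozen=True)
class IntensityRecord:
    """Average UVB intensity (W/m²) for one (month, hour-bin) cell."""

    month: str
    hour_start: int
    intensity_w_m2: float

    def __post_init__(self) -> None:
        if not 0 <= self.hour_start <= 23:
            raise ValueError(f"hour_start must be in 0..23, got {self.hour_start}")
        if self.intensity_w_m2 < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity_w_m2}")


class IntensitySeries:
    """Hourly UVB intensity records for one or more months.

    At most one record per (month, hour-bin).  Lookups for hours without a
    record return 0 by default; with ``strict=True`` they raise
    :class:`MissingDataError` instead.
    """

    def __init__(self, records: Iterable[IntensityRecord], *, strict: bool = False):
        self._strict = strict
        self._cells: dict[tuple[str, int], float] = {}
        self._months: list[str] = []
        for rec in records:
            key = (rec.month, rec.hour_start)
            if key in self._cells:
                raise ValueError(f"duplicate record for {key}")
            self._cells[key] = rec.intensity_w_m2
            if rec.month not in self._months:
                self._months.append(rec.month)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, strict: bool = False) -> "IntensitySeries":
        """Build from a DataFrame with columns month, hour_start, intensity_w_m2."""
        records = [
            IntensityRecord(str(row.month), int(row.hour_start), float(row.intensity_w_m2))
            for row in frame.itertuples(index=False)
        ]
        return cls(records, strict=strict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"month": m, "hour_start": h, "intensity_w_m2": v}
            for (m, h), v in sorted(
                self._cells.items(), key=lambda kv: (self._months.index(kv[0][0]), kv[0][1])
            )
        ]
        return pd.DataFrame(rows, columns=["month", "hour_start", "intensity_w_m2"])

    @property
    def months(self) -> list[str]:
        """Months in first-appearance order."""
        return list(self._months)

    def intensity(self, month: str, hour_start: int) -> float:
        """Intensity (W/m²) of the ``[hour_start, hour_start+1)`` bin."""
        if month not in self._months:
            raise MissingDataError(f"month {month!r} absent from series")
        try:
            return self._cells[(month, hour_start)]
        except KeyError:
            if self._strict:
                raise MissingDataError(
                    f"no record for month {month!r} hour {hour_start}"
                ) from None
            return 0.0

    def hourly_intensities(self, month: str) -> list[float]:
        """The 24 hourly intensities for a month (gaps zero-filled)."""
        if month not in self._months:
            raise MissingDataError(f"month {month!r} absent from series")
        return [self.intensity(month, h) for h in range(24)]

    def scaled(self, factor: float) -> "IntensitySeries":
        """A copy with every intensity multiplied by ``factor`` (>= 0)."""
        return IntensitySeries(
            [
                IntensityRecord(m, h, v * factor)
                for (m, h), v in self._cells.items()
            ],
            strict=self._strict,
        )


@dataclass(frozen=True)
class MedParameters:
    """Energy per unit area (J/m²) defining 1 MED, with a provenance note."""

    med_threshold_j_m2: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.med_threshold_j_m2 > 0:
            raise ValueError(
                f"med_threshold_j_m2 must be > 0, got {self.med_threshold_j_m2}"
            )


@dataclass(frozen=True)
class RecommendationParameters:
    """Parameters of the minimum-duration recommendation.

    holick_fraction
        Fraction of the time-to-1-MED considered sufficient for adequate
        vitamin D synthesis when the reference area is exposed (default 0.25).
    reference_percentage
        Reference exposed area as % of TBSA — face plus both arms with
        hands, 22.5 by default.
    time_rounding
        ``half-hour-down`` floors time-to-1-MED to a 30-minute multiple
        before applying the fraction (reproduces the conventional
        "2.5 hours" reading of a 0.39 MED/h median); ``none`` keeps it exact.
    med_rate_override
        Optional direct dose rate (MED/hour) to use instead of converting
        intensities through a MED threshold.
    """

    holick_fraction: float = 0.25
    reference_percentage: float = 22.5
    time_rounding: Literal["none", "half-hour-down"] = "half-hour-down"
    med_rate_override: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.holick_fraction <= 1:
            raise ValueError(
                f"holick_fraction must be in (0, 1], got {self.holick_fraction}"
            )
        if not 0 < self.reference_percentage <= 100:
            raise ValueError(
                f"reference_percentage must be in (0, 100], got {self.reference_percentage}"
            )
        if self.time_rounding not in ("none", "half-hour-down"):
            raise ValueError(f"unknown time_rounding {self.time_rounding!r}")


@dataclass(frozen=True)
class DoseResult:
    """Accumulated dose (MED) over a clock-time window."""

    dose_med: float
    window: tuple[float, float]
    mean_rate_med_per_hour: float


def watt_to_med_rate(intensity_w_m2: float, params: MedParameters) -> float:
    """Convert UVB intensity (W/m²) to a dose rate in MED/hour.

    Linear in intensity: ``intensity × 3600 / med_threshold``.
    """
    if intensity_w_m2 < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity_w_m2}")
    return intensity_w_m2 * 3600.0 / params.med_threshold_j_m2


def accumulate_dose(
    series: IntensitySeries,
    month: str,
    start_hour: float,
    end_hour: float,
    params: MedParameters,
) -> DoseResult:
    """Dose (MED) accumulated between two clock times on a day of ``month``.

    Piecewise-constant integration over hour bins: each overlapped bin
    contributes its MED/hour rate times the overlap duration in hours.
    ``start_hour``/``end_hour`` are decimal hours in [0, 24] with
    start <= end.
    """
    if not (0 <= start_hour <= end_hour <= 24):
        raise ValueError(
            f"window must satisfy 0 <= start <= end <= 24, got ({start_hour}, {end_hour})"
        )
    if month not in series.months:
        raise MissingDataError(f"month {month!r} absent from series")
    dose = 0.0
    for h in range(int(math.floor(start_hour)), int(math.ceil(end_hour))):
        overlap = min(end_hour, h + 1) - max(start_hour, h)
        if overlap <= 0:
            continue
        rate = watt_to_med_rate(series.intensity(month, h), params)
        dose += rate * overlap
    width = end_hour - start_hour
    mean_rate = dose / width if width > 0 else 0.0
    return DoseResult(dose_med=dose, window=(start_hour, end_hour), mean_rate_med_per_hour=mean_rate)


def peak_window(
    series: IntensitySeries, month: str, width_hours: int
) -> tuple[int, int]:
    """The contiguous ``width_hours``-hour window maximizing summed intensity.

    Ties are broken by earliest start.  Returns (start_hour, end_hour).
    """
    if not 1 <= width_hours <= 24:
        raise ValueError(f"width_hours must be in 1..24, got {width_hours}")
    hourly = series.hourly_intensities(month)
    best_start, best_sum = 0, -math.inf
    for start in range(0, 24 - width_hours + 1):
        total = sum(hourly[start : start + width_hours])
        if total > best_sum:  # strict: earliest start wins ties
            best_start, best_sum = start, total
    return best_start, best_start + width_hours


def lowest_month(series: IntensitySeries) -> str:
    """The month with the lowest mean daytime (06:00–18:00) intensity."""
    months = series.months
    if not months:
        raise MissingDataError("intensity series is empty")
    means = {
        m: sum(series.intensity(m, h) for h in DAYTIME_HOURS) / len(DAYTIME_HOURS)
        for m in months
    }
    return min(months, key=lambda m: means[m])


def _floor_to_half_hour(minutes: float) -> float:
    return 30.0 * math.floor(minutes / 30.0)


def time_to_one_med(
    rate_med_per_hour: float,
    rounding: Literal["none", "half-hour-down"] = "half-hour-down",
) -> float:
    """Minutes of exposure needed to accumulate 1 MED at a constant rate.

    ``60 / rate``; under half-hour-down rounding the result is floored to
    the nearest 30-minute multiple (so a 0.39 MED/h rate reads as 150 min,
    i.e. two and a half hours).
    """
    if not rate_med_per_hour > 0:
        raise ValueError(f"rate must be > 0, got {rate_med_per_hour}")
    minutes = 60.0 / rate_med_per_hour
    if rounding == "half-hour-down":
        return _floor_to_half_hour(minutes)
    if rounding == "none":
        return minutes
    raise ValueError(f"unknown rounding {rounding!r}")


def minimum_exposure_duration(
    rate_med_per_hour: float, params: RecommendationParameters | None = None
) -> float:
    """Minimum daily sun-exposure duration (minutes) at the reference area.

    The time to reach 1 MED at the given rate (rounded per the configured
    convention) scaled by the Holick fraction.  At the cohort-median rate of
    0.39 MED/h with defaults this is 150 × 0.25 = 37.5 minutes.
    """
    if params is None:
        params = RecommendationParameters()
    return time_to_one_med(rate_med_per_hour, params.time_rounding) * params.holick_fraction


def adjusted_duration_for_clothing(
    base_minutes: float,
    exposed_percentage: float,
    params: RecommendationParameters | None = None,
) -> float:
    """Scale a reference-area duration to a clothing ensemble's exposed area.

    Duration × reference% / exposed% — exposing less skin requires
    proportionally longer exposure to accumulate the same dose over the
    reference area.  Strictly decreasing in the exposed percentage.
    """
    if params is None:
        params = RecommendationParameters()
    if not exposed_percentage > 0:
        raise ValueError(f"exposed_percentage must be > 0, got {exposed_percentage}")
    return base_minutes * params.reference_percentage / exposed_percentage
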