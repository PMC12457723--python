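"""Reproduction-peak timing conventions.

Literature sources report the reproduction peak as a month, so timing
is coded as an approximate Julian day (+/- 15): the day-of-year of the
15th of the month on a 366-day (leap) calendar.  Autumn peaks (the
southern distribution edge reproduces in late autumn) are mapped to
negative values by subtracting 366, which keeps the latitude-timing
relationship a single monotone line instead of wrapping at New Year.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

__all__ = ["PhenologyRecord", "month_to_julian_day", "build_phenology_record"]

#: Months mapped to negative days under the autumn-negative policy.
AUTUMN_WRAP_FROM = 10
_LEAP_YEAR = 2024  # any leap year gives the same day-of-year table
_DAYS_IN_LEAP_YEAR = 366


@dataclass(frozen=True)
class PhenologyRecord:
    region_id: str
    latitude: float  # degrees N
    sst_mean: float | None  # deg C
    peak_month: int | None  # 1-12 when the source reported a month
    peak_jd: int  # approximate Julian day (+/- 15), may be negative


def month_to_julian_day(month: int, wrap_policy: str = "autumn-negative") -> int:
    """Approximate Julian day of a reproduction peak in ``month``.

    The 15th of the month is taken as the peak day on a leap (366-day)
    calendar; under ``"autumn-negative"`` (the default), months from
    October onwards map to day-of-year minus 366.  ``"none"`` returns
    the plain day-of-year.
    """
    if not isinstance(month, int) or not 1 <= month <= 12:
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    if wrap_policy not in ("autumn-negative", "none"):
        raise ValueError(f"unknown wrap_policy {wrap_policy!r}")
    doy = _dt.date(_LEAP_YEAR, month, 15).timetuple().tm_yday
    if wrap_policy == "autumn-negative" and month >= AUTUMN_WRAP_FROM:
        return doy - _DAYS_IN_LEAP_YEAR
    return doy


def build_phenology_record(
    region_id: str,
    latitude: float,
    sst_mean: float | None = None,
    peak_month: int | None = None,
    peak_jd: int | None = None,
    wrap_policy: str = "autumn-negative",
) -> PhenologyRecord:
    """Normalize a peak specifier (month or explicit Julian day).

    Exactly one of ``peak_month`` / ``peak_jd`` must be given; explicit
    Julian days pass through unchanged.
    """
    if (peak_month is None) == (peak_jd is None):
        raise ValueError("supply exactly one of peak_month or peak_jd")
    if peak_jd is None:
        peak_jd = month_to_julian_day(peak_month, wrap_policy)
    else:
        if not -122 <= peak_jd <= 366:
            raise ValueError(f"peak_jd {peak_jd} outside [-122, 366]")
    return PhenologyRecord(
        region_id=region_id,
        latitude=latitude,
        sst_mean=sst_mean,
        peak_month=peak_month,
        peak_jd=int(peak_jd),
    )
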