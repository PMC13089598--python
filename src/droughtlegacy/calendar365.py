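"""365-day calendar helpers shared across the pipeline.

All generators and statistics in this package operate on a 365-day year
(leap days are dropped), so that day-of-year and week-of-year align exactly
across years. Weeks are 7-day blocks counted from 1 January; the 52nd week
absorbs the leftover day and spans 8 days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
WEEKS_PER_YEAR = 52


def year_days(start_year: int, end_year: int) -> pd.DataFrame:
    """Daily calendar frame for [start_year, end_year], Feb 29 removed.

    Returns columns ``date`` (datetime64), ``year``, ``doy`` (1..365,
    recounted after dropping the leap day) and ``week`` (1..52).
    """
    if end_year < start_year:
        raise ValueError(f"end_year {end_year} before start_year {start_year}")
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    dates = dates[~((dates.month == 2) & (dates.day == 29))]
    frame = pd.DataFrame({"date": dates, "year": dates.year})
    frame["doy"] = frame.groupby("year").cumcount() + 1
    frame["week"] = week_of_year(frame["doy"].to_numpy())
    return frame


def week_of_year(doy: np.ndarray | pd.Series) -> np.ndarray:
    """Map day-of-year (1..365) to week-of-year (1..52, last week 8 days)."""
    doy = np.asarray(doy)
    return np.minimum((doy - 1) // 7, WEEKS_PER_YEAR - 1) + 1


def attach_calendar(frame: pd.DataFrame, date_col: str = "date") -> pd.DataFrame:
    """Add ``year``, ``doy`` and ``week`` columns derived from ``date_col``."""
    out = frame.copy()
    dates = pd.DatetimeIndex(out[date_col])
    out = out[~((dates.month == 2) & (dates.day == 29))]
    out = out.sort_values(date_col).reset_index(drop=True)
    dates = pd.DatetimeIndex(out[date_col])
    out["year"] = dates.year
    # recount doy so leap years still land on the 365-day grid
    doy = dates.dayofyear.to_numpy().astype(int)
    leap = dates.is_leap_year
    doy = doy - (leap & (doy > 59)).astype(int)
    out["doy"] = doy
    out["week"] = week_of_year(out["doy"].to_numpy())
    return out
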