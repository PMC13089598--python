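"""Direct drought-impact statistics and record-extreme periods.

Quantifies how a focal (drought) year deviates from the rest of the record:
SD-scaled anomalies and rank fractions of yearly and half-yearly means, and
contiguous runs of days on which the focal year is the pointwise record
minimum or maximum across all years. A presentation-only moving-average
smoother is provided separately and never feeds the statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calendar365 import attach_calendar

PERIODS = ("full_year", "first_half", "second_half")
_HALF_SPLIT_DOY = 182  # July 1 on the 365-day calendar


def _period_mask(doy: pd.Series, period: str) -> pd.Series:
    if period == "full_year":
        return pd.Series(True, index=doy.index)
    if period == "first_half":
        return doy < _HALF_SPLIT_DOY
    if period == "second_half":
        return doy >= _HALF_SPLIT_DOY
    raise ValueError(f"unknown period {period!r}")


def period_impact(series: pd.DataFrame, focal_year: int,
                  periods: tuple[str, ...] = PERIODS,
                  variable: str = "value") -> pd.DataFrame:
    """SD-scaled anomaly and rank of the focal year's period means.

    For each period (full year, first half to June 30, second half from
    July 1) the focal year's mean is compared with the mean of all other
    years' period means; the anomaly is scaled by the sample SD of the other
    years' means. ``rank_fraction`` is the fraction of all years (focal
    included) whose period mean is <= the focal year's — ties count, so
    equal years yield the maximal rank fraction. Periods without valid
    focal-year days are omitted with a warning.
    """
    cal = attach_calendar(series)
    if focal_year not in set(cal["year"]):
        raise ValueError(f"focal year {focal_year} not in record")
    if cal["year"].nunique() < 3:
        raise ValueError("need at least 3 years of data")
    rows = []
    for period in periods:
        mask = _period_mask(cal["doy"], period)
        sub = cal[mask]
        means = sub.groupby("year")[variable].mean()
        means = means.dropna()
        if focal_year not in means.index:
            import warnings
            warnings.warn(f"no valid {period} days in focal year {focal_year}; row omitted")
            continue
        focal = means.loc[focal_year]
        others = means.drop(index=focal_year)
        sd = others.std(ddof=1)
        diff = focal - others.mean()
        if diff == 0:
            anomaly = 0.0
        elif sd == 0:           # identical reference years, focal differs
            anomaly = np.sign(diff) * np.inf
        else:
            anomaly = diff / sd
        rows.append({
            "variable": variable,
            "period": period,
            "year_value": float(focal),
            "longterm_mean": float(others.mean()),
            "anomaly_sd": float(anomaly),
            "rank_fraction": float((means <= focal).mean()),
            "n_years": int(len(means)),
        })
    return pd.DataFrame(rows)


def extreme_runs(series: pd.DataFrame, focal_year: int,
                 min_len: int = 8, variable: str = "value") -> pd.DataFrame:
    """Contiguous day-of-year runs where the focal year is the record extreme.

    A day-of-year counts as a pointwise minimum (maximum) when the focal
    year's value is strictly below (above) that day's value in every other
    year; days where any year is missing are skipped. Maximal consecutive
    runs of at least ``min_len`` days (default 8, i.e. longer than one week)
    are reported with their start/end dates and kind.
    """
    cal = attach_calendar(series)
    wide = cal.pivot_table(index="doy", columns="year", values=variable,
                           aggfunc="first")
    if focal_year not in wide.columns:
        raise ValueError(f"focal year {focal_year} not in record")
    others = wide.drop(columns=focal_year)
    complete = wide.notna().all(axis=1)
    focal = wide[focal_year]
    is_min = complete & (focal < others.min(axis=1)) & (len(others.columns) > 0)
    is_max = complete & (focal > others.max(axis=1)) & (len(others.columns) > 0)

    date_by_doy = (cal[cal["year"] == focal_year]
                   .set_index("doy")["date"].to_dict())
    runs = []
    for kind, flags in (("min", is_min), ("max", is_max)):
        doys = flags[flags].index.to_numpy()
        if len(doys) == 0:
            continue
        breaks = np.flatnonzero(np.diff(doys) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(doys) - 1]])
        for s, e in zip(starts, ends):
            length = int(doys[e] - doys[s] + 1)
            if length >= min_len:
                runs.append({
                    "variable": variable, "year": focal_year, "kind": kind,
                    "start": date_by_doy.get(int(doys[s])),
                    "end": date_by_doy.get(int(doys[e])),
                    "length_days": length,
                })
    return pd.DataFrame(runs, columns=["variable", "year", "kind", "start",
                                       "end", "length_days"])


def smooth(series: pd.DataFrame, window: int, variable: str = "value") -> pd.DataFrame:
    """Centred moving average over available values — presentation only.

    Never feed the result back into the statistics; the impact and run
    detectors take unsmoothed series.
    """
    if window < 1:
        raise ValueError("window must be >= 1 day")
    out = series.copy().sort_values("date").reset_index(drop=True)
    out[variable] = (out[variable]
                     .rolling(window, center=True, min_periods=1)
                     .mean())
    return out
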