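"""Long-term sap-flow processing for degrading thermal-dissipation sensors.

Thermal-dissipation sap-flow probes lose signal amplitude over multi-year
deployments as stem growth detaches the needles from conducting xylem, and
sensors are periodically replaced, so raw multi-sensor records are neither
level- nor variance-consistent over time. This module implements a
four-step per-sensor processing chain that recovers temporally consistent
(but physically uninterpretable, dimensionless) tree-level dynamics:

(a) aggregate half-hourly records to daytime daily means and filter sparse
    days, sparse years and per-year outliers;
(b) remove the long-term trend with a seasonal-trend decomposition (annual
    period, 3-year loess trend window);
(c) divide each year by an annual standard deviation computed in a 3-year
    moving window, homogenizing interannual variance;
(d) average the processed sensors of each tree.

No gap-filling is performed at any step: steps a-c never create values on
days that had none, and step d only fills a day when at least one sensor
reports.

Series are plain pandas frames with ``date`` and ``value`` columns; missing
days carry NaN on the full daily grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import STL

from .calendar365 import attach_calendar, DAYS_PER_YEAR


class ProcessingError(ValueError):
    """Raised when a series cannot be processed (too short, degenerate)."""


@dataclass(frozen=True)
class SapflowParams:
    """Tunable thresholds of the processing chain.

    ``min_day_frac``/``min_year_frac`` are inclusive (at-least) availability
    thresholds; ``window_align`` selects a centred (year +/- 1, truncated at
    record edges) or trailing (previous 2 years + current) moving window for
    the variance normalization.
    """

    min_day_frac: float = 0.70
    min_year_frac: float = 0.40
    outlier_sd: float = 3.0
    trend_years: int = 3
    window_years: int = 3
    window_align: str = "centred"   # or "trailing"
    min_window_sd: float = 1e-8


def _as_daily_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).normalize()
    return out.sort_values("date").reset_index(drop=True)


# ---------------------------------------------------------------------------
# step a: aggregate and filter
# ---------------------------------------------------------------------------

def aggregate_daily(series: pd.DataFrame, min_day_frac: float = 0.70) -> pd.DataFrame:
    """Aggregate half-hourly sensor records to daytime daily means.

    A day's value is the arithmetic mean of its available daytime half-hours
    and is set missing when fewer than ``min_day_frac`` (inclusive) of the
    day's daytime slots carry a value. Days without daytime slots are
    missing. Input already at daily resolution passes through unchanged.

    Parameters
    ----------
    series
        Frame with ``timestamp``, ``value`` and ``daytime_flag`` columns on a
        fixed half-hourly (or daily) grid; gaps are NaN values, not absent
        rows.
    """
    ts = pd.DatetimeIndex(series["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ProcessingError("timestamps must be strictly increasing")
    per_day = series.groupby(ts.normalize()).size()
    if per_day.max() <= 1:  # already daily
        out = pd.DataFrame({
            "date": ts.normalize(),
            "value": series["value"].to_numpy(),
        })
        out["n_available"] = out["value"].notna().astype(int)
        return _as_daily_frame(out)

    day = ts.normalize()
    df = pd.DataFrame({
        "day": day,
        "value": series["value"].to_numpy(),
        "daytime": np.asarray(series["daytime_flag"], dtype=bool),
    })
    df = df[df["daytime"]]
    grouped = df.groupby("day")["value"]
    n_slots = grouped.size()
    n_avail = grouped.count()
    mean = grouped.mean()
    frac = n_avail / n_slots
    value = mean.where(frac >= min_day_frac)

    # days with no daytime slots at all stay missing
    all_days = pd.DatetimeIndex(sorted(day.unique()))
    out = pd.DataFrame({"date": all_days})
    out["value"] = value.reindex(all_days).to_numpy()
    out["n_available"] = n_avail.reindex(all_days).fillna(0).astype(int).to_numpy()
    return _as_daily_frame(out)


def year_coverage(daily: pd.DataFrame) -> pd.Series:
    """Fraction of days with a value, per calendar year of the record."""
    cal = attach_calendar(daily)
    return cal.groupby("year")["value"].apply(lambda v: v.notna().mean())


def filter_years(daily: pd.DataFrame, min_year_frac: float = 0.40) -> pd.DataFrame:
    """Drop calendar years whose daily coverage is below ``min_year_frac``.

    Low-coverage years have every value set missing; other years pass
    through untouched. The threshold is inclusive (a year at exactly the
    threshold is retained).
    """
    out = _as_daily_frame(daily)
    cov = year_coverage(out)
    bad_years = set(cov[cov < min_year_frac].index)
    years = pd.DatetimeIndex(out["date"]).year
    out.loc[np.isin(years, list(bad_years)), "value"] = np.nan
    return out


def remove_outliers(daily: pd.DataFrame, sd_multiple: float = 3.0) -> tuple[pd.DataFrame, int]:
    """Remove values more than ``sd_multiple`` SDs from their annual mean.

    A single pass per calendar year: the year's mean and sample SD are
    computed over its available days, then every value strictly beyond the
    band is set missing. Years with fewer than two available days are left
    untouched. Returns the filtered frame and the number of removed days.
    """
    out = _as_daily_frame(daily)
    years = pd.DatetimeIndex(out["date"]).year
    removed = 0
    for year in np.unique(years):
        sel = years == year
        vals = out.loc[sel, "value"]
        ok = vals.dropna()
        if len(ok) < 2:
            continue
        mean, sd = ok.mean(), ok.std(ddof=1)
        flag = (vals - mean).abs() > sd_multiple * sd
        flag = flag.fillna(False)
        removed += int(flag.sum())
        out.loc[flag[flag].index, "value"] = np.nan
    return out, removed


# ---------------------------------------------------------------------------
# step b: long-term trend removal
# ---------------------------------------------------------------------------

def detrend_longterm(daily: pd.DataFrame, trend_years: int = 3) -> pd.DataFrame:
    """Subtract the long-term trend of a seasonal-trend decomposition.

    The series is decomposed with an annual period (365 days) and a loess
    trend window spanning ``trend_years`` years; the trend is subtracted
    from the original values. The decomposition requires a complete series,
    so gaps are linearly interpolated on a working copy used only for trend
    estimation — missing days remain missing in the output.
    """
    out = _as_daily_frame(daily)
    n_years_with_data = year_coverage(out).gt(0).sum()
    if n_years_with_data < 3:
        raise ProcessingError(
            f"detrending needs >= 3 years with retained data, found {n_years_with_data}")
    values = out["value"].astype(float)
    filled = values.interpolate(limit_direction="both")
    trend_window = trend_years * DAYS_PER_YEAR
    if trend_window % 2 == 0:
        trend_window += 1
    res = STL(filled.to_numpy(), period=DAYS_PER_YEAR, trend=trend_window).fit()
    out["value"] = values - res.trend
    return out


# ---------------------------------------------------------------------------
# step c: moving-window variance normalization
# ---------------------------------------------------------------------------

def normalize_variability(detrended: pd.DataFrame, window_years: int = 3,
                          align: str = "centred", min_sd: float = 1e-8) -> pd.DataFrame:
    """Divide each year by an annual SD from a moving multi-year window.

    For each calendar year the sample SD is computed over all available
    daily values within the window — centred (the year and its neighbours)
    or trailing (the year and the preceding years) — truncated to years that
    exist in the record. Every value in the year is divided by that SD,
    homogenizing interannual variability that stems from sensor-gain decay.
    """
    if align not in ("centred", "trailing"):
        raise ValueError(f"align must be 'centred' or 'trailing', got {align!r}")
    out = _as_daily_frame(detrended)
    years = pd.DatetimeIndex(out["date"]).year.to_numpy()
    values = out["value"].to_numpy(dtype=float)
    half = (window_years - 1) // 2
    result = np.full_like(values, np.nan)
    for year in np.unique(years):
        if align == "centred":
            window = (years >= year - half) & (years <= year + half)
        else:
            window = (years > year - window_years) & (years <= year)
        pool = values[window]
        pool = pool[np.isfinite(pool)]
        sel = years == year
        if not np.isfinite(values[sel]).any():
            continue
        if len(pool) < 2:
            raise ProcessingError(f"year {year}: not enough data in moving window")
        sd = np.std(pool, ddof=1)
        if sd < min_sd:
            raise ProcessingError(f"year {year}: near-constant signal (window SD {sd:.2e})")
        result[sel] = values[sel] / sd
    out["value"] = result
    return out


# ---------------------------------------------------------------------------
# step d: tree-level averaging
# ---------------------------------------------------------------------------

def combine_sensors(processed: list[pd.DataFrame], tree_id: str) -> pd.DataFrame:
    """Per-day mean across sensors; a day is kept if any sensor reports.

    Returns a frame with ``tree_id``, ``date``, ``value`` and ``n_sensors``
    (the per-day count of contributing sensors).
    """
    if not processed:
        raise ValueError("combine_sensors needs at least one sensor series")
    merged = None
    for i, frame in enumerate(processed):
        f = _as_daily_frame(frame)[["date", "value"]].rename(columns={"value": f"v{i}"})
        merged = f if merged is None else merged.merge(f, on="date", how="outer")
    merged = merged.sort_values("date").reset_index(drop=True)
    vals = merged.drop(columns="date")
    out = pd.DataFrame({
        "tree_id": tree_id,
        "date": merged["date"],
        "value": vals.mean(axis=1, skipna=True),
        "n_sensors": vals.notna().sum(axis=1).astype(int),
    })
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def process_sensor(sensor: pd.DataFrame,
                   params: SapflowParams = SapflowParams()) -> tuple[pd.DataFrame, dict]:
    """Apply steps a-c to one sensor; returns the series and a step report."""
    daily = aggregate_daily(sensor, params.min_day_frac)
    n_days = int(daily["value"].notna().sum())
    filtered = filter_years(daily, params.min_year_frac)
    n_after_years = int(filtered["value"].notna().sum())
    cleaned, n_outliers = remove_outliers(filtered, params.outlier_sd)
    detrended = detrend_longterm(cleaned, params.trend_years)
    normalized = normalize_variability(
        detrended, params.window_years, params.window_align, params.min_window_sd)
    report = {
        "days_aggregated": n_days,
        "days_dropped_year_filter": n_days - n_after_years,
        "days_removed_outliers": n_outliers,
        "outlier_fraction": n_outliers / max(n_after_years, 1),
    }
    return normalized, report


def process_tree(sensors: pd.DataFrame,
                 params: SapflowParams = SapflowParams()) -> tuple[pd.DataFrame, dict]:
    """Full per-tree chain: steps a-c per sensor, then the tree mean (d).

    Parameters
    ----------
    sensors
        Long-format frame for one tree: ``tree_id``, ``sensor_id``,
        ``timestamp``, ``value``, ``daytime_flag``.

    Returns
    -------
    (tree_series, report)
        ``tree_series`` has ``tree_id``, ``date``, ``value``, ``n_sensors``;
        the report maps sensor ids to per-step removal counts.
    """
    trees = sensors["tree_id"].unique()
    if len(trees) != 1:
        raise ValueError(f"process_tree expects a single tree, got {list(trees)}")
    processed, report = [], {}
    for sensor_id, group in sensors.groupby("sensor_id"):
        series, sensor_report = process_sensor(group, params)
        processed.append(series)
        report[str(sensor_id)] = sensor_report
    combined = combine_sensors(processed, str(trees[0]))
    return combined, report


def process_all_trees(sensors: pd.DataFrame,
                      params: SapflowParams = SapflowParams()) -> tuple[pd.DataFrame, dict]:
    """Process every tree in a long-format sensor table; concatenated output."""
    frames, reports = [], {}
    for tree_id, group in sensors.groupby("tree_id"):
        series, report = process_tree(group, params)
        frames.append(series)
        reports[str(tree_id)] = report
    return pd.concat(frames, ignore_index=True), reports
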