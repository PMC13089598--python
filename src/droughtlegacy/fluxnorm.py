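"""Cross-instrument normalization of ecosystem flux and greenness series.

Eddy-covariance instrumentation is typically replaced during multi-decade
deployments, shifting the level and scale of derived fluxes. To make GPP and
ET temporally consistent across instrument eras, each era (segment) is
z-scored independently — subtract the segment mean, divide by the segment
sample SD — and the standardized segments are concatenated. Water-use
efficiency (WUE = GPP/ET) is formed on the physical scale before any
standardization; satellite greenness (EVI) is corrected for a long-term
linear trend instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class NormalizationError(ValueError):
    """Raised for degenerate segments (too short or zero variance)."""


@dataclass(frozen=True)
class SegmentSpec:
    """Instrument-era breakpoints.

    ``breakpoints`` are dates at which a new instrument era starts; the
    default single break at 2014-01-01 splits a 2003-2021 record into the
    two eras of the reference site. Every segment must contain at least
    ``min_segment_days`` valid days.
    """

    breakpoints: tuple[str, ...] = ("2014-01-01",)
    min_segment_days: int = 30

    def edges(self, dates: pd.DatetimeIndex) -> list[np.ndarray]:
        """Boolean masks assigning each date to its segment, in time order."""
        bounds = [pd.Timestamp.min, *sorted(pd.Timestamp(b) for b in self.breakpoints),
                  pd.Timestamp.max]
        return [(dates >= lo) & (dates < hi) for lo, hi in zip(bounds[:-1], bounds[1:])]


def normalize_segments(series: pd.DataFrame,
                       spec: SegmentSpec = SegmentSpec()) -> pd.DataFrame:
    """Z-score a flux series independently within each instrument era.

    Within each segment, ``value -> (value - mean) / sd`` using the sample
    (n-1) SD over valid days; missing values stay missing. The operation is
    idempotent up to floating error and preserves within-segment ranks.

    Parameters
    ----------
    series
        Frame with ``date`` and ``value`` columns.
    """
    out = series.copy().sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(out["date"])
    for i, mask in enumerate(spec.edges(dates)):
        vals = out.loc[mask, "value"]
        ok = vals.dropna()
        if mask.sum() == 0:
            continue
        if len(ok) < spec.min_segment_days:
            raise NormalizationError(
                f"segment {i} has {len(ok)} valid days (< {spec.min_segment_days})")
        sd = ok.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise NormalizationError(f"segment {i} has zero variance")
        out.loc[mask, "value"] = (vals - ok.mean()) / sd
    return out


def compute_wue(gpp: pd.DataFrame, et: pd.DataFrame,
                et_floor: float | None = None) -> pd.DataFrame:
    """Water-use efficiency: per-day GPP / ET on the physical scale.

    The ratio is undefined (missing) wherever either input is missing or ET
    falls below ``et_floor``; the floor defaults to the 1st percentile of
    positive ET values, guarding against blow-ups on near-zero days. The
    number of floored days is recorded in ``frame.attrs['n_floored']``.
    """
    g = gpp.sort_values("date").reset_index(drop=True)
    e = et.sort_values("date").reset_index(drop=True)
    merged = g[["date", "value"]].rename(columns={"value": "gpp"}).merge(
        e[["date", "value"]].rename(columns={"value": "et"}), on="date", how="inner")
    et_vals = merged["et"]
    if et_floor is None:
        positive = et_vals[et_vals > 0]
        et_floor = float(np.nanpercentile(positive, 1)) if len(positive) else 0.0
    valid = merged["gpp"].notna() & et_vals.notna() & (et_vals >= et_floor) & (et_vals > 0)
    out = pd.DataFrame({"date": merged["date"],
                        "value": np.where(valid, merged["gpp"] / et_vals, np.nan)})
    out.attrs["n_floored"] = int((et_vals.notna() & merged["gpp"].notna() & ~valid).sum())
    out.attrs["et_floor"] = et_floor
    return out


@dataclass
class TrendReport:
    slope_per_day: float
    intercept: float
    t_value: float
    p_value: float


def detrend_linear(series: pd.DataFrame) -> tuple[pd.DataFrame, TrendReport]:
    """Remove a long-term linear trend by OLS, preserving the mean level.

    Fits ``value ~ days_since_start`` over valid days and returns the
    residuals plus the overall mean, together with the fitted slope and its
    significance. Used for satellite greenness, where a multi-year greening
    trend would otherwise mask drought anomalies.
    """
    out = series.copy().sort_values("date").reset_index(drop=True)
    vals = out["value"].astype(float)
    ok = vals.notna()
    if ok.sum() < 2:
        raise ValueError("detrend_linear needs at least 2 valid days")
    t = (pd.DatetimeIndex(out["date"]) - pd.DatetimeIndex(out["date"])[0]).days.to_numpy(float)
    X = sm.add_constant(t[ok])
    fit = sm.OLS(vals[ok].to_numpy(), X).fit()
    trend = fit.params[1] * t + fit.params[0]
    out["value"] = vals - trend + vals[ok].mean()
    report = TrendReport(slope_per_day=float(fit.params[1]), intercept=float(fit.params[0]),
                         t_value=float(fit.tvalues[1]), p_value=float(fit.pvalues[1]))
    return out, report
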