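"""Random-forest residual detection of post-drought legacy effects.

A random-forest regression learns the relation between daily
hydro-meteorological drivers (SWC, VPD, SW_IN, TA, WS, precip) and a target
flux using every year except the post-drought period, then predicts the
target in the post-drought years from their observed drivers. The residual
(observed minus predicted) estimates the legacy effect: functioning the
current meteorology cannot explain. Because the model never sees
post-drought data, it cannot absorb a legacy signal into the fit.

Model uncertainty is quantified by leave-one-out: for every non-post-drought
year, a forest is trained with that year (and the post-drought years)
withheld and the held-out year is predicted; the resulting residuals,
aggregated to weekly means, define per-week-of-year percentile bands
(5th-95th and 25th-75th). A post-drought weekly residual outside the
5th-95th band is flagged as a significant negative or positive deviation.

Sap flow can be analysed per tree or pooled across trees with the tree
identity as an additional (one-hot) categorical predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .calendar365 import attach_calendar

DRIVER_PREDICTORS = ("SWC", "VPD", "SW_IN", "TA", "WS", "precip")


class TrainingError(ValueError):
    """Raised for empty or degenerate training sets."""


@dataclass(frozen=True)
class LegacyModelConfig:
    """Configuration of one legacy-detection run.

    ``predict_years`` defaults to ``post_drought_years``; setting it to the
    drought year itself (with the drought year then also excluded from
    training) reproduces the drought-year predictability check. ``train_start``
    / ``train_end`` restrict the training years (robustness variant);
    ``add_month`` appends the month of year as a predictor; ``pooled_trees``
    expects a long-format target with a ``tree_id`` column.

    Band options: ``band_scope`` is ``per_week`` (percentiles per
    week-of-year across held-out years, a seasonally varying envelope) or
    ``global`` (one percentile set pooled over all weeks); ``band_level``
    chooses whether weekly-mean or daily residuals feed the percentile pool.
    """

    post_drought_years: tuple[int, ...]
    predictors: tuple[str, ...] = DRIVER_PREDICTORS
    target_name: str = "target"
    n_trees: int = 500
    seed: int = 0
    predict_years: tuple[int, ...] | None = None
    train_start: int | None = None
    train_end: int | None = None
    add_month: bool = False
    pooled_trees: bool = False
    band_scope: str = "per_week"    # or "global"
    band_level: str = "weekly"      # or "daily"
    min_loo_years: int = 5

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictor set must be non-empty")
        if self.band_scope not in ("per_week", "global"):
            raise ValueError(f"unknown band_scope {self.band_scope!r}")
        if self.band_level not in ("weekly", "daily"):
            raise ValueError(f"unknown band_level {self.band_level!r}")
        object.__setattr__(self, "post_drought_years", tuple(self.post_drought_years))
        if self.predict_years is None:
            object.__setattr__(self, "predict_years", self.post_drought_years)
        else:
            object.__setattr__(self, "predict_years", tuple(self.predict_years))

    @property
    def excluded_years(self) -> frozenset[int]:
        """Years that must never appear in a training set."""
        return frozenset(self.post_drought_years) | frozenset(self.predict_years)


@dataclass
class LegacyResult:
    """Bundle of one detection run."""

    daily: pd.DataFrame          # date, year, week, observed, predicted, residual
    weekly: pd.DataFrame         # year, week, weekly_residual, p5..p95, flag
    bands: pd.DataFrame          # week, p5, p25, p75, p95, n_contributing_years
    oob_score: float
    loo_rmse: float
    config: LegacyModelConfig

    @property
    def flag_counts(self) -> dict:
        counts = {"negative": 0, "none": 0, "positive": 0}
        by_year: dict[int, dict] = {}
        for _, row in self.weekly.dropna(subset=["flag"]).iterrows():
            counts[row["flag"]] += 1
            by_year.setdefault(int(row["year"]), {"negative": 0, "none": 0, "positive": 0})
            by_year[int(row["year"])][row["flag"]] += 1
        return {"total": counts, "per_year": by_year}

    @property
    def flagged_fraction(self) -> float:
        flags = self.weekly["flag"].dropna()
        if len(flags) == 0:
            return np.nan
        return float((flags != "none").mean())

    def summary(self) -> dict:
        return {
            "target": self.config.target_name,
            "oob_score": self.oob_score,
            "loo_rmse": self.loo_rmse,
            "flagged_fraction": self.flagged_fraction,
            "flag_counts": self.flag_counts,
        }


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------

def _merge(drivers: pd.DataFrame, target: pd.DataFrame,
           config: LegacyModelConfig) -> pd.DataFrame:
    cols = ["date"] + list(DRIVER_PREDICTORS)
    missing = [c for c in config.predictors if c not in drivers.columns
               and c not in ("month_of_year", "tree_id")]
    if missing:
        raise TrainingError(f"drivers lack predictor columns: {missing}")
    tcols = ["date", "value"] + (["tree_id"] if config.pooled_trees else [])
    if config.pooled_trees and "tree_id" not in target.columns:
        raise TrainingError("pooled_trees requires a tree_id column in the target")
    merged = target[tcols].merge(drivers[cols], on="date", how="inner")
    merged = attach_calendar(merged)
    if config.add_month:
        merged["month_of_year"] = pd.DatetimeIndex(merged["date"]).month
    return merged


def _design(frame: pd.DataFrame, config: LegacyModelConfig,
            tree_levels: list[str] | None) -> pd.DataFrame:
    cols = [p for p in config.predictors if p not in ("tree_id", "month_of_year")]
    X = frame[cols].copy()
    if config.add_month:
        X["month_of_year"] = frame["month_of_year"]
    if config.pooled_trees:
        # one-hot with a fixed, sorted level set: prediction columns always
        # align with training regardless of which trees appear
        for level in tree_levels:
            X[f"tree_{level}"] = (frame["tree_id"] == level).astype(float)
    return X


def assemble_training(drivers: pd.DataFrame, target: pd.DataFrame,
                      config: LegacyModelConfig,
                      extra_exclude: frozenset[int] = frozenset()) -> pd.DataFrame:
    """Rows with complete predictors and target, restricted to training years.

    Post-drought years (and any explicitly predicted years) never enter;
    ``train_start``/``train_end`` further restrict the span. With
    ``pooled_trees`` the result is long format, one row per tree-day.
    """
    merged = _merge(drivers, target, config)
    years = merged["year"]
    keep = ~years.isin(config.excluded_years | extra_exclude)
    if config.train_start is not None:
        keep &= years >= config.train_start
    if config.train_end is not None:
        keep &= years <= config.train_end
    merged = merged[keep]
    pred_cols = [p for p in config.predictors if p not in ("tree_id", "month_of_year")]
    merged = merged.dropna(subset=pred_cols + ["value"]).reset_index(drop=True)
    if merged.empty:
        raise TrainingError("empty training set after masking and dropping gaps")
    _assert_no_leak(merged, config)
    return merged


def _assert_no_leak(training: pd.DataFrame, config: LegacyModelConfig) -> None:
    leaked = set(training["year"].unique()) & set(config.excluded_years)
    if leaked:  # defensive: violating this invalidates the whole inference
        raise AssertionError(f"training set contains excluded years {sorted(leaked)}")


# ---------------------------------------------------------------------------
# forest fitting
# ---------------------------------------------------------------------------

def _forest(n_features: int, n_trees: int, seed: int) -> RandomForestRegressor:
    # R randomForest regression defaults: mtry = max(floor(p/3), 1), nodesize 5
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, n_features // 3),
        min_samples_leaf=5,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
        bootstrap=True,
    )


def fit_predict(training: pd.DataFrame, prediction: pd.DataFrame,
                config: LegacyModelConfig,
                seed: int | None = None) -> tuple[pd.DataFrame, float]:
    """Fit the forest on training rows and predict the requested rows.

    Returns the prediction frame with a ``predicted`` column added, and the
    out-of-bag pseudo-R². Both frames must already carry the predictor
    columns (see :func:`assemble_training`).
    """
    _assert_no_leak(training, config)
    if training["value"].nunique() < 2:
        raise TrainingError("degenerate single-valued target")
    tree_levels = (sorted(training["tree_id"].unique().tolist())
                   if config.pooled_trees else None)
    X = _design(training, config, tree_levels)
    y = training["value"].to_numpy()
    forest = _forest(X.shape[1], config.n_trees, config.seed if seed is None else seed)
    with warnings.catch_warnings():
        # small training sets can leave some rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(X.to_numpy(), y)
        oob = float(forest.oob_score_)
    out = prediction.copy()
    Xp = _design(out, config, tree_levels)
    out["predicted"] = forest.predict(Xp.to_numpy())
    return out, oob


def prediction_rows(drivers: pd.DataFrame, target: pd.DataFrame,
                    config: LegacyModelConfig,
                    years: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Rows of the prediction period with complete predictors.

    The observed target may be missing (predictions are still made); rows
    with incomplete predictors are dropped.
    """
    merged = _merge(drivers, target, config)
    years = config.predict_years if years is None else years
    merged = merged[merged["year"].isin(years)]
    pred_cols = [p for p in config.predictors if p not in ("tree_id", "month_of_year")]
    return merged.dropna(subset=pred_cols).reset_index(drop=True)


# ---------------------------------------------------------------------------
# leave-one-out uncertainty
# ---------------------------------------------------------------------------

def _weekly_mean(frame: pd.DataFrame, col: str) -> pd.DataFrame:
    return (frame.dropna(subset=[col])
            .groupby(["year", "week"], as_index=False)[col].mean())


def loo_uncertainty(drivers: pd.DataFrame, target: pd.DataFrame,
                    config: LegacyModelConfig) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Percentile bands of held-out-year residuals, plus the mean LOO RMSE.

    For every non-post-drought year ``y`` a forest is trained on all other
    non-post-drought years and predicts year ``y``; residuals are collected
    across years. Returns ``(bands, loo_rmse, loo_residuals)`` where bands
    has one row per week-of-year with p5/p25/p75/p95 and the number of
    contributing years, and ``loo_residuals`` carries daily held-out
    residuals for diagnostics.
    """
    merged = _merge(drivers, target, config)
    candidate_years = sorted(set(merged["year"].unique()) - set(config.excluded_years))
    if config.train_start is not None:
        candidate_years = [y for y in candidate_years if y >= config.train_start]
    if config.train_end is not None:
        candidate_years = [y for y in candidate_years if y <= config.train_end]
    if len(candidate_years) < config.min_loo_years:
        raise TrainingError(
            f"need >= {config.min_loo_years} non-post-drought years, "
            f"got {len(candidate_years)}")

    seeds = np.random.SeedSequence(config.seed).generate_state(len(candidate_years) + 1)
    residual_frames = []
    rmses = []
    for i, held_out in enumerate(candidate_years):
        training = assemble_training(drivers, target, config,
                                     extra_exclude=frozenset({held_out}))
        if held_out in set(training["year"]):
            raise AssertionError("held-out year leaked into LOO training")
        rows = prediction_rows(drivers, target, config, years=(held_out,))
        rows = rows.dropna(subset=["value"])
        if rows.empty:
            warnings.warn(f"held-out year {held_out} has no valid days; skipped")
            continue
        rows, _ = fit_predict(training, rows, config, seed=int(seeds[i] % (2**31)))
        rows["residual"] = rows["value"] - rows["predicted"]
        if config.pooled_trees:
            rows = (rows.groupby(["date", "year", "week"], as_index=False)
                    ["residual"].mean())
        residual_frames.append(rows[["date", "year", "week", "residual"]])
        rmses.append(float(np.sqrt(np.mean(rows["residual"] ** 2))))

    if not residual_frames:
        raise TrainingError("no held-out year produced residuals")
    loo_res = pd.concat(residual_frames, ignore_index=True)
    bands = _percentile_bands(loo_res, config)
    return bands, float(np.mean(rmses)), loo_res


def _percentile_bands(loo_res: pd.DataFrame, config: LegacyModelConfig) -> pd.DataFrame:
    if config.band_level == "weekly":
        pool = _weekly_mean(loo_res, "residual")
    else:
        pool = loo_res[["year", "week", "residual"]].dropna()
    rows = []
    if config.band_scope == "global":
        q = np.percentile(pool["residual"], [5, 25, 75, 95])
        for week in range(1, 53):
            rows.append({"week": week, "p5": q[0], "p25": q[1], "p75": q[2],
                         "p95": q[3], "n_contributing_years": pool["year"].nunique()})
    else:
        for week, grp in pool.groupby("week"):
            q = np.percentile(grp["residual"], [5, 25, 75, 95])
            rows.append({"week": int(week), "p5": q[0], "p25": q[1], "p75": q[2],
                         "p95": q[3], "n_contributing_years": grp["year"].nunique()})
    bands = pd.DataFrame(rows).sort_values("week").reset_index(drop=True)
    assert ((bands["p5"] <= bands["p25"]) & (bands["p25"] <= bands["p75"])
            & (bands["p75"] <= bands["p95"])).all()
    return bands


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------

def flag_legacy(daily_residuals: pd.DataFrame, bands: pd.DataFrame) -> pd.DataFrame:
    """Weekly residual means flagged against the uncertainty bands.

    A week is flagged ``positive`` when its mean residual lies strictly
    above p95, ``negative`` strictly below p5, else ``none``; weeks without
    residual days are missing. Boundary values are not flagged.
    """
    weekly = _weekly_mean(daily_residuals, "residual").rename(
        columns={"residual": "weekly_residual"})
    weekly = weekly.merge(bands, on="week", how="left")
    flags = np.where(weekly["weekly_residual"] > weekly["p95"], "positive",
                     np.where(weekly["weekly_residual"] < weekly["p5"],
                              "negative", "none"))
    weekly["flag"] = flags
    weekly.loc[weekly["weekly_residual"].isna(), "flag"] = np.nan
    return weekly


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_analysis(drivers: pd.DataFrame, target: pd.DataFrame,
                 config: LegacyModelConfig) -> LegacyResult:
    """Full detection run for one target.

    Assembles the training set (all years except the predicted/post-drought
    ones), fits the forest and predicts the prediction period, derives the
    leave-one-out uncertainty bands, and flags post-drought weekly residuals
    outside the 5th-95th percentile envelope.
    """
    training = assemble_training(drivers, target, config)
    pred = prediction_rows(drivers, target, config)
    pred, oob = fit_predict(training, pred, config)
    pred["residual"] = pred["value"] - pred["predicted"]
    if config.pooled_trees:
        daily = (pred.groupby(["date", "year", "week"], as_index=False)
                 .agg(observed=("value", "mean"), predicted=("predicted", "mean"),
                      residual=("residual", "mean")))
    else:
        daily = pred.rename(columns={"value": "observed"})[
            ["date", "year", "week", "observed", "predicted", "residual"]]
    bands, loo_rmse, _ = loo_uncertainty(drivers, target, config)
    weekly = flag_legacy(daily, bands)
    return LegacyResult(daily=daily, weekly=weekly, bands=bands,
                        oob_score=oob, loo_rmse=loo_rmse, config=config)


def run_targets(drivers: pd.DataFrame, targets: dict[str, pd.DataFrame],
                base_config: LegacyModelConfig) -> dict[str, LegacyResult]:
    """Run the analysis for several named targets with a shared configuration."""
    results = {}
    for name, frame in targets.items():
        pooled = "tree_id" in frame.columns
        predictors = base_config.predictors
        cfg = LegacyModelConfig(
            post_drought_years=base_config.post_drought_years,
            predictors=predictors, target_name=name,
            n_trees=base_config.n_trees, seed=base_config.seed,
            predict_years=base_config.predict_years,
            train_start=base_config.train_start, train_end=base_config.train_end,
            add_month=base_config.add_month, pooled_trees=pooled,
            band_scope=base_config.band_scope, band_level=base_config.band_level,
            min_loo_years=base_config.min_loo_years)
        results[name] = run_analysis(drivers, frame, cfg)
    return results
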