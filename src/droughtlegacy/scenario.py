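"""Synthetic drought-scenario generator.

Emulates the data structure of a Mediterranean forest monitoring site:
seasonal hydro-meteorological drivers with AR(1) anomalies, a severe
late-season drought year followed by a wet year, carbon and water fluxes
(GPP, ET, tree sap flow) responding nonlinearly to the drivers, multi-sensor
sap-flow records with progressive gain loss and sensor replacements, and an
optional injected post-drought suppression that serves as a ground-truth
legacy effect for parameter-recovery experiments.

All series live on a 365-day calendar (see :mod:`droughtlegacy.calendar365`)
and every draw is tied to ``ScenarioConfig.seed``: the same configuration and
seed reproduce every table bit-identically, and two configurations that
differ only in the legacy suppression share all randomness, so the null and
alternative scenarios are coupled counterfactuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .calendar365 import year_days

DRIVER_COLUMNS = ["SWC", "VPD", "SW_IN", "TA", "WS", "precip"]


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicDriver:
    """Annual harmonic mean curve plus stationary AR(1) anomaly.

    ``phase_doy`` is the day-of-year of the seasonal maximum; ``sd`` is the
    stationary standard deviation of the anomaly (the innovation variance is
    scaled accordingly); ``floor`` clips the final series from below.
    """

    mean: float
    amplitude: float
    phase_doy: float
    rho: float = 0.6
    sd: float = 1.0
    floor: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ConfigurationError(f"AR(1) coefficient must be in [0,1), got {self.rho}")


@dataclass(frozen=True)
class PrecipParams:
    """Intermittent precipitation: Bernoulli occurrence x exponential amount.

    Both the daily wet-day probability and the mean wet-day amount follow an
    annual harmonic. Wet-day frequency peaks in winter and bottoms out in
    July (every summer dries the soil down); wet-day amounts peak with the
    autumn storm season. Defaults give an expected annual total near 930 mm.
    """

    occ_mean: float = 0.25
    occ_amplitude: float = 0.13
    occ_phase_doy: float = 5.0
    amount_mean: float = 10.0       # mm on wet days, annual mean
    amount_amplitude: float = 5.0   # mm, seasonal swing
    amount_phase_doy: float = 290.0


@dataclass(frozen=True)
class DroughtSpec:
    """Precipitation deficit in the drought year.

    ``deficit`` in [0, 1] scales wet-day amounts by (1 - deficit) during
    ``months`` of the drought year. The default (0.89 over July-September)
    leaves ~11% of climatological precipitation in that window.
    ``offseason_deficit`` applies a milder scaling to the drought year's
    remaining months — severe drought years are dry year-round, not only in
    the core window (roughly a quarter below climatology).
    """

    deficit: float = 0.89
    months: tuple[int, ...] = (7, 8, 9)
    offseason_deficit: float = 0.23

    def __post_init__(self) -> None:
        if not 0 <= self.deficit <= 1:
            raise ConfigurationError(f"deficit must be in [0,1], got {self.deficit}")
        if not 0 <= self.offseason_deficit <= 1:
            raise ConfigurationError(
                f"offseason_deficit must be in [0,1], got {self.offseason_deficit}")


@dataclass(frozen=True)
class WetYearSpec:
    """Precipitation surplus fraction for the first post-drought year."""

    surplus: float = 0.55

    def __post_init__(self) -> None:
        if self.surplus < 0:
            raise ConfigurationError(f"surplus must be >= 0, got {self.surplus}")


@dataclass(frozen=True)
class ResponseParams:
    """Coefficients of the flux response functions.

    Each latent flux is a product of four driver kernels — saturating in
    shortwave radiation, unimodal in air temperature, linearly increasing in
    soil water below a stress threshold, hyperbolically decreasing in VPD —
    scaled by an amplitude, with additive Gaussian observation noise
    truncated at zero. Sap flow additionally carries small per-tree
    multiplicative factors (lognormal, sd ``tree_factor_sd``).
    """

    gpp_amplitude: float = 12.0
    et_amplitude: float = 7.0
    sap_amplitude: float = 6.0
    sw_halfsat: float = 150.0       # W m-2
    ta_opt: float = 21.0            # degC
    ta_width: float = 11.0          # degC
    swc_stress_threshold: float = 0.45   # fraction of bucket capacity
    vpd_halfdecay_gpp: float = 25.0      # hPa
    vpd_halfdecay_et: float = 40.0
    vpd_halfdecay_sap: float = 35.0
    noise_sd_gpp: float = 0.35
    noise_sd_et: float = 0.22
    noise_sd_sap: float = 0.20
    tree_factor_sd: float = 0.15


@dataclass(frozen=True)
class LegacySpec:
    """Injected post-drought suppression (the ground-truth legacy effect).

    Fluxes are multiplied by ``1 - lam * exp(-(t - onset)/tau)`` from the
    onset date onward. ``lam = 0`` is the null scenario; ``onset = None``
    defaults to 1 January of the first post-drought year.
    """

    lam: float = 0.0
    onset: str | None = None        # ISO date
    tau_days: float = 180.0

    def __post_init__(self) -> None:
        if not 0 <= self.lam < 1:
            raise ConfigurationError(f"lambda must be in [0,1), got {self.lam}")
        if self.tau_days <= 0:
            raise ConfigurationError(f"tau must be positive, got {self.tau_days}")


@dataclass(frozen=True)
class SensorSpec:
    """Multi-sensor sap-flow instrumentation model.

    Each sensor's gain decays exponentially from 1 at installation at
    ``decay_rate_per_year`` (a scalar applied to all sensors, or one rate per
    sensor slot) and resets to 1 at each replacement date (default: a single
    mid-record replacement). Isolated missing days arise at ``gap_prob``;
    multi-week outage blocks at ``block_gap_per_year`` blocks per year with
    length 14-35 days; spikes at ``outlier_prob`` land
    ``outlier_sd_multiple`` annual standard deviations from the annual mean.
    """

    n_trees: int = 5
    sensors_per_tree: int = 2
    decay_rate_per_year: float | tuple[float, ...] = 0.15
    replacement_dates: tuple[str, ...] | None = None   # None -> one mid-record
    gap_prob: float = 0.02
    block_gap_per_year: float = 0.1
    outlier_prob: float = 0.003
    outlier_sd_multiple: float = 5.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.sensors_per_tree < 1 or self.n_trees < 1:
            raise ConfigurationError("need at least one tree and one sensor per tree")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic experiment."""

    start_year: int = 2003
    end_year: int = 2021
    drought_year: int = 2017
    post_drought_years: tuple[int, ...] | None = None   # default: 2 years after
    driver_params: dict[str, HarmonicDriver] = field(default_factory=dict)
    precip_params: PrecipParams = field(default_factory=PrecipParams)
    drought_spec: DroughtSpec = field(default_factory=DroughtSpec)
    wet_year_spec: WetYearSpec = field(default_factory=WetYearSpec)
    response_params: ResponseParams = field(default_factory=ResponseParams)
    legacy_spec: LegacySpec = field(default_factory=LegacySpec)
    sensor_spec: SensorSpec = field(default_factory=SensorSpec)
    bucket_capacity_mm: float = 400.0  # ~4.5 m rooting depth in rocky soil
    demand_coefficient: float = 0.5    # mm day-1 per (hPa * degC/15)
    swc_init: float = 0.6
    daytime_sw_threshold: float = 20.0  # W m-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigurationError("end_year before start_year")
        if not self.start_year <= self.drought_year <= self.end_year:
            raise ConfigurationError("drought_year outside the record")
        post = self.post_drought_years
        if post is None:
            post = tuple(
                y for y in (self.drought_year + 1, self.drought_year + 2)
                if y <= self.end_year
            )
            object.__setattr__(self, "post_drought_years", post)
        else:
            object.__setattr__(self, "post_drought_years", tuple(post))
        for y in self.post_drought_years:
            if y <= self.drought_year or y > self.end_year:
                raise ConfigurationError(
                    f"post-drought year {y} must lie after {self.drought_year} "
                    f"and within the record"
                )
        if not self.driver_params:
            object.__setattr__(self, "driver_params", default_driver_params())

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def legacy_onset(self) -> pd.Timestamp:
        if self.legacy_spec.onset is not None:
            return pd.Timestamp(self.legacy_spec.onset)
        first_post = min(self.post_drought_years) if self.post_drought_years else self.end_year
        return pd.Timestamp(f"{first_post}-01-01")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        raw = dict(raw)
        converters = {
            "driver_params": lambda d: {k: HarmonicDriver(**v) for k, v in d.items()},
            "precip_params": lambda d: PrecipParams(**d),
            "drought_spec": lambda d: DroughtSpec(**{
                **d, "months": tuple(d.get("months", (7, 8, 9)))}),
            "wet_year_spec": lambda d: WetYearSpec(**d),
            "response_params": lambda d: ResponseParams(**d),
            "legacy_spec": lambda d: LegacySpec(**d),
            "sensor_spec": lambda d: SensorSpec(**{
                **d,
                "decay_rate_per_year": (
                    tuple(d["decay_rate_per_year"])
                    if isinstance(d.get("decay_rate_per_year"), (list, tuple))
                    else d.get("decay_rate_per_year", 0.15)
                ),
                "replacement_dates": (
                    tuple(d["replacement_dates"])
                    if d.get("replacement_dates") is not None else None
                ),
            }),
        }
        for key, conv in converters.items():
            if key in raw and isinstance(raw[key], dict) or (
                key in raw and key == "driver_params"
            ):
                raw[key] = conv(raw[key])
        if "post_drought_years" in raw and raw["post_drought_years"] is not None:
            raw["post_drought_years"] = tuple(raw["post_drought_years"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_driver_params() -> dict[str, HarmonicDriver]:
    """Mediterranean-like seasonal driver parameterization (daily scale)."""
    return {
        "TA": HarmonicDriver(mean=13.5, amplitude=8.5, phase_doy=200, rho=0.80, sd=2.0),
        "SW_IN": HarmonicDriver(mean=180.0, amplitude=110.0, phase_doy=172, rho=0.60,
                                sd=30.0, floor=0.0),
        "VPD": HarmonicDriver(mean=8.0, amplitude=6.0, phase_doy=200, rho=0.70,
                              sd=2.2, floor=0.0),
        "WS": HarmonicDriver(mean=3.5, amplitude=0.8, phase_doy=15, rho=0.40,
                             sd=1.0, floor=0.0),
    }


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _harmonic(doy: np.ndarray, mean: float, amplitude: float, phase_doy: float) -> np.ndarray:
    return mean + amplitude * np.cos(2 * np.pi * (doy - phase_doy) / 365.0)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    return lfilter([1.0], [1.0, -rho], innov)


def generate_drivers(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the daily hydro-meteorological driver table.

    Each meteorological driver is an annual harmonic plus a stationary AR(1)
    anomaly. Precipitation is an intermittent occurrence-amount process whose
    wet-day amounts are scaled by ``1 - deficit`` in the drought window and
    by ``1 + surplus`` throughout the first post-drought year. Soil water
    content integrates precipitation through a single-bucket balance: gain
    from precip, loss proportional to an atmospheric demand driven by VPD and
    temperature and limited by the current store, clipped to [0, 1].
    """
    cal = year_days(config.start_year, config.end_year)
    n = len(cal)
    doy = cal["doy"].to_numpy()
    streams = np.random.default_rng(config.seed).spawn(6)
    out = cal.copy()

    for stream, name in zip(streams[:4], ["TA", "SW_IN", "VPD", "WS"]):
        p = config.driver_params[name]
        series = _harmonic(doy, p.mean, p.amplitude, p.phase_doy) + _ar1(
            stream, n, p.rho, p.sd)
        if p.floor is not None:
            series = np.clip(series, p.floor, None)
        out[name] = series

    pp = config.precip_params
    occ_p = np.clip(_harmonic(doy, pp.occ_mean, pp.occ_amplitude, pp.occ_phase_doy), 0.0, 1.0)
    amt_mean = np.clip(
        _harmonic(doy, pp.amount_mean, pp.amount_amplitude, pp.amount_phase_doy), 0.1, None)
    occ = streams[4].random(n) < occ_p
    amounts = streams[5].exponential(1.0, size=n) * amt_mean
    precip = np.where(occ, amounts, 0.0)

    months = pd.DatetimeIndex(out["date"]).month.to_numpy()
    drought_year = out["year"].to_numpy() == config.drought_year
    in_window = drought_year & np.isin(months, list(config.drought_spec.months))
    precip = np.where(in_window, precip * (1.0 - config.drought_spec.deficit), precip)
    off_window = drought_year & ~in_window
    precip = np.where(
        off_window, precip * (1.0 - config.drought_spec.offseason_deficit), precip)
    if config.post_drought_years:
        wet = out["year"].to_numpy() == min(config.post_drought_years)
        precip = np.where(wet, precip * (1.0 + config.wet_year_spec.surplus), precip)
    out["precip"] = precip

    # bucket water balance -> volumetric soil water fraction
    demand = (config.demand_coefficient * out["VPD"].to_numpy()
              * np.clip(out["TA"].to_numpy(), 0.0, None) / 15.0)
    cap = config.bucket_capacity_mm
    store = np.empty(n)
    w = config.swc_init * cap
    for i in range(n):
        w = w + precip[i] - demand[i] * (w / cap)
        w = min(max(w, 0.0), cap)
        store[i] = w
    out["SWC"] = store / cap

    return out[["date", "year", "doy", "week"] + DRIVER_COLUMNS]


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

def legacy_multiplier(dates: pd.Series | pd.DatetimeIndex, config: ScenarioConfig) -> np.ndarray:
    """1 - lam * exp(-(t - onset)/tau) from onset onward, 1 before."""
    spec = config.legacy_spec
    dates = pd.DatetimeIndex(dates)
    days_since = (dates - config.legacy_onset).days.to_numpy().astype(float)
    mult = np.ones(len(dates))
    after = days_since >= 0
    mult[after] = 1.0 - spec.lam * np.exp(-days_since[after] / spec.tau_days)
    return mult


def tree_ids(config: ScenarioConfig) -> list[str]:
    return [f"T{i + 1}" for i in range(config.sensor_spec.n_trees)]


def _response_kernels(drivers: pd.DataFrame, p: ResponseParams) -> dict[str, np.ndarray]:
    sw = drivers["SW_IN"].to_numpy()
    ta = drivers["TA"].to_numpy()
    swc = drivers["SWC"].to_numpy()
    vpd = drivers["VPD"].to_numpy()
    return {
        "light": sw / (sw + p.sw_halfsat),
        "temp": np.exp(-((ta - p.ta_opt) / p.ta_width) ** 2),
        "water": np.clip(swc / p.swc_stress_threshold, 0.0, 1.0),
        "vpd_gpp": 1.0 / (1.0 + vpd / p.vpd_halfdecay_gpp),
        "vpd_et": 1.0 / (1.0 + vpd / p.vpd_halfdecay_et),
        "vpd_sap": 1.0 / (1.0 + vpd / p.vpd_halfdecay_sap),
    }


def generate_fluxes(drivers: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Latent fluxes driven nonlinearly by the drivers.

    Returns a frame with ``GPP_true``, ``ET_true``, ``sapflow_true``, one
    ``sapflow_<tree>`` column per tree (small lognormal per-tree factors) and
    the ``legacy_multiplier`` applied to every flux. Noise is truncated so
    fluxes stay non-negative; the multiplier (<= 1) is applied afterwards, so
    scenarios differing only in the suppression share all noise draws.
    """
    missing = [c for c in DRIVER_COLUMNS if c not in drivers.columns]
    if missing:
        raise ValueError(f"driver table lacks columns: {missing}")
    p = config.response_params
    k = _response_kernels(drivers, p)
    n = len(drivers)
    # stream indices 6.. keep flux noise independent of the driver streams
    streams = np.random.default_rng(config.seed).spawn(10)
    noise_gpp = streams[6].normal(0.0, p.noise_sd_gpp, n)
    noise_et = streams[7].normal(0.0, p.noise_sd_et, n)
    noise_sap = streams[8].normal(0.0, p.noise_sd_sap, n)
    factors = np.exp(streams[9].normal(0.0, p.tree_factor_sd, config.sensor_spec.n_trees))

    mult = legacy_multiplier(drivers["date"], config)
    out = drivers[["date", "year", "doy", "week"]].copy()
    out["legacy_multiplier"] = mult
    gpp = p.gpp_amplitude * k["light"] * k["temp"] * k["water"] * k["vpd_gpp"]
    et = p.et_amplitude * k["light"] ** 0.6 * k["temp"] ** 0.5 * k["water"] * k["vpd_et"]
    sap = p.sap_amplitude * k["light"] ** 0.5 * k["temp"] ** 0.6 * k["water"] * k["vpd_sap"]
    out["GPP_true"] = mult * np.clip(gpp + noise_gpp, 0.0, None)
    out["ET_true"] = mult * np.clip(et + noise_et, 0.0, None)
    sap_obs = mult * np.clip(sap + noise_sap, 0.0, None)
    out["sapflow_true"] = sap_obs
    for tree, f in zip(tree_ids(config), factors):
        out[f"sapflow_{tree}"] = f * sap_obs
    return out


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

def _sensor_decay_rate(spec: SensorSpec, slot: int) -> float:
    r = spec.decay_rate_per_year
    if isinstance(r, (tuple, list)):
        return float(r[slot % len(r)])
    return float(r)


def sensor_gain(dates: pd.DatetimeIndex, rate_per_year: float,
                replacements: list[pd.Timestamp]) -> np.ndarray:
    """Exponential gain decay from 1, resetting to 1 at each replacement."""
    elapsed = (dates - dates[0]).days.to_numpy().astype(float)
    for rep in sorted(replacements):
        after = dates >= rep
        elapsed[after] = (dates[after] - rep).days
    return np.exp(-rate_per_year * elapsed / 365.0)


def simulate_sensors(fluxes: pd.DataFrame, config: ScenarioConfig,
                     freq: str = "D") -> pd.DataFrame:
    """Raw multi-sensor sap-flow records with degradation artefacts.

    Each sensor observes its tree's latent sap flow through an exponentially
    decaying gain (reset to 1 at replacement dates), multiplicative
    measurement noise, isolated and multi-week gaps, and occasional spikes
    placed several annual standard deviations from the annual mean. With
    ``freq='30min'`` the daily signal is expanded into a half-hourly diurnal
    course (daylength varies seasonally; the daytime mean of the expansion
    equals the daily value in expectation).

    Returns a long-format frame: tree_id, sensor_id, timestamp, value,
    daytime_flag. Gaps are NaN values on the full time grid.
    """
    spec = config.sensor_spec
    dates = pd.DatetimeIndex(fluxes["date"])
    if spec.replacement_dates is None:
        mid = dates[len(dates) // 2]
        replacements = [mid]
    else:
        replacements = [pd.Timestamp(d) for d in spec.replacement_dates]
        for rep in replacements:
            if rep < dates[0] or rep > dates[-1]:
                raise ConfigurationError(f"replacement date {rep.date()} outside record")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(11)[10])
    frames = []
    for t_idx, tree in enumerate(tree_ids(config)):
        truth = fluxes[f"sapflow_{tree}"].to_numpy()
        for s_idx in range(spec.sensors_per_tree):
            slot = t_idx * spec.sensors_per_tree + s_idx
            rate = _sensor_decay_rate(spec, slot)
            gain = sensor_gain(dates, rate, replacements)
            noise = rng.normal(0.0, spec.noise_sd, len(dates))
            value = gain * truth * (1.0 + noise)

            # isolated daily gaps
            value = np.where(rng.random(len(dates)) < spec.gap_prob, np.nan, value)
            # multi-week outage blocks
            n_blocks = rng.poisson(spec.block_gap_per_year * config.n_years)
            for _ in range(n_blocks):
                start = rng.integers(0, len(dates))
                length = rng.integers(14, 36)
                value[start:start + length] = np.nan
            # spikes relative to that sensor-year's statistics
            spike_days = np.flatnonzero(rng.random(len(dates)) < spec.outlier_prob)
            if len(spike_days):
                years = fluxes["year"].to_numpy()
                for day in spike_days:
                    sel = (years == years[day]) & np.isfinite(value)
                    if sel.sum() < 2:
                        continue
                    mean, sd = value[sel].mean(), value[sel].std(ddof=1)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    value[day] = mean + sign * spec.outlier_sd_multiple * sd

            if freq == "D":
                frames.append(pd.DataFrame({
                    "tree_id": tree, "sensor_id": f"{tree}S{s_idx + 1}",
                    "timestamp": dates, "value": value, "daytime_flag": True,
                }))
            elif freq == "30min":
                frames.append(_expand_halfhourly(
                    dates, value, fluxes["doy"].to_numpy(), tree,
                    f"{tree}S{s_idx + 1}", rng, spec.noise_sd))
            else:
                raise ConfigurationError(f"unsupported frequency {freq!r}")
    return pd.concat(frames, ignore_index=True)


def _expand_halfhourly(dates: pd.DatetimeIndex, daily: np.ndarray, doy: np.ndarray,
                       tree: str, sensor: str, rng: np.random.Generator,
                       noise_sd: float) -> pd.DataFrame:
    """Expand daily values into a half-hourly diurnal course.

    Daytime follows a half-sine between sunrise and sunset (daylength 8-16 h
    with a summer peak); the half-sine is scaled so its daytime mean equals
    the daily value. Night-time flow is 5% of the daily value.
    """
    slots = np.arange(48) / 2.0  # hour of day
    daylength = 12.0 + 4.0 * np.cos(2 * np.pi * (doy - 172) / 365.0)
    sunrise = 12.0 - daylength / 2.0
    # (n_days, 48) grids
    hrs = np.broadcast_to(slots, (len(dates), 48))
    sr = sunrise[:, None]
    dl = daylength[:, None]
    frac = (hrs - sr) / dl
    day_mask = (frac >= 0) & (frac < 1)
    profile = np.where(day_mask, np.sin(np.pi * np.clip(frac, 0, 1)), 0.05)
    # scale each day so the mean over its daytime slots is exactly the
    # daily value (aggregate_daily then recovers it without bias)
    with np.errstate(invalid="ignore"):
        day_means = np.where(day_mask, profile, np.nan)
        norm = np.nanmean(day_means, axis=1, keepdims=True)
    profile = np.where(day_mask, profile / norm, profile)
    values = daily[:, None] * profile
    values = values * (1.0 + rng.normal(0.0, noise_sd, values.shape))
    values[np.isnan(daily), :] = np.nan

    timestamps = dates.repeat(48) + pd.to_timedelta(np.tile(slots, len(dates)), unit="h")
    return pd.DataFrame({
        "tree_id": tree, "sensor_id": sensor, "timestamp": timestamps,
        "value": values.ravel(), "daytime_flag": day_mask.ravel(),
    })


# ---------------------------------------------------------------------------
# convenience orchestration and IO
# ---------------------------------------------------------------------------

def generate_scenario(config: ScenarioConfig, sensor_freq: str = "D") -> dict:
    """Run the full generator: drivers -> fluxes -> sensors."""
    drivers = generate_drivers(config)
    fluxes = generate_fluxes(drivers, config)
    sensors = simulate_sensors(fluxes, config, freq=sensor_freq)
    return {"drivers": drivers, "fluxes": fluxes, "sensors": sensors}


def write_scenario(tables: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables["drivers"].to_csv(out / "drivers.csv", index=False, date_format="%Y-%m-%d")
    tables["fluxes"].to_csv(out / "fluxes.csv", index=False, date_format="%Y-%m-%d")
    tables["sensors"].to_csv(out / "sensors.csv", index=False,
                             date_format="%Y-%m-%d %H:%M:%S")
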