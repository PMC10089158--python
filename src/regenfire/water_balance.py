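"""Monthly water balance and derived climate metrics.

Climatic water deficit (CWD = PET - AET) is the drought index driving the
recruitment models.  The implementation is a classical Thornthwaite potential
evapotranspiration (temperature + daylength) feeding Thornthwaite-Mather soil
bookkeeping with exponential drying, extended with a simple snow store: all
precipitation falls as snow at or below 0 degC, as rain at or above 6 degC,
linearly in between, and melts in proportion to above-freezing temperature.

All monthly series are pandas DataFrames in long format with columns
``year``, ``month``, ``tmean_c``, ``precip_mm`` (and optionally ``vpd_kpa``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WaterBalanceConfig",
    "compute_pet",
    "run_water_balance",
    "baseline_zscore",
    "postfire_extremes",
    "annual_aggregates",
    "metrics_from_annual",
    "compute_climate_metrics",
    "GROWING_SEASON_MONTHS",
    "SUMMER_MONTHS",
    "BASELINE_YEARS",
]

#: April-September, the seasonal aggregation window for deficit and precipitation.
GROWING_SEASON_MONTHS = (4, 5, 6, 7, 8, 9)
#: June-August, the window for summer vapor pressure deficit.
SUMMER_MONTHS = (6, 7, 8)
#: Climatological baseline years (inclusive).
BASELINE_YEARS = (1981, 2010)

_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# mid-month day of year, used for solar declination
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


@dataclass
class WaterBalanceConfig:
    """Tunables for the soil/snow bookkeeping.

    whc_mm: soil water-holding capacity (default 150 mm, a typical forest soil).
    snow_all_c / rain_all_c: temperatures bounding the linear rain/snow split.
    melt_mm_per_degc_day: degree-day melt coefficient.
    """

    whc_mm: float = 150.0
    snow_all_c: float = 0.0
    rain_all_c: float = 6.0
    melt_mm_per_degc_day: float = 2.0
    spinup: bool = True

    def __post_init__(self) -> None:
        if self.whc_mm <= 0:
            raise ValueError(f"whc_mm must be positive, got {self.whc_mm}")
        if self.rain_all_c <= self.snow_all_c:
            raise ValueError("rain_all_c must exceed snow_all_c")


def _daylength_hours(latitude: float) -> np.ndarray:
    """Mid-month daylength (h) for the 12 calendar months."""
    phi = np.deg2rad(latitude)
    decl = 0.409 * np.sin(2.0 * np.pi * _MID_MONTH_DOY / 365.0 - 1.39)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 / np.pi * omega


def compute_pet(tmean_c: np.ndarray, latitude: float, year: int | None = None) -> np.ndarray:
    """Thornthwaite potential evapotranspiration, mm per month.

    Parameters
    ----------
    tmean_c
        Monthly mean temperatures.  Length must be a multiple of 12 and
        aligned to calendar years starting in January; the annual heat index
        is computed per calendar year.
    latitude
        Site latitude in degrees, within [-90, 90].
    year
        Unused placeholder kept for signature stability (the calendar
        alignment carries the year information).

    Freezing months (tmean <= 0 degC) have PET = 0 by convention.
    """
    tmean_c = np.asarray(tmean_c, dtype=float)
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude must be in [-90, 90], got {latitude}")
    if tmean_c.ndim != 1 or tmean_c.size % 12 != 0:
        raise ValueError("tmean_c must be a 1-D array with a whole number of years")

    n_years = tmean_c.size // 12
    t = tmean_c.reshape(n_years, 12)
    t_pos = np.clip(t, 0.0, None)
    heat_index = np.sum((t_pos / 5.0) ** 1.514, axis=1)  # per calendar year
    heat_index = np.maximum(heat_index, 1e-9)
    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index + 0.49239)
    pet_unadj = 16.0 * (10.0 * t_pos / heat_index[:, None]) ** a[:, None]
    daylen = _daylength_hours(latitude)
    corr = (daylen / 12.0) * (_DAYS_IN_MONTH / 30.0)
    pet = pet_unadj * corr[None, :]
    pet[t <= 0.0] = 0.0
    return pet.reshape(-1)


def _check_chronological(series: pd.DataFrame) -> None:
    idx = series["year"].to_numpy() * 12 + (series["month"].to_numpy() - 1)
    diffs = np.diff(idx)
    bad = np.nonzero(diffs != 1)[0]
    if bad.size:
        i = bad[0] + 1
        raise ValueError(
            "climate series must be chronological and gap-free; first offending "
            f"month: year={series['year'].iloc[i]} month={series['month'].iloc[i]}"
        )


def _snow_rain_split(tmean: np.ndarray, cfg: WaterBalanceConfig) -> np.ndarray:
    """Fraction of precipitation falling as snow."""
    frac = (cfg.rain_all_c - tmean) / (cfg.rain_all_c - cfg.snow_all_c)
    return np.clip(frac, 0.0, 1.0)


def _step_month(tmean, precip, pet, days, soil, snow, cfg):
    """Advance the store vectors one month; returns (aet, runoff, soil, snow)."""
    fs = _snow_rain_split(tmean, cfg)
    snowfall = precip * fs
    rain = precip - snowfall
    snow = snow + snowfall
    melt = np.minimum(snow, cfg.melt_mm_per_degc_day * np.clip(tmean, 0.0, None) * days)
    snow = snow - melt
    water_in = rain + melt

    wet = water_in >= pet
    aet = np.where(wet, pet, 0.0)
    surplus = np.where(wet, water_in - pet, 0.0)
    recharge = np.minimum(surplus, cfg.whc_mm - soil)
    runoff = surplus - recharge

    shortfall = np.where(wet, 0.0, pet - water_in)
    withdrawal = np.where(wet, 0.0, soil * (1.0 - np.exp(-shortfall / cfg.whc_mm)))
    aet = np.where(wet, aet, water_in + withdrawal)
    soil = np.where(wet, soil + recharge, soil - withdrawal)
    return aet, runoff, soil, snow


def _run_engine(tmean: np.ndarray, precip: np.ndarray, pet: np.ndarray,
                cfg: WaterBalanceConfig):
    """Vectorized monthly loop.  Arrays are (n_months,) or (n_months, n_sites).

    Returns dict of arrays with the same shape: aet, deficit, soil, snow, runoff.
    """
    squeeze = tmean.ndim == 1
    tmean = np.atleast_2d(tmean.T).T
    precip = np.atleast_2d(precip.T).T
    pet = np.atleast_2d(pet.T).T
    n_months, n_sites = tmean.shape
    if n_months % 12 != 0:
        raise ValueError("series length must be a whole number of years")

    soil = np.zeros(n_sites)
    snow = np.zeros(n_sites)
    if cfg.spinup:
        for m in range(min(12, n_months)):
            d = _DAYS_IN_MONTH[m % 12]
            _, _, soil, snow = _step_month(
                tmean[m], precip[m], pet[m], d, soil, snow, cfg)

    out = {k: np.zeros((n_months, n_sites)) for k in
           ("aet", "deficit", "soil", "snow", "runoff")}
    out["soil_init"] = soil.copy()
    out["snow_init"] = snow.copy()
    for m in range(n_months):
        d = _DAYS_IN_MONTH[m % 12]
        aet, runoff, soil, snow = _step_month(
            tmean[m], precip[m], pet[m], d, soil, snow, cfg)
        out["aet"][m] = aet
        out["deficit"][m] = pet[m] - aet
        out["soil"][m] = soil
        out["snow"][m] = snow
        out["runoff"][m] = runoff
    if squeeze:
        out = {k: (v[:, 0] if v.ndim == 2 else v[0]) for k, v in out.items()}
    return out


def run_water_balance(series: pd.DataFrame, whc: float | None = None,
                      latitude: float = 45.0,
                      config: WaterBalanceConfig | None = None) -> pd.DataFrame:
    """Run the monthly water balance for one site.

    Parameters
    ----------
    series
        Long-format monthly climate with columns year, month, tmean_c,
        precip_mm; chronological, gap-free, starting in January.
    whc
        Soil water-holding capacity (mm); overrides ``config.whc_mm``.
    latitude
        Site latitude (degrees) for the daylength term of PET.

    Returns the input plus columns pet_mm, aet_mm, deficit_mm, soil_mm,
    snow_mm, runoff_mm.  The first simulated year is re-run once as spin-up
    to initialize the soil and snow stores.
    """
    cfg = config or WaterBalanceConfig()
    if whc is not None:
        cfg = WaterBalanceConfig(whc_mm=whc, snow_all_c=cfg.snow_all_c,
                                 rain_all_c=cfg.rain_all_c,
                                 melt_mm_per_degc_day=cfg.melt_mm_per_degc_day,
                                 spinup=cfg.spinup)
    required = {"year", "month", "tmean_c", "precip_mm"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"climate series missing columns: {sorted(missing)}")
    if (series["precip_mm"].to_numpy() < 0).any():
        raise ValueError("precipitation must be nonnegative")
    _check_chronological(series)
    if series["month"].iloc[0] != 1:
        raise ValueError("series must start in January")

    tmean = series["tmean_c"].to_numpy(dtype=float)
    precip = series["precip_mm"].to_numpy(dtype=float)
    pet = compute_pet(tmean, latitude)
    res = _run_engine(tmean, precip, pet, cfg)

    out = series.copy()
    out["pet_mm"] = pet
    out["aet_mm"] = res["aet"]
    out["deficit_mm"] = res["deficit"]
    out["soil_mm"] = res["soil"]
    out["snow_mm"] = res["snow"]
    out["runoff_mm"] = res["runoff"]
    out.attrs["soil_init_mm"] = float(np.asarray(res["soil_init"]).reshape(-1)[0])
    out.attrs["snow_init_mm"] = float(np.asarray(res["snow_init"]).reshape(-1)[0])
    return out


def baseline_zscore(values: pd.Series, years: pd.Series | np.ndarray,
                    baseline: tuple[int, int] = BASELINE_YEARS) -> pd.Series:
    """Standardize an annual/seasonal series against a baseline period.

    z = (x - baseline mean) / baseline sd, with sd over the baseline years
    only (ddof=1).  A constant baseline (sd = 0) yields z = 0 everywhere with
    a warning rather than infinities.
    """
    values = pd.Series(np.asarray(values, dtype=float), index=pd.Index(np.asarray(years)))
    in_base = (values.index >= baseline[0]) & (values.index <= baseline[1])
    base = values[in_base]
    if len(base) < 2:
        raise ValueError(
            f"need >= 2 baseline years in {baseline}, found {len(base)}")
    mu = base.mean()
    sd = base.std(ddof=1)
    if sd == 0:
        warnings.warn("baseline standard deviation is 0; z-scores set to 0")
        return pd.Series(np.zeros(len(values)), index=values.index)
    return (values - mu) / sd


def postfire_extremes(z_series: pd.Series, fire_year: int,
                      window: int = 5) -> tuple[float, float]:
    """(max, min) of an annual z series over the first `window` postfire years.

    The window is fire_year+1 .. fire_year+window; all years must be present.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    wanted = list(range(fire_year + 1, fire_year + window + 1))
    missing = [y for y in wanted if y not in z_series.index]
    if missing:
        raise ValueError(f"postfire window years missing from series: {missing}")
    vals = z_series.loc[wanted].to_numpy(dtype=float)
    return float(vals.max()), float(vals.min())


@dataclass
class SiteClimate:
    """Per-site inputs for metric computation."""
    site: object
    latitude: float = 45.0
    whc_mm: float = 150.0


METRIC_COLUMNS = [
    "mean_annual_deficit_mm",
    "mean_growing_season_deficit_mm",
    "max_postfire_gs_deficit_z", "min_postfire_gs_deficit_z",
    "max_postfire_summer_vpd_z", "min_postfire_summer_vpd_z",
    "max_postfire_gs_precip_z", "min_postfire_gs_precip_z",
]


def _seasonal_tables(wb: pd.DataFrame) -> pd.DataFrame:
    """Annual aggregates: deficit sums, growing-season sums, summer VPD mean."""
    gs = wb[wb["month"].isin(GROWING_SEASON_MONTHS)]
    summer = wb[wb["month"].isin(SUMMER_MONTHS)]
    ann = pd.DataFrame({
        "annual_deficit": wb.groupby("year")["deficit_mm"].sum(),
        "gs_deficit": gs.groupby("year")["deficit_mm"].sum(),
        "gs_precip": gs.groupby("year")["precip_mm"].sum(),
    })
    if "vpd_kpa" in wb.columns:
        ann["summer_vpd"] = summer.groupby("year")["vpd_kpa"].mean()
    return ann


def annual_aggregates(series: pd.DataFrame, latitude: float = 45.0,
                      whc: float = 150.0,
                      config: WaterBalanceConfig | None = None) -> pd.DataFrame:
    """Run the water balance and return the per-year seasonal aggregates."""
    wb = run_water_balance(series, whc=whc, latitude=latitude, config=config)
    return _seasonal_tables(wb)


def metrics_from_annual(ann: pd.DataFrame, fire_year: int,
                        window: int = 5) -> dict:
    """Climate metrics for one fire year from precomputed annual aggregates."""
    y0, y1 = BASELINE_YEARS
    base = ann.loc[(ann.index >= y0) & (ann.index <= y1)]
    if base.empty:
        raise ValueError("series does not cover the 1981-2010 baseline")

    out = {
        "mean_annual_deficit_mm": float(base["annual_deficit"].mean()),
        "mean_growing_season_deficit_mm": float(base["gs_deficit"].mean()),
    }
    pairs = [("gs_deficit", "gs_deficit_z"),
             ("summer_vpd", "summer_vpd_z"),
             ("gs_precip", "gs_precip_z")]
    for col, tag in pairs:
        if col not in ann.columns:
            out[f"max_postfire_{tag}"] = np.nan
            out[f"min_postfire_{tag}"] = np.nan
            continue
        z = baseline_zscore(ann[col], ann.index)
        hi, lo = postfire_extremes(z, fire_year, window=window)
        out[f"max_postfire_{tag}"] = hi
        out[f"min_postfire_{tag}"] = lo
    return out


def compute_climate_metrics(series: pd.DataFrame, fire_year: int,
                            latitude: float = 45.0, whc: float = 150.0,
                            window: int = 5,
                            config: WaterBalanceConfig | None = None) -> dict:
    """All nine per-site climate metrics for one site and fire year.

    30-y means are over 1981-2010; postfire extremes are the max and min of
    annual z-scores (growing-season deficit, June-August VPD, growing-season
    precipitation, all standardized against 1981-2010) over the first
    ``window`` years after the fire.
    """
    ann = annual_aggregates(series, latitude=latitude, whc=whc, config=config)
    return metrics_from_annual(ann, fire_year, window=window)
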