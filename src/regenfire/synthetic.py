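"""Synthetic study generator with known ground truth.

Emulates the structure of a multi-fire postfire regeneration survey: fires
with normally distributed random intercepts, plots nested in fires with
biophysical covariates, one 4-km climate site per fire with a monthly series
spanning 1979-2050, and Bernoulli recruitment outcomes from a logit-linear
model with a log(plot area) offset.  Because the generating parameters are
recorded, every downstream stage (water balance, model fitting, selection,
thresholds, projection) can be tested against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["TruthParams", "SyntheticDataset", "generate_fires",
           "generate_climate_series", "simulate_recruitment", "make_dataset"]

DISTURBANCE_LEVELS = ("none", "wildfire", "fuel treatment", "beetle outbreak",
                      "blowdown")
# observational imbalance: undisturbed plots dominate
_DISTURBANCE_PROBS = (0.70, 0.10, 0.08, 0.08, 0.04)

DEFAULT_COVARIATE_RANGES = {
    "dist_seed_m": (0.0, 500.0),
    "tree_cover_pct": (0.0, 70.0),
    "rbr": (0.0, 800.0),
    "chili": (0.0, 255.0),
}


@dataclass
class TruthParams:
    """Ground-truth data-generating parameters.

    fixed_coefficients map term names to logit-scale coefficients; term names
    are raw covariate columns, ``<col>^2`` for quadratics, and ``a:b`` for
    products.  ``intercept`` is the intercept.  random_intercept_sd is the
    between-fire standard deviation on the logit scale.
    temp_trend_c_per_decade warms the climate series linearly, which
    propagates into a drying (deficit) trend downstream.
    """

    fixed_coefficients: dict = field(default_factory=lambda: {"intercept": 0.0})
    random_intercept_sd: float = 0.7
    n_fires: int = 100
    plots_per_fire: int = 20
    area_m2_range: tuple = (10.0, 1000.0)
    covariate_ranges: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES))
    temp_trend_c_per_decade: float = 0.0
    seed: int = 20230306

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be nonnegative")
        if self.n_fires < 1:
            raise ValueError("n_fires must be >= 1")
        if self.plots_per_fire < 1:
            raise ValueError("plots_per_fire must be >= 1")
        for name, (lo, hi) in {**self.covariate_ranges,
                               "area_m2": self.area_m2_range}.items():
            if not hi > lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    plots: pd.DataFrame
    fires: pd.DataFrame
    climate: pd.DataFrame
    truth: TruthParams


def generate_fires(n_fires: int, sd: float, seed: int) -> pd.DataFrame:
    """Fires with uniform fire years (1984-2018) and N(0, sd^2) intercepts."""
    if n_fires < 1:
        raise ValueError(f"n_fires must be >= 1, got {n_fires}")
    if sd < 0:
        raise ValueError(f"random-intercept sd must be nonnegative, got {sd}")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "fire_id": [f"F{i:04d}" for i in range(n_fires)],
        "fire_year": rng.integers(1984, 2019, size=n_fires),
        "intercept": rng.normal(0.0, sd, size=n_fires),
    })


def generate_climate_series(site_count: int, trend: float = 0.0,
                            seed: int = 0, year_range: tuple = (1979, 2050),
                            ) -> pd.DataFrame:
    """Monthly per-site climate series with seasonality and interannual noise.

    Temperature is a sinusoidal annual cycle (peak in July) around a per-site
    mean, plus white noise and an optional linear warming ``trend``
    (degC/decade).  Precipitation is gamma-distributed with a winter-wet
    seasonal profile; VPD increases with temperature.

    Returns long format: site, year, month, tmean_c, precip_mm, vpd_kpa.
    """
    if site_count < 1:
        raise ValueError(f"site_count must be >= 1, got {site_count}")
    rng = np.random.default_rng(seed)
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)

    site_mean_t = rng.uniform(2.0, 12.0, size=site_count)
    site_amp = rng.uniform(8.0, 14.0, size=site_count)
    site_wet = rng.uniform(30.0, 90.0, size=site_count)  # mean winter monthly precip

    yy, mm = np.meshgrid(years, months, indexing="ij")
    yy = yy.reshape(-1)
    mm = mm.reshape(-1)
    n_m = yy.size

    frames = []
    for s in range(site_count):
        seasonal = site_mean_t[s] + site_amp[s] * np.cos(2 * np.pi * (mm - 7) / 12.0)
        warming = trend * (yy - y0) / 10.0
        tmean = seasonal + warming + rng.normal(0.0, 1.2, size=n_m)
        # winter-wet profile: precipitation peaks in December/January
        p_season = site_wet[s] * (0.65 + 0.45 * np.cos(2 * np.pi * (mm - 1) / 12.0))
        precip = rng.gamma(shape=2.0, scale=np.maximum(p_season, 4.0) / 2.0, size=n_m)
        vpd = np.clip(0.15 + 0.075 * np.clip(tmean, 0.0, None)
                      + rng.normal(0.0, 0.08, size=n_m), 0.01, None)
        frames.append(pd.DataFrame({
            "site": f"S{s:04d}", "year": yy, "month": mm,
            "tmean_c": tmean, "precip_mm": precip, "vpd_kpa": vpd,
        }))
    return pd.concat(frames, ignore_index=True)


def _term_column(plots: pd.DataFrame, term: str) -> np.ndarray:
    """Resolve a truth term name to a raw-scale column vector."""
    if term == "intercept":
        return np.ones(len(plots))
    if term.endswith("^2"):
        base = term[:-2]
        if base not in plots.columns:
            raise KeyError(f"term '{term}' requires missing column '{base}'")
        return plots[base].to_numpy(dtype=float) ** 2
    if ":" in term:
        a, b = term.split(":", 1)
        for c in (a, b):
            if c not in plots.columns:
                raise KeyError(f"term '{term}' requires missing column '{c}'")
        return plots[a].to_numpy(dtype=float) * plots[b].to_numpy(dtype=float)
    if term not in plots.columns:
        raise KeyError(f"term '{term}' has no matching column")
    return plots[term].to_numpy(dtype=float)


def recruitment_probability(plots: pd.DataFrame, truth: TruthParams,
                            fire_intercepts: pd.Series | None = None) -> np.ndarray:
    """True success probability per plot under the generating model."""
    if (plots["area_m2"] <= 0).any():
        raise ValueError("plot areas must be positive")
    eta = np.log(plots["area_m2"].to_numpy(dtype=float))
    for term, beta in truth.fixed_coefficients.items():
        eta = eta + beta * _term_column(plots, term)
    if fire_intercepts is not None:
        eta = eta + plots["fire_id"].map(fire_intercepts).to_numpy(dtype=float)
    return expit(eta)


def simulate_recruitment(plots: pd.DataFrame, truth: TruthParams,
                         fire_intercepts: pd.Series | None = None,
                         seed: int | None = None) -> np.ndarray:
    """Draw Bernoulli presence/absence outcomes from the logit-linear truth."""
    p = recruitment_probability(plots, truth, fire_intercepts)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    return (rng.uniform(size=len(p)) < p).astype(int)


def _truth_base_columns(truth: TruthParams) -> set:
    cols = set()
    for term in truth.fixed_coefficients:
        if term == "intercept":
            continue
        if term.endswith("^2"):
            cols.add(term[:-2])
        elif ":" in term:
            cols.update(term.split(":", 1))
        else:
            cols.add(term)
    return cols


def make_dataset(truth: TruthParams, with_climate: bool = True,
                 latitude: float = 45.0, whc_mm: float = 150.0) -> SyntheticDataset:
    """Full synthetic study: fires, plots with covariates, climate, outcomes.

    One climate site per fire (4-km climate cells are large relative to most
    fires).  Survey years are 2-12 y postfire; fire years are restricted so
    the 5-y postfire climate window stays inside the observed series.

    If the truth coefficients reference climate-metric columns, those metrics
    are computed from the generated climate through the water balance (the
    same pathway the analysis re-derives) and joined to the plots before
    outcomes are drawn.
    """
    rng = np.random.default_rng(truth.seed)
    fires = generate_fires(truth.n_fires, truth.random_intercept_sd,
                           int(rng.integers(2**31)))
    # keep the 5-y postfire window within the 1979-2020 historical record
    fires["fire_year"] = np.minimum(fires["fire_year"], 2014)
    fires["site"] = [f"S{i:04d}" for i in range(len(fires))]

    n = truth.n_fires * truth.plots_per_fire
    plots = pd.DataFrame({
        "plot_id": [f"P{i:06d}" for i in range(n)],
        "fire_id": np.repeat(fires["fire_id"].to_numpy(), truth.plots_per_fire),
    })
    plots = plots.merge(fires[["fire_id", "fire_year", "site"]], on="fire_id")
    delay = rng.integers(2, 13, size=n)
    plots["survey_year"] = plots["fire_year"] + delay
    plots["time_since_fire"] = delay
    lo, hi = truth.area_m2_range
    plots["area_m2"] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    for name, (a, b) in truth.covariate_ranges.items():
        plots[name] = rng.uniform(a, b, size=n)
    plots["disturbance"] = rng.choice(DISTURBANCE_LEVELS, size=n,
                                      p=_DISTURBANCE_PROBS)
    plots["variety"] = rng.choice(["typical", "alternate"], size=n, p=[0.8, 0.2])
    plots["burned"] = True
    plots["planted"] = False

    climate = (generate_climate_series(truth.n_fires,
                                       trend=truth.temp_trend_c_per_decade,
                                       seed=int(rng.integers(2**31)))
               if with_climate else pd.DataFrame())

    needed = _truth_base_columns(truth) - set(plots.columns)
    if needed:
        if not with_climate:
            raise ValueError(
                f"truth references climate metrics {sorted(needed)} but "
                "with_climate=False")
        from .water_balance import compute_climate_metrics
        rows = []
        for _, f in fires.iterrows():
            series = climate[climate["site"] == f["site"]].reset_index(drop=True)
            m = compute_climate_metrics(series, int(f["fire_year"]),
                                        latitude=latitude, whc=whc_mm)
            m["fire_id"] = f["fire_id"]
            rows.append(m)
        metrics = pd.DataFrame(rows)
        still = needed - set(metrics.columns)
        if still:
            raise KeyError(f"truth references unknown column(s): {sorted(still)}")
        plots = plots.merge(metrics[["fire_id", *sorted(needed)]], on="fire_id")

    intercepts = fires.set_index("fire_id")["intercept"]
    plots["presence"] = simulate_recruitment(
        plots, truth, fire_intercepts=intercepts, seed=int(rng.integers(2**31)))
    return SyntheticDataset(plots=plots, fires=fires, climate=climate, truth=truth)
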