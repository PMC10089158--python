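"""Scenario projection, likelihood categories, and partial dependence.

Recruitment probability is projected for every site under paired
fire-severity scenarios (a covariate bundle: distance to seed source,
surrounding tree cover, burn severity) and 20-y climate periods, holding
time since fire at 10 y and plot area at 100 m2 (so probability reads as
"at least one seedling per 0.01 ha").  Sites are then classified, per
threshold, as likely under both severities, only under low severity, or
unlikely under both, and area-weighted category proportions are summarized
by region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import FittedGLMM, predict_probability

__all__ = ["Scenario", "SEVERITY_BUNDLES", "PERIODS", "project_scenario",
           "period_climate_metrics", "classify_sites", "area_summary",
           "partial_dependence"]

#: fire-severity covariate bundles: (distance m, tree cover %, RBR)
SEVERITY_BUNDLES = {
    "low": {"dist_seed_m": 10.0, "tree_cover_pct": 30.0, "rbr": 100.0},
    "high": {"dist_seed_m": 150.0, "tree_cover_pct": 10.0, "rbr": 400.0},
}

#: the three 20-y projection periods (inclusive year ranges)
PERIODS = {
    "1981-2000": (1981, 2000),
    "2001-2020": (2001, 2020),
    "2031-2050": (2031, 2050),
}

CATEGORY_LIKELY_BOTH = "likely-both"
CATEGORY_LIKELY_LOW_ONLY = "likely-low-only"
CATEGORY_UNLIKELY_BOTH = "unlikely-both"
CATEGORY_ANOMALOUS = "likely-high-only"


@dataclass
class Scenario:
    """One projection condition: a severity bundle and a climate period."""
    severity: str                      # "low" | "high"
    period: str                        # key of PERIODS
    emissions: str = ""                # e.g. "RCP4.5" for future periods
    time_since_fire: float = 10.0
    area_m2: float = 100.0
    bundle: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.severity not in SEVERITY_BUNDLES:
            raise ValueError(f"severity must be one of {list(SEVERITY_BUNDLES)}")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {list(PERIODS)}")
        if not self.bundle:
            self.bundle = dict(SEVERITY_BUNDLES[self.severity])


def period_climate_metrics(series: pd.DataFrame, period: tuple[int, int],
                           latitude: float = 45.0, whc: float = 150.0,
                           window: int = 5,
                           annual: pd.DataFrame | None = None) -> dict:
    """Period-level climate metrics for one site.

    The postfire anomaly extremes depend on a fire year; a 20-y period does
    not fix one.  We therefore compute the 5-y-window extreme metrics for
    every fire year whose window fits inside the available series and falls
    in the period, and average them — the period value is the expectation
    over a fire occurring in that period.  The 30-y means stay anchored to
    the 1981-2010 baseline.  Pass precomputed ``annual`` aggregates (from
    :func:`regenfire.water_balance.annual_aggregates`) to amortize the water
    balance across periods.
    """
    from .water_balance import annual_aggregates, metrics_from_annual
    y0, y1 = period
    if annual is None:
        annual = annual_aggregates(series, latitude=latitude, whc=whc)
    last = int(annual.index.max())
    fire_years = [y for y in range(y0, y1 + 1) if y + window <= last]
    if not fire_years:
        raise ValueError(f"no fire year in {period} has a complete "
                         f"{window}-y postfire window in the series")
    rows = [metrics_from_annual(annual, fy, window=window)
            for fy in fire_years]
    df = pd.DataFrame(rows)
    return {c: float(df[c].mean()) for c in df.columns}


def project_scenario(fitted: FittedGLMM, sites: pd.DataFrame,
                     scenario: Scenario) -> np.ndarray:
    """Population-level recruitment probability per site under a scenario.

    ``sites`` must carry the model's climate-metric columns for the
    scenario's period plus any further covariates the model needs (e.g.
    CHILI, disturbance); the severity bundle, time since fire and plot area
    override the corresponding columns.
    """
    nd = sites.copy()
    for k, v in scenario.bundle.items():
        nd[k] = v
    nd["time_since_fire"] = scenario.time_since_fire
    nd[fitted.spec.offset_col] = scenario.area_m2
    return predict_probability(fitted, nd, level="population")


def classify_sites(prob_low, prob_high, threshold: float) -> pd.DataFrame:
    """Three-way likelihood category per site, given both severity runs.

    A site with prob_high above the threshold but prob_low at or below it
    contradicts the expected severity ordering; such sites are categorized
    likely-high-only, flagged anomalous, retained, and reported.
    """
    prob_low = np.asarray(prob_low, dtype=float)
    prob_high = np.asarray(prob_high, dtype=float)
    if ((prob_low < 0) | (prob_low > 1) | (prob_high < 0) | (prob_high > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    low_likely = prob_low > threshold
    high_likely = prob_high > threshold
    cat = np.where(low_likely & high_likely, CATEGORY_LIKELY_BOTH,
                   np.where(low_likely, CATEGORY_LIKELY_LOW_ONLY,
                            np.where(high_likely, CATEGORY_ANOMALOUS,
                                     CATEGORY_UNLIKELY_BOTH)))
    anomalous = high_likely & ~low_likely
    if anomalous.any():
        warnings.warn(f"{int(anomalous.sum())} site(s) likely only under the "
                      "high-severity scenario (severity ordering violated)")
    return pd.DataFrame({"prob_low": prob_low, "prob_high": prob_high,
                         "category": cat, "anomalous": anomalous})


def area_summary(category_map: pd.DataFrame, region: np.ndarray | None = None,
                 cell_area: np.ndarray | None = None) -> pd.DataFrame:
    """Area-weighted category proportions per region (rows sum to 1)."""
    if len(category_map) == 0:
        raise ValueError("empty category map")
    area = (np.ones(len(category_map)) if cell_area is None
            else np.asarray(cell_area, dtype=float))
    if (area <= 0).any():
        raise ValueError("cell areas must be positive")
    reg = (np.repeat("all", len(category_map)) if region is None
           else np.asarray(region))
    df = pd.DataFrame({"region": reg, "category": category_map["category"],
                       "area": area})
    total = df.groupby("region")["area"].sum()
    if (total <= 0).any():
        raise ValueError("zero total area in a region")
    out = (df.groupby(["region", "category"])["area"].sum()
             .unstack(fill_value=0.0))
    out = out.div(total, axis=0)
    for c in (CATEGORY_LIKELY_BOTH, CATEGORY_LIKELY_LOW_ONLY,
              CATEGORY_UNLIKELY_BOTH, CATEGORY_ANOMALOUS):
        if c not in out.columns:
            out[c] = 0.0
    return out[[CATEGORY_LIKELY_BOTH, CATEGORY_LIKELY_LOW_ONLY,
                CATEGORY_UNLIKELY_BOTH, CATEGORY_ANOMALOUS]]


def _median_row(fitted: FittedGLMM, data: pd.DataFrame) -> dict:
    """Baseline row: continuous covariates at medians, categoricals at the
    reference level, plot area at its median."""
    row = {}
    for t in fitted.spec.terms:
        if t.categorical:
            levels = fitted.scaler.get(f"levels::{t.name}")
            row[t.name] = (levels["ref"] if levels
                           else sorted(data[t.name].unique())[0])
        else:
            row[t.name] = float(data[t.name].median())
    row[fitted.spec.offset_col] = float(data[fitted.spec.offset_col].median())
    return row


def partial_dependence(fitted: FittedGLMM, data: pd.DataFrame, focal: str,
                       interacting: str | None = None, draws: int = 1000,
                       seed: int = 20230306, grid: int = 100) -> pd.DataFrame:
    """Partial-dependence curve(s) with parametric-bootstrap 95% CI bands.

    The focal covariate sweeps its observed range (``grid`` points); all
    other covariates sit at their medians (categoricals at the reference
    level).  With an ``interacting`` covariate, three curves are returned at
    its 10th/50th/90th percentiles.  Bands come from ``draws`` multivariate
    normal draws of the fixed coefficients around the fit (percentiles 2.5
    and 97.5).  A categorical focal term yields per-level point estimates
    with CIs instead of a curve.
    """
    if draws < 200:
        raise ValueError(f"draws must be >= 200, got {draws}")
    term = fitted.spec.term(focal)
    base = _median_row(fitted, data)

    if term.categorical:
        levels = fitted.scaler.get(f"levels::{focal}")
        lev_list = levels["levels"] if levels else sorted(data[focal].unique())
        frames = []
        for lev in lev_list:
            row = dict(base); row[focal] = lev
            frames.append(row)
        nd = pd.DataFrame(frames)
        nd["_x"] = lev_list
    else:
        xs = np.linspace(data[focal].min(), data[focal].max(), grid)
        if interacting is not None:
            qs = np.percentile(data[interacting].to_numpy(float), [10, 50, 90])
            frames = []
            for q, tag in zip(qs, ("p10", "p50", "p90")):
                block = pd.DataFrame([dict(base) for _ in xs])
                block[focal] = xs
                block[interacting] = q
                block["_level"] = tag
                frames.append(block)
            nd = pd.concat(frames, ignore_index=True)
            nd["_x"] = np.tile(xs, 3)
        else:
            nd = pd.DataFrame([dict(base) for _ in xs])
            nd[focal] = xs
            nd["_x"] = xs

    from .dataset import build_design
    from scipy.special import expit
    design = build_design(nd, fitted.spec, scaler=fitted.scaler,
                          require_response=False)
    Xm = design.X.to_numpy(float)
    beta_hat = fitted.coef.reindex(design.X.columns).to_numpy()
    eta = Xm @ beta_hat + design.offset
    center = expit(eta)

    rng = np.random.default_rng(seed)
    cov = fitted.cov.reindex(index=design.X.columns,
                             columns=design.X.columns).to_numpy()
    draws_b = rng.multivariate_normal(beta_hat, cov, size=draws,
                                      method="svd")
    etas = draws_b @ Xm.T + design.offset[None, :]
    ps = expit(etas)
    lo, hi = np.percentile(ps, [2.5, 97.5], axis=0)

    out = pd.DataFrame({"x": nd["_x"].to_numpy(), "prob": center,
                        "lo": lo, "hi": hi})
    if "_level" in nd.columns:
        out["interacting_level"] = nd["_level"].to_numpy()
    return out
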