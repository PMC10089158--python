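import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from regenfire import dataset, glmm


def simulate_plot_table(n_fires, plots_per_fire, beta, sigma, seed,
                        covariates=("x",), area=1.0):
    """Minimal grouped binary table: standardized-normal covariates,
    N(0, sigma^2) fire intercepts, logit-linear outcomes.

    ``beta`` maps "intercept"/covariate names to coefficients on the raw
    (= generated) scale; the offset log(area) is always included.
    """
    rng = np.random.default_rng(seed)
    n = n_fires * plots_per_fire
    fid = np.repeat([f"F{i:03d}" for i in range(n_fires)], plots_per_fire)
    tab = pd.DataFrame({"fire_id": fid, "area_m2": area})
    eta = np.full(n, beta.get("intercept", 0.0)) + np.log(tab["area_m2"])
    for c in covariates:
        tab[c] = rng.normal(size=n)
        eta = eta + beta.get(c, 0.0) * tab[c]
    for key, b in beta.items():
        if ":" in key:  # product terms, e.g. "deficit_z:rbr"
            a, c = key.split(":", 1)
            eta = eta + b * tab[a] * tab[c]
    b = rng.normal(0.0, sigma, size=n_fires)
    eta = eta + np.repeat(b, plots_per_fire)
    tab["presence"] = (rng.uniform(size=n) < expit(eta)).astype(int)
    return tab


def manual_fit(table, spec, coef, sigma=0.0, cov_scale=1e-8):
    """A FittedGLMM with prescribed standardized-scale coefficients.

    Used to test prediction/projection logic independently of estimation.
    """
    d = dataset.build_design(table, spec, require_response=False)
    names = list(d.X.columns)
    beta = pd.Series([coef.get(c, 0.0) for c in names], index=names)
    labels = pd.unique(d.groups)
    return glmm.FittedGLMM(
        coef=beta, sigma=sigma,
        cov=pd.DataFrame(np.eye(len(names)) * cov_scale, index=names,
                         columns=names),
        loglik=np.nan, group_modes=pd.Series(0.0, index=labels),
        scaler=d.scaler, spec=spec, n_obs=len(table), n_groups=len(labels))


@pytest.fixture
def rng():
    return np.random.default_rng(20230306)


@pytest.fixture
def monthly_series():
    """One site, 1979-2020, deterministic seasonal climate."""
    from regenfire.synthetic import generate_climate_series
    clim = generate_climate_series(1, trend=0.0, seed=11,
                                   year_range=(1979, 2020))
    return clim[clim["site"] == "S0000"].reset_index(drop=True)
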