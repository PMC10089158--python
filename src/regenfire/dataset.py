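"""Modeling-table assembly: inclusion filters, design matrices, screening.

The modeling table is one row per plot.  Plot inclusion follows the survey
protocol: burned (wildfire, not prescribed) plots only, no postfire planting,
fire years 1984-2018, surveyed at least 2 y postfire.  Continuous predictors
are standardized (mean 0, sd 1) before fitting; categorical predictors are
dummy-coded against a stated reference level; quadratics and interactions are
built from the standardized columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Term", "ModelSpec", "DesignMatrices", "apply_inclusion_filters",
           "build_design", "collinearity_screen"]

REQUIRED_FILTER_COLUMNS = ["burned", "planted", "fire_year", "survey_year"]

#: dummy-coding reference level for prefire disturbance
DISTURBANCE_REFERENCE = "none"

#: roles drive selection: biophysical terms are never removal candidates
ROLES = ("biophysical", "climate_mean", "climate_post")


def apply_inclusion_filters(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the four plot-inclusion rules; returns (kept, exclusion log).

    Rules, applied in order so the log counts sum to the rows dropped:
    unburned controls out; planted plots out; fire year within 1984-2018;
    survey at least 2 y after fire.
    """
    missing = [c for c in REQUIRED_FILTER_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    log: dict[str, int] = {}
    df = raw

    rules = [
        ("unburned_control", df["burned"].astype(bool)),
    ]
    kept = df[rules[0][1]]
    log["unburned_control"] = len(df) - len(kept)

    m = ~kept["planted"].astype(bool)
    log["planted"] = int((~m).sum())
    kept = kept[m]

    m = kept["fire_year"].between(1984, 2018)
    log["fire_year_out_of_range"] = int((~m).sum())
    kept = kept[m]

    tsf = kept["survey_year"] - kept["fire_year"]
    m = tsf >= 2
    log["surveyed_lt_2y_postfire"] = int((~m).sum())
    kept = kept[m]

    return kept.reset_index(drop=True), log


@dataclass(frozen=True)
class Term:
    """One fixed-effect term: a covariate, optionally with a quadratic."""
    name: str
    quadratic: bool = False
    categorical: bool = False
    role: str = "biophysical"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown term role '{self.role}'")


@dataclass
class ModelSpec:
    """Term structure of a recruitment model.

    The offset is always log(plot area) and the random grouping is fire id;
    interactions must have both parents present as fixed terms (hierarchy).
    """
    response: str = "presence"
    terms: tuple = ()
    interactions: tuple = ()  # pairs of covariate names
    offset_col: str = "area_m2"
    group_col: str = "fire_id"
    variety: bool = False

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(names) != len(set(names)):
            raise ValueError("duplicated fixed terms")
        if len(self.interactions) != len(set(self.interactions)):
            raise ValueError("duplicated interaction terms")
        for a, b in self.interactions:
            for c in (a, b):
                if c not in names:
                    raise ValueError(
                        f"interaction ({a},{b}) violates hierarchy: '{c}' "
                        "is not a fixed term")

    # -- selection helpers -------------------------------------------------
    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def removable_terms(self) -> list[str]:
        """Main effects eligible for removal: non-biophysical, not a parent
        of any retained interaction."""
        parents = {c for pair in self.interactions for c in pair}
        return [t.name for t in self.terms
                if t.role != "biophysical" and t.name not in parents]

    def drop_term(self, name: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t.name != name))

    def drop_interaction(self, pair: tuple) -> "ModelSpec":
        return replace(self, interactions=tuple(
            p for p in self.interactions if p != pair))

    def add_interaction(self, pair: tuple) -> "ModelSpec":
        return replace(self, interactions=self.interactions + (pair,))

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": [vars(t).copy() for t in self.terms],
            "interactions": [list(p) for p in self.interactions],
            "offset_col": self.offset_col,
            "group_col": self.group_col,
            "variety": self.variety,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(response=d["response"],
                   terms=tuple(Term(**t) for t in d["terms"]),
                   interactions=tuple(tuple(p) for p in d["interactions"]),
                   offset_col=d["offset_col"], group_col=d["group_col"],
                   variety=d["variety"])


@dataclass
class DesignMatrices:
    """Design matrix plus everything needed to refit and re-predict."""
    X: pd.DataFrame            # includes the intercept column
    y: np.ndarray
    offset: np.ndarray         # log(area m2)
    groups: np.ndarray
    scaler: dict               # covariate -> (mean, sd) on the raw scale
    spec: ModelSpec


def _standardize(col: np.ndarray, name: str,
                 scaler: dict | None) -> tuple[np.ndarray, tuple]:
    if scaler is not None and name in scaler:
        mu, sd = scaler[name]
    else:
        mu = float(np.mean(col))
        sd = float(np.std(col, ddof=1))
        if sd == 0:
            raise ValueError(f"zero-variance covariate '{name}'")
    return (col - mu) / sd, (mu, sd)


def build_design(table: pd.DataFrame, spec: ModelSpec,
                 scaler: dict | None = None,
                 require_response: bool = True) -> DesignMatrices:
    """Build the standardized design matrix for a model spec.

    When ``scaler`` is given (means/sds from a training table), it is applied
    instead of refitting the standardization — used for out-of-fold
    prediction and projection.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    out_scaler: dict[str, tuple] = {}
    std: dict[str, np.ndarray] = {}

    for t in spec.terms:
        if t.name not in table.columns:
            raise ValueError(f"term '{t.name}' not found in table")
        if t.categorical:
            levels = sorted(x for x in table[t.name].unique())
            ref = DISTURBANCE_REFERENCE if DISTURBANCE_REFERENCE in levels else levels[0]
            known = _known_levels(spec, t.name, scaler)
            if known is not None:
                unseen = set(levels) - set(known["levels"])
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(unseen)} for '{t.name}'")
                levels, ref = known["levels"], known["ref"]
            out_scaler[f"levels::{t.name}"] = {"levels": levels, "ref": ref}
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{t.name}[{lev}]"] = (table[t.name] == lev).to_numpy(float)
        else:
            raw = table[t.name].to_numpy(dtype=float)
            z, ms = _standardize(raw, t.name, scaler)
            out_scaler[t.name] = ms
            std[t.name] = z
            cols[t.name] = z
            if t.quadratic:
                cols[f"{t.name}^2"] = z**2

    for a, b in spec.interactions:
        for c in (a, b):
            if c not in std:
                raise ValueError(
                    f"interaction ({a},{b}) requires continuous term '{c}'")
        cols[f"{a}:{b}"] = std[a] * std[b]

    X = pd.DataFrame(cols, index=table.index)
    if spec.offset_col not in table.columns:
        raise ValueError(f"offset column '{spec.offset_col}' not found")
    area = table[spec.offset_col].to_numpy(dtype=float)
    if (area <= 0).any():
        raise ValueError("plot areas must be positive")
    offset = np.log(area)

    y = (table[spec.response].to_numpy(dtype=int)
         if (require_response and spec.response in table.columns)
         else np.zeros(len(table), dtype=int))
    if require_response and spec.response not in table.columns:
        raise ValueError(f"response column '{spec.response}' not found")
    groups = (table[spec.group_col].to_numpy()
              if spec.group_col in table.columns else np.zeros(len(table)))
    return DesignMatrices(X=X, y=y, offset=offset, groups=groups,
                          scaler=(scaler if scaler is not None else out_scaler),
                          spec=spec)


def _known_levels(spec: ModelSpec, name: str, scaler: dict | None):
    if scaler is None:
        return None
    return scaler.get(f"levels::{name}")


def collinearity_screen(X: pd.DataFrame, r_max: float = 0.6,
                        vif_max: float = 5.0,
                        priority: list[str] | None = None,
                        auto_drop: bool = False) -> dict:
    """Pairwise-correlation and VIF screening of continuous design columns.

    Flags every pair with \\|r\\| >= ``r_max`` and every column with
    VIF >= ``vif_max``.  Advisory by default; with ``auto_drop`` the
    lower-priority member of each flagged pair (later in ``priority``, which
    defaults to column order) is dropped, deterministically.
    """
    cols = [c for c in X.columns if c != "intercept"]
    if len(cols) < 2:
        raise ValueError("need >= 2 continuous columns to screen")
    Z = X[cols].to_numpy(dtype=float)
    sds = Z.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"constant column(s): {bad}")

    from statsmodels.stats.outliers_influence import variance_inflation_factor
    Zc = np.column_stack([np.ones(len(Z)), Z])
    vifs = {c: float(variance_inflation_factor(Zc, i + 1))
            for i, c in enumerate(cols)}

    corr = np.corrcoef(Z, rowvar=False)
    flagged_pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) >= r_max:
                flagged_pairs.append((cols[i], cols[j], float(corr[i, j])))
    flagged_vif = [c for c in cols if vifs[c] >= vif_max]

    prio = priority or cols
    rank = {c: prio.index(c) if c in prio else len(prio) for c in cols}
    dropped: list[str] = []
    if auto_drop:
        for a, b, _ in flagged_pairs:
            loser = a if rank[a] > rank[b] else b
            if loser not in dropped:
                dropped.append(loser)
    return {"pairs": flagged_pairs, "vif": vifs, "flagged_vif": flagged_vif,
            "dropped": dropped,
            "retained": [c for c in cols if c not in dropped]}
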