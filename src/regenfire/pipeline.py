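"""End-to-end pipeline: simulate -> metrics -> assemble -> fit -> select ->
threshold -> project, with reproducible configuration and stage caching.

Every stage derives its own seed from the global seed by stable hashing of
the stage name, so stage outputs are reproducible independently of execution
order.  Each stage records a hash of its configuration and input files in
``manifest.json``; a rerun with an unchanged hash and intact outputs reuses
the cached files, and corrupting any cached file invalidates that stage and
its descendants.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic, water_balance, dataset, glmm, selection, thresholds, projection
from .dataset import ModelSpec, Term

__all__ = ["RunConfig", "run_pipeline", "STAGES", "default_model_spec"]

STAGES = ["simulate", "metrics", "assemble", "fit", "select", "threshold",
          "project"]

_STAGE_INPUTS = {
    "simulate": [],
    "metrics": ["fires.csv", "climate.csv"],
    "assemble": ["plots.csv", "metrics.csv"],
    "fit": ["modeling_table.csv"],
    "select": ["modeling_table.csv"],
    "threshold": ["modeling_table.csv", "model_selected.json"],
    "project": ["model_selected.json", "thresholds.json", "fires.csv",
                "climate.csv"],
}
_STAGE_OUTPUTS = {
    "simulate": ["plots.csv", "fires.csv", "climate.csv", "truth.yaml"],
    "metrics": ["metrics.csv"],
    "assemble": ["modeling_table.csv", "screening.json", "exclusions.json"],
    "fit": ["model_full.json"],
    "select": ["model_selected.json", "selection_trace.json"],
    "threshold": ["thresholds.json"],
    "project": ["projections.csv", "region_summary.csv"],
}

DEFAULT_POSTFIRE_METRICS = [
    "max_postfire_gs_deficit_z", "min_postfire_gs_deficit_z",
    "max_postfire_summer_vpd_z", "min_postfire_summer_vpd_z",
    "max_postfire_gs_precip_z", "min_postfire_gs_precip_z",
]


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""
    seed: int = 20230306
    outdir: str = "results/pipeline"
    # synthetic-study conditions
    n_fires: int = 100
    plots_per_fire: int = 20
    random_intercept_sd: float = 0.7
    fixed_coefficients: dict = field(default_factory=lambda: {
        "intercept": -4.0,
        "dist_seed_m": -0.004,          # per m: farther seed source, less recruitment
        "tree_cover_pct": 0.03,         # per %, more surviving canopy helps
        "rbr": -0.002,                  # per RBR unit: severity hurts
        "time_since_fire": 0.10,        # per year
        "chili": -0.002,
        "mean_annual_deficit_mm": -0.004,   # per mm: drier sites recruit less
        "max_postfire_gs_deficit_z": -0.5,  # a hot dry postfire year hurts
        "min_postfire_gs_precip_z": 0.0,
    })
    temp_trend_c_per_decade: float = 0.35
    # water balance
    whc_mm: float = 150.0
    latitude: float = 45.0
    # model structure
    postfire_metrics: list = field(default_factory=lambda: list(DEFAULT_POSTFIRE_METRICS))
    mean_climate_metric: str = "mean_annual_deficit_mm"
    quadratic_terms: list = field(default_factory=lambda: ["time_since_fire",
                                                           "dist_seed_m"])
    use_disturbance: bool = True
    use_variety: bool = True
    # selection / thresholds / projection
    cv_folds: int = 10
    threshold_method: str = "max_kappa"
    threshold_source: str = "cv"        # "cv" (out-of-fold) or "insample"
    periods: list = field(default_factory=lambda: list(projection.PERIODS))
    pdp_draws: int = 1000

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        return cls(**yaml.safe_load(text))

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(h[:8], 16) % (2**31)

    def truth(self) -> synthetic.TruthParams:
        return synthetic.TruthParams(
            fixed_coefficients=dict(self.fixed_coefficients),
            random_intercept_sd=self.random_intercept_sd,
            n_fires=self.n_fires, plots_per_fire=self.plots_per_fire,
            temp_trend_c_per_decade=self.temp_trend_c_per_decade,
            seed=self.stage_seed("simulate"))


def default_model_spec(config: RunConfig) -> ModelSpec:
    """The full starting model: protected biophysical terms, climate mains,
    and mean-climate x postfire-climate interactions."""
    terms = [
        Term("time_since_fire", quadratic="time_since_fire" in config.quadratic_terms),
        Term("dist_seed_m", quadratic="dist_seed_m" in config.quadratic_terms),
        Term("rbr", quadratic="rbr" in config.quadratic_terms),
        Term("tree_cover_pct", quadratic="tree_cover_pct" in config.quadratic_terms),
        Term("chili"),
    ]
    if config.use_disturbance:
        terms.append(Term("disturbance", categorical=True))
    if config.use_variety:
        terms.append(Term("variety", categorical=True))
    terms.append(Term(config.mean_climate_metric, role="climate_mean"))
    for m in config.postfire_metrics:
        terms.append(Term(m, role="climate_post"))
    interactions = tuple((config.mean_climate_metric, m)
                         for m in config.postfire_metrics)
    return ModelSpec(terms=tuple(terms), interactions=interactions,
                     variety=config.use_variety)


# --------------------------------------------------------------------------
# stage implementations (each: config, outdir -> writes its declared outputs)

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def stage_simulate(config: RunConfig, out: Path) -> None:
    ds = synthetic.make_dataset(config.truth())
    _write_csv(ds.plots, out / "plots.csv")
    _write_csv(ds.fires, out / "fires.csv")
    _write_csv(ds.climate, out / "climate.csv")
    (out / "truth.yaml").write_text(yaml.safe_dump(ds.truth.to_dict(),
                                                   sort_keys=True))


def stage_metrics(config: RunConfig, out: Path) -> None:
    fires = pd.read_csv(out / "fires.csv")
    climate = pd.read_csv(out / "climate.csv")
    rows = []
    for _, f in fires.iterrows():
        series = climate[climate["site"] == f["site"]].reset_index(drop=True)
        m = water_balance.compute_climate_metrics(
            series, int(f["fire_year"]), latitude=config.latitude,
            whc=config.whc_mm)
        m.update({"site": f["site"], "fire_id": f["fire_id"]})
        rows.append(m)
    _write_csv(pd.DataFrame(rows), out / "metrics.csv")


def stage_assemble(config: RunConfig, out: Path) -> None:
    plots = pd.read_csv(out / "plots.csv")
    metrics = pd.read_csv(out / "metrics.csv")
    kept, log = dataset.apply_inclusion_filters(plots)
    # metrics are recomputed by the pipeline; drop any generator-provided copies
    dup = [c for c in metrics.columns if c in kept.columns and c != "fire_id"]
    table = kept.drop(columns=dup).merge(metrics.drop(columns=["site"]),
                                         on="fire_id", how="left")
    n_missing = int(table.isna().any(axis=1).sum())
    table = table.dropna().reset_index(drop=True)
    log["missing_covariates"] = n_missing
    _write_csv(table, out / "modeling_table.csv")
    (out / "exclusions.json").write_text(json.dumps(log, indent=1))

    spec = default_model_spec(config)
    design = dataset.build_design(table, spec)
    cont = [c for c in design.X.columns
            if ("^2" not in c and ":" not in c and "[" not in c)]
    report = dataset.collinearity_screen(design.X[cont])
    (out / "screening.json").write_text(json.dumps(report, indent=1,
                                                   default=str))


def stage_fit(config: RunConfig, out: Path) -> None:
    table = pd.read_csv(out / "modeling_table.csv")
    spec = default_model_spec(config)
    fitted = glmm.fit_glmm(table, spec, on_fail="warn")
    fitted.to_json(out / "model_full.json")


def stage_select(config: RunConfig, out: Path) -> None:
    table = pd.read_csv(out / "modeling_table.csv")
    spec = default_model_spec(config)
    trace = selection.backward_select(spec, table, k=config.cv_folds,
                                      seed=config.stage_seed("select"))
    fitted = glmm.fit_glmm(table, trace.final_spec, on_fail="warn")
    fitted.to_json(out / "model_selected.json")
    doc = {"initial_cv_auc": trace.initial_cv_auc,
           "final_cv_auc": trace.final_cv_auc,
           "steps": trace.to_records(),
           "final_spec": trace.final_spec.to_dict()}
    (out / "selection_trace.json").write_text(json.dumps(doc, indent=1))


def stage_threshold(config: RunConfig, out: Path) -> None:
    table = pd.read_csv(out / "modeling_table.csv")
    fitted = glmm.FittedGLMM.from_json(out / "model_selected.json")
    if config.threshold_source == "cv":
        res = selection.cv_auc(fitted.spec, table, k=config.cv_folds,
                               seed=config.stage_seed("select"))
        probs, labels = res.oof_prob, res.oof_label
    else:
        probs = glmm.predict_probability(fitted, table, level="population")
        labels = table[fitted.spec.response].to_numpy(int)
    doc = {}
    for method in thresholds.METHODS:
        doc[method] = thresholds.select_threshold(probs, labels, method).to_dict()
    (out / "thresholds.json").write_text(json.dumps(doc, indent=1))


def stage_project(config: RunConfig, out: Path) -> None:
    fitted = glmm.FittedGLMM.from_json(out / "model_selected.json")
    fires = pd.read_csv(out / "fires.csv")
    climate = pd.read_csv(out / "climate.csv")
    tdoc = json.loads((out / "thresholds.json").read_text())
    thr = tdoc[config.threshold_method]["threshold"]

    # synthetic "study area": one projection site per climate site, region
    # labels by thirds of the site index
    annual = {
        f["site"]: water_balance.annual_aggregates(
            climate[climate["site"] == f["site"]].reset_index(drop=True),
            latitude=config.latitude, whc=config.whc_mm)
        for _, f in fires.iterrows()}
    frames = []
    for period in config.periods:
        rows = []
        for _, f in fires.iterrows():
            m = projection.period_climate_metrics(
                None, projection.PERIODS[period], annual=annual[f["site"]])
            m["site"] = f["site"]
            rows.append(m)
        sites = pd.DataFrame(rows)
        sites["chili"] = 128.0
        sites["disturbance"] = "none"
        sites["variety"] = "typical"
        idx = np.arange(len(sites))
        sites["region"] = np.array(["west", "center", "east"])[
            (3 * idx // max(len(sites), 1)).clip(0, 2)]
        p_low = projection.project_scenario(
            fitted, sites, projection.Scenario("low", period))
        p_high = projection.project_scenario(
            fitted, sites, projection.Scenario("high", period))
        cat = projection.classify_sites(p_low, p_high, thr)
        cat["site"] = sites["site"].to_numpy()
        cat["region"] = sites["region"].to_numpy()
        cat["period"] = period
        frames.append(cat)
    allcat = pd.concat(frames, ignore_index=True)
    _write_csv(allcat, out / "projections.csv")
    summaries = []
    for period, sub in allcat.groupby("period"):
        s = projection.area_summary(sub, region=sub["region"].to_numpy())
        s = s.reset_index().assign(period=period)
        summaries.append(s)
    _write_csv(pd.concat(summaries, ignore_index=True),
               out / "region_summary.csv")


_STAGE_FN = {
    "simulate": stage_simulate, "metrics": stage_metrics,
    "assemble": stage_assemble, "fit": stage_fit, "select": stage_select,
    "threshold": stage_threshold, "project": stage_project,
}

_STAGE_CONFIG_KEYS = {
    "simulate": ["seed", "n_fires", "plots_per_fire", "random_intercept_sd",
                 "fixed_coefficients", "temp_trend_c_per_decade"],
    "metrics": ["whc_mm", "latitude"],
    "assemble": ["postfire_metrics", "mean_climate_metric", "quadratic_terms",
                 "use_disturbance", "use_variety"],
    "fit": ["postfire_metrics", "mean_climate_metric", "quadratic_terms",
            "use_disturbance", "use_variety"],
    "select": ["cv_folds", "postfire_metrics", "mean_climate_metric",
               "quadratic_terms", "use_disturbance", "use_variety", "seed"],
    "threshold": ["threshold_method", "threshold_source", "cv_folds", "seed"],
    "project": ["periods", "threshold_method", "whc_mm", "latitude"],
}


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_hash(config: RunConfig, stage: str, out: Path) -> str:
    cfg = {k: getattr(config, k) for k in _STAGE_CONFIG_KEYS[stage]}
    payload = json.dumps(cfg, sort_keys=True, default=str)
    for fname in _STAGE_INPUTS[stage]:
        p = out / fname
        payload += f"|{fname}:{_file_hash(p) if p.exists() else 'missing'}"
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig, stages: list | None = None,
                 force: bool = False) -> dict:
    """Execute the pipeline in dependency order; returns the run manifest.

    Stages whose configuration hash and output hashes match the cached
    manifest are skipped; any mismatch (including a corrupted output file)
    recomputes the stage, and the changed outputs then invalidate descendant
    stages through their input hashes.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    wanted = stages or STAGES

    for stage in STAGES:
        if stage not in wanted:
            continue
        h = _stage_hash(config, stage, out)
        rec = manifest["stages"].get(stage)
        outputs = [out / f for f in _STAGE_OUTPUTS[stage]]
        cached = (not force and rec is not None and rec["hash"] == h
                  and all(p.exists() for p in outputs)
                  and all(_file_hash(p) == rec["outputs"].get(p.name)
                          for p in outputs))
        if cached:
            continue
        t0 = time.time()
        try:
            _STAGE_FN[stage](config, out)
        except Exception as exc:
            manifest["stages"][stage] = {"hash": None, "outputs": {},
                                         "error": str(exc)}
            manifest_path.write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "hash": _stage_hash(config, stage, out),
            "outputs": {p.name: _file_hash(p) for p in outputs},
            "seconds": round(time.time() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
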