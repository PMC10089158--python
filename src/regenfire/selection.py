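"""Cross-validated AUC and backward model selection.

Model skill is the area under the ROC curve of out-of-fold predictions from
10-fold cross-validation.  Folds partition *fires*, not plots: plots within a
fire share a random intercept, so plot-level folds would leak group
information and inflate AUC.  Selection proceeds in two phases: greedy
backward removal of climate terms and climate x mean-climate interactions
(biophysical terms are never candidates), then a forward check of postfire
climate x severity/seed-availability interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import ModelSpec, build_design
from .glmm import fit_glmm_design, predict_probability, ConvergenceError

__all__ = ["auc", "cv_auc", "backward_select", "SelectionTrace", "CVResult"]

#: severity / seed-availability covariates probed for interactions in phase 2
SEVERITY_SEED_TERMS = ("rbr", "dist_seed_m", "tree_cover_pct")


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def make_fire_folds(fires: np.ndarray, k: int, seed: int) -> dict:
    """Deterministic partition of fire ids into k folds."""
    uniq = np.array(sorted(pd.unique(fires)))
    if len(uniq) < k:
        raise ValueError(f"need >= {k} fires for {k}-fold CV, have {len(uniq)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(perm, k)):
        for i in chunk:
            assignment[uniq[i]] = fold
    return assignment


@dataclass
class CVResult:
    mean_auc: float
    fold_aucs: list
    skipped_folds: list
    oof_prob: np.ndarray       # out-of-fold probabilities, aligned to table
    oof_label: np.ndarray


def cv_auc(spec: ModelSpec, table: pd.DataFrame, k: int = 10,
           seed: int = 20230306, folds: dict | None = None,
           start: np.ndarray | None = None) -> CVResult:
    """Grouped k-fold cross-validated AUC with population-level prediction.

    Each fold is scored by a model fitted on the remaining folds; a fold with
    a single outcome class is skipped with a warning.  ``folds`` may be
    supplied so competing specs are compared on identical partitions.
    """
    if folds is None:
        folds = make_fire_folds(table[spec.group_col].to_numpy(), k, seed)
    fold_of = table[spec.group_col].map(folds).to_numpy()

    oof_prob = np.full(len(table), np.nan)
    y_all = table[spec.response].to_numpy(int)
    fold_aucs, skipped = [], []
    warm = start
    for fold in sorted(set(folds.values())):
        test = fold_of == fold
        train_tab = table[~test]
        design = build_design(train_tab, spec)
        fitted = fit_glmm_design(design, gtol=1e-5, compute_cov=False,
                                 start=warm, on_fail="warn")
        # successive folds see near-identical data; reuse the solution
        warm = np.append(fitted.coef.to_numpy(),
                         np.log(max(fitted.sigma, 1e-4)))
        p = predict_probability(fitted, table[test], level="population")
        oof_prob[test] = p
        y = y_all[test]
        if y.min() == y.max():
            skipped.append(fold)
            warnings.warn(f"fold {fold} has a single outcome class; skipped")
            continue
        fold_aucs.append(auc(p, y))
    if not fold_aucs:
        raise ValueError("no scorable folds (every fold single-class)")
    return CVResult(mean_auc=float(np.mean(fold_aucs)), fold_aucs=fold_aucs,
                    skipped_folds=skipped, oof_prob=oof_prob, oof_label=y_all)


@dataclass
class SelectionStep:
    action: str               # "remove" or "add"
    candidate: str
    cv_auc: float
    fold_aucs: list
    accepted: bool


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_cv_auc: float = np.nan
    initial_cv_auc: float = np.nan

    def to_records(self) -> list:
        return [{"action": s.action, "candidate": s.candidate,
                 "cv_auc": s.cv_auc, "accepted": s.accepted}
                for s in self.steps]


def _interaction_label(pair: tuple) -> str:
    return f"{pair[0]}:{pair[1]}"


def _phase1_candidates(spec: ModelSpec) -> list:
    """Removable items, interactions first (hierarchy), then lexicographic."""
    cands = [("interaction", p) for p in sorted(spec.interactions)]
    cands += [("term", n) for n in sorted(spec.removable_terms())]
    return cands


def _apply_removal(spec: ModelSpec, kind: str, item) -> ModelSpec:
    return spec.drop_interaction(item) if kind == "interaction" else spec.drop_term(item)


def _warm_start(spec: ModelSpec, table: pd.DataFrame):
    design = build_design(table, spec)
    try:
        fitted = fit_glmm_design(design, gtol=1e-5, compute_cov=False,
                                 on_fail="warn")
        return np.append(fitted.coef.to_numpy(),
                         np.log(max(fitted.sigma, 1e-4)))
    except (ConvergenceError, ValueError):
        return None


def backward_select(full_spec: ModelSpec, table: pd.DataFrame, k: int = 10,
                    seed: int = 20230306) -> SelectionTrace:
    """Two-phase greedy selection maximizing cross-validated AUC.

    Phase 1 repeatedly removes the single climate term or climate
    interaction whose removal most increases CV AUC, stopping when no removal
    helps.  Phase 2 then tests adding each remaining postfire-climate x
    {severity, seed availability} interaction, keeping additions that
    increase CV AUC.  Ties break toward removing higher-order terms first,
    then lexicographically (the candidate enumeration order).  Candidate fits
    that fail are marked infeasible and skipped.
    """
    folds = make_fire_folds(table[full_spec.group_col].to_numpy(), k, seed)
    trace = SelectionTrace()
    current = full_spec
    best = cv_auc(current, table, k=k, seed=seed, folds=folds)
    trace.initial_cv_auc = best.mean_auc

    # phase 1: backward removal of climate terms and their interactions
    while True:
        candidates = _phase1_candidates(current)
        if not candidates:
            break
        results = []
        for kind, item in candidates:
            cand_spec = _apply_removal(current, kind, item)
            label = _interaction_label(item) if kind == "interaction" else item
            try:
                res = cv_auc(cand_spec, table, k=k, seed=seed, folds=folds)
            except (ConvergenceError, ValueError) as exc:
                trace.steps.append(SelectionStep(
                    "remove", label, np.nan, [], False))
                warnings.warn(f"candidate removal '{label}' infeasible: {exc}")
                continue
            results.append((res.mean_auc, kind, item, label, res))
        if not results:
            break
        # candidate order already encodes the tie-break preference
        best_auc = max(r[0] for r in results)
        winner = next(r for r in results if r[0] == best_auc)
        improved = best_auc > best.mean_auc
        for mean_a, kind, item, label, res in results:
            accepted = improved and (label == winner[3])
            trace.steps.append(SelectionStep("remove", label, mean_a,
                                             res.fold_aucs, accepted))
        if not improved:
            break
        current = _apply_removal(current, winner[1], winner[2])
        best = winner[4]

    # phase 2: postfire climate x severity/seed-availability interactions
    post_terms = [t.name for t in current.terms if t.role == "climate_post"]
    sev_terms = [t.name for t in current.terms if t.name in SEVERITY_SEED_TERMS]
    for clim in sorted(post_terms):
        for sev in sorted(sev_terms):
            pair = (clim, sev)
            if pair in current.interactions or (sev, clim) in current.interactions:
                continue
            cand_spec = current.add_interaction(pair)
            label = _interaction_label(pair)
            try:
                res = cv_auc(cand_spec, table, k=k, seed=seed, folds=folds)
            except (ConvergenceError, ValueError) as exc:
                trace.steps.append(SelectionStep("add", label, np.nan, [], False))
                warnings.warn(f"candidate addition '{label}' infeasible: {exc}")
                continue
            accepted = res.mean_auc > best.mean_auc
            trace.steps.append(SelectionStep("add", label, res.mean_auc,
                                             res.fold_aucs, accepted))
            if accepted:
                current = cand_spec
                best = res

    trace.final_spec = current
    trace.final_cv_auc = best.mean_auc
    return trace
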