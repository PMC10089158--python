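"""Presence/absence probability cutoffs.

A site is called "likely to regenerate" when its predicted probability
strictly exceeds a cutoff.  Two standard cutoff rules are provided: the
threshold maximizing Cohen's kappa and the threshold maximizing sensitivity
+ specificity (Youden's J + 1).  Both objectives are step functions of the
cutoff, so scanning the finite candidate set (midpoints between adjacent
sorted unique probabilities, plus 0 and 1) finds the exact maximum; ties go
to the smallest cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["cohens_kappa", "select_threshold", "ThresholdResult", "METHODS"]

METHODS = ("max_kappa", "max_sens_spec")


def cohens_kappa(confusion) -> float:
    """Chance-corrected agreement from a 2x2 table [[TP, FN], [FP, TN]].

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from the
    marginal products.  Degenerate marginals (p_e = 1) return 0 with a
    warning rather than 0/0.
    """
    (tp, fn), (fp, tn) = np.asarray(confusion, dtype=float)
    n = tp + fn + fp + tn
    if n <= 0:
        raise ValueError("confusion table must have positive total count")
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / (n * n)
    if pe >= 1.0:
        warnings.warn("degenerate marginals (expected agreement = 1); kappa = 0")
        return 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass
class ThresholdResult:
    method: str
    threshold: float
    kappa: float
    sensitivity: float
    specificity: float
    confusion: tuple  # (tp, fn, fp, tn)

    def to_dict(self) -> dict:
        return {"method": self.method, "threshold": self.threshold,
                "kappa": self.kappa, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "confusion": list(self.confusion)}


def _confusion_at(probs, labels, t):
    pred = probs > t
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fn, fp, tn


def candidate_thresholds(probs: np.ndarray) -> np.ndarray:
    """Complete candidate set for step-function objectives."""
    u = np.unique(probs)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.array([])
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def select_threshold(probs, labels, method: str = "max_kappa") -> ThresholdResult:
    """Exact maximizer of the chosen objective over all candidate cutoffs.

    Classification is "likely" when probability strictly exceeds the cutoff.
    Among tied maximizers the smallest cutoff is returned.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got '{method}'")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("threshold selection requires both classes present")

    best = None
    for t in candidate_thresholds(probs):
        tp, fn, fp, tn = _confusion_at(probs, labels, t)
        sens = tp / (tp + fn)
        spec = tn / (fp + tn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kap = cohens_kappa([[tp, fn], [fp, tn]])
        obj = kap if method == "max_kappa" else sens + spec
        if best is None or obj > best[0] + 1e-15:
            best = (obj, t, kap, sens, spec, (tp, fn, fp, tn))
    _, t, kap, sens, spec, conf = best
    return ThresholdResult(method=method, threshold=float(t), kappa=kap,
                           sensitivity=sens, specificity=spec, confusion=conf)
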