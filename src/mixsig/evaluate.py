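"""ROC/AUC machinery, Youden cutpoint, classification metrics,
smoothed-bootstrap confidence intervals, and permutation importance.

Conventions: higher score means responder; a sample is called positive
when its score is >= the cutpoint; undefined predictive values (empty
denominator) are reported as None, never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationReport:
    """Point estimates with 95% smoothed-bootstrap CIs."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float | None
    sensitivity_ci: tuple[float, float]
    specificity: float | None
    specificity_ci: tuple[float, float]
    ppv: float | None
    ppv_ci: tuple[float, float]
    npv: float | None
    npv_ci: tuple[float, float]
    cutpoint: float
    youden_j: float
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity, "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity, "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv, "ppv_ci": list(self.ppv_ci),
            "npv": self.npv, "npv_ci": list(self.npv_ci),
            "cutpoint": self.cutpoint, "youden_j": self.youden_j,
            "n_boot": self.n_boot,
        }


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=float)
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise EvaluationError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise EvaluationError("both classes must be present")
    return labels == 1, labels == 0


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected probability that a responder outscores a non-responder."""
    pos, neg = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_cutpoint(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold (midpoint scan) maximizing J = sens + spec - 1.

    Candidate thresholds are the midpoints between consecutive distinct
    scores; J-ties resolve to the lowest threshold.
    """
    pos, neg = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores)
    if len(distinct) == 1:
        return float(distinct[0]), 0.0
    cands = (distinct[:-1] + distinct[1:]) / 2.0
    best_cut, best_j = cands[0], -np.inf
    n_pos, n_neg = pos.sum(), neg.sum()
    for c in cands:
        called = scores >= c
        j = (called & pos).sum() / n_pos + (~called & neg).sum() / n_neg - 1.0
        if j > best_j + 1e-12:
            best_cut, best_j = c, j
    return float(best_cut), float(best_j)


def classification_metrics(scores: np.ndarray, labels: np.ndarray,
                           cutpoint: float) -> dict[str, float | None]:
    """2x2 rates at ``score >= cutpoint`` -> positive call."""
    pos, neg = _check_two_classes(labels)
    if not np.isfinite(cutpoint):
        raise EvaluationError("cutpoint must be finite")
    called = np.asarray(scores, dtype=float) >= cutpoint
    tp = int((called & pos).sum())
    fn = int((~called & pos).sum())
    tn = int((~called & neg).sum())
    fp = int((called & neg).sum())
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp > 0 else None,
        "npv": tn / (tn + fn) if tn + fn > 0 else None,
    }


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0.0:
        return 0.0
    return 0.9 * spread * n ** (-0.2)


def smoothed_bootstrap_ci(scores: np.ndarray, labels: np.ndarray,
                          metric: Callable[[np.ndarray, np.ndarray], float],
                          n_boot: int = 1000, seed: int = 0,
                          bandwidth: float | None = None,
                          max_redraws: int = 100) -> tuple[float, float]:
    """Percentile 95% CI from a smoothed bootstrap.

    (score, label) pairs are resampled with replacement; Gaussian kernel
    noise (Silverman bandwidth on the observed scores unless overridden) is
    added to the resampled *scores* only.  Resamples on which the metric is
    undefined are redrawn.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    n = len(scores)
    h = _silverman_bandwidth(scores) if bandwidth is None else float(bandwidth)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            s = scores[idx]
            if h > 0:
                s = s + rng.normal(0.0, h, size=n)
            try:
                vals[b] = metric(s, labels[idx])
                break
            except EvaluationError:
                if attempt == max_redraws - 1:
                    raise EvaluationError("metric undefined on repeated bootstrap resamples")
                log.debug("redrawing degenerate bootstrap resample")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def permutation_importance(model, subset: list[str] | tuple[str, ...],
                           X: pd.DataFrame, y: pd.Series,
                           n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Mean AUC decrease when one feature's column is permuted.

    The subset score uses the model's fixed coefficients; a feature with a
    zero coefficient therefore has importance exactly 0.
    """
    yv = np.asarray(y, dtype=float)
    _check_two_classes(yv)
    subset = list(subset)
    missing = [f for f in subset if f not in model.coefficients.index]
    if missing:
        raise EvaluationError(f"feature(s) not in the model: {missing[:5]}")
    beta = model.coefficients[subset].to_numpy()
    Xv = X[subset].to_numpy(dtype=float)
    base_score = Xv @ beta
    base_auc = roc_auc(base_score, yv)
    rng = np.random.default_rng(seed)

    rows = []
    n = len(yv)
    n_pos = int(yv.sum())
    n_neg = n - n_pos
    for j, f in enumerate(subset):
        if beta[j] == 0.0:
            rows.append((f, 0.0, n_perm))
            continue
        partial = base_score - beta[j] * Xv[:, j]
        perms = np.empty((n_perm, n))
        for t in range(n_perm):
            perms[t] = partial + beta[j] * rng.permutation(Xv[:, j])
        ranks = stats.rankdata(perms, axis=1)
        aucs = (ranks[:, yv == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        rows.append((f, float(base_auc - aucs.mean()), n_perm))
    return pd.DataFrame(rows, columns=["feature", "auc_decrease", "n_perm"]).set_index("feature")


def evaluate_scores(scores: np.ndarray, labels: np.ndarray,
                    n_boot: int = 1000, seed: int = 0) -> EvaluationReport:
    """Full report: AUC, Youden cutpoint, 2x2 rates, all with 95% CIs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    cut, j = youden_cutpoint(scores, labels)
    m = classification_metrics(scores, labels, cut)
    auc = roc_auc(scores, labels)

    def metric_at_youden(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
        def fn(s: np.ndarray, lab: np.ndarray) -> float:
            c, _ = youden_cutpoint(s, lab)
            v = classification_metrics(s, lab, c)[name]
            if v is None:
                raise EvaluationError(f"{name} undefined on resample")
            return v
        return fn

    cis = {}
    for i, name in enumerate(["auc", "sensitivity", "specificity", "ppv", "npv"]):
        fn = roc_auc if name == "auc" else metric_at_youden(name)
        cis[name] = smoothed_bootstrap_ci(scores, labels, fn, n_boot=n_boot, seed=seed + i)
    return EvaluationReport(
        auc=auc, auc_ci=cis["auc"],
        sensitivity=m["sensitivity"], sensitivity_ci=cis["sensitivity"],
        specificity=m["specificity"], specificity_ci=cis["specificity"],
        ppv=m["ppv"], ppv_ci=cis["ppv"],
        npv=m["npv"], npv_ci=cis["npv"],
        cutpoint=cut, youden_j=j, n_boot=n_boot)
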