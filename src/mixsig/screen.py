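"""Univariate association screen and greedy correlation pruning.

Each feature is screened with a univariate logistic regression of response
on the (standardized) feature; the likelihood-ratio p-value against the
intercept-only model, the McFadden pseudo-R2 and the orientation-corrected
AUC of the raw feature are recorded.  Features passing the p-value screen
are then pruned greedily — ranked by pseudo-R2 — so that no two kept
features exceed the pairwise correlation ceiling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .config import ScreenConfig
from .errors import ScreeningError
from .normalize import ExpressionMatrix

log = logging.getLogger(__name__)

# total ridge penalty added to the per-feature fits, far below the p-value
# resolution we report but enough to keep separated fits finite
_RIDGE = 1e-6


@dataclass(frozen=True)
class ScreenResult:
    stats: pd.DataFrame        # per feature: p_value, r2, auc, converged
    survivors: tuple[str, ...]


def _rank_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected rank-sum AUC of x as a score for y, oriented >= 0.5."""
    ranks = stats.rankdata(x)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(max(auc, 1.0 - auc))


def _binom_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """-2 log-likelihood of a logistic model with linear predictor eta."""
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def univariate_screen(X: ExpressionMatrix | pd.DataFrame, y: pd.Series | np.ndarray,
                      config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Per-feature logistic screen; survivors have LR p < ``config.p_max``."""
    values = X.values if isinstance(X, ExpressionMatrix) else X
    yv = np.asarray(y, dtype=float)
    if len(np.unique(yv)) < 2:
        raise ScreeningError("response contains a single class")
    if len(yv) <= 3:
        raise ScreeningError("need more than 3 samples to screen")
    if len(yv) != len(values):
        raise ScreeningError("response length does not match sample count")

    n = len(yv)
    ybar = yv.mean()
    null_dev = _binom_deviance(yv, np.full(n, np.log(ybar / (1 - ybar))))
    clf = LogisticRegression(penalty="l2", C=1.0 / _RIDGE, solver="lbfgs",
                             max_iter=2000, tol=1e-10)

    records = []
    arr = values.to_numpy(dtype=float)
    for j, name in enumerate(values.columns):
        x = arr[:, j]
        sd = x.std()
        if sd == 0.0:
            records.append((name, 1.0, 0.0, 0.5, True))
            continue
        xs = ((x - x.mean()) / sd).reshape(-1, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(xs, yv)
            converged = clf.n_iter_[0] < clf.max_iter
        eta = clf.intercept_[0] + xs[:, 0] * clf.coef_[0, 0]
        dev = _binom_deviance(yv, eta)
        lr = max(null_dev - dev, 0.0)
        p = float(stats.chi2.sf(lr, df=1))
        r2 = float(np.clip(1.0 - dev / null_dev, 0.0, 1.0))
        if not converged:
            log.warning("univariate fit did not converge for %s; p set to 1", name)
            p, r2 = 1.0, 0.0
        records.append((name, p, r2, _rank_auc(x, yv), converged))

    table = pd.DataFrame(records, columns=["feature", "p_value", "r2", "auc", "converged"])
    table = table.set_index("feature")
    survivors = tuple(table.index[table["p_value"] < config.p_max])
    return ScreenResult(stats=table, survivors=survivors)


def prune_correlated(X: ExpressionMatrix | pd.DataFrame, screen_stats: pd.DataFrame,
                     config: ScreenConfig = ScreenConfig(),
                     candidates: list[str] | tuple[str, ...] | None = None) -> list[str]:
    """Greedy low-collinearity subset of ``candidates`` (default: all
    features in ``screen_stats``).

    Features are visited in descending rank statistic (pseudo-R2 by
    default; ties broken by higher AUC, then feature id) and kept iff their
    absolute Pearson correlation with every already-kept feature stays
    within the ceiling.  The returned order is the keep order.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else X
    cand = list(candidates) if candidates is not None else list(screen_stats.index)
    missing = [c for c in cand if c not in screen_stats.index]
    if missing:
        raise ScreeningError(f"screen stats missing for candidate(s) {missing[:5]}")
    if not cand:
        return []

    primary, secondary = ("r2", "auc") if config.rank_by == "r2" else ("auc", "r2")
    order = sorted(cand, key=lambda f: (-screen_stats.at[f, primary],
                                        -screen_stats.at[f, secondary], f))
    sub = values[order].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(sub.T))
    corr = np.nan_to_num(corr, nan=0.0)  # constant features correlate with nothing
    threshold = config.r_max if config.corr_scale == "r" else np.sqrt(config.r_max)

    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(corr[i, k] <= threshold for k in kept_idx):
            kept_idx.append(i)
    kept = [order[i] for i in kept_idx]

    # hard post-condition: the kept set is below the correlation ceiling
    if len(kept) > 1:
        sub_corr = np.abs(np.corrcoef(values[kept].to_numpy(dtype=float).T))
        np.fill_diagonal(sub_corr, 0.0)
        assert np.nan_to_num(sub_corr).max() <= threshold + 1e-12
    return kept


def write_screen(result: ScreenResult, kept: list[str], outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.stats.to_csv(out / "univariate_stats.tsv", sep="\t")
    pd.Series(kept, name="feature").to_csv(out / "pruned_features.tsv", sep="\t", index=False)
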