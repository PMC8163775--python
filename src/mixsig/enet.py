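"""Elastic-net model building: (alpha, lambda) tuning by replicated
cross-validation, bootstrap stability selection, and the final sparse fit.

The penalty follows the glmnet convention,

    mean binomial NLL + lambda * [ (1 - alpha)/2 * ||b||_2^2 + alpha * ||b||_1 ],

so alpha = 0.15 means a mostly-ridge blend.  Features are standardized
internally; reported coefficients are mapped back to the expression scale
so that signature scores are plain dot products with the normalized matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import TuningConfig
from .errors import EmptyModelError, MixsigError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElasticNetParams:
    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise MixsigError("alpha must lie in [0, 1]")
        if self.lam <= 0.0:
            raise MixsigError("lambda must be positive")


@dataclass(frozen=True)
class StabilityResult:
    selection_frequency: pd.Series   # feature -> count of bootstraps with b != 0
    model_sizes: np.ndarray          # per-bootstrap non-zero count
    median_size: int
    top_features: tuple[str, ...]    # the median-size most frequent features


@dataclass(frozen=True)
class FittedModel:
    coefficients: pd.Series          # expression-scale b per feature
    intercept: float
    params: ElasticNetParams

    @property
    def nonzero_features(self) -> tuple[str, ...]:
        return tuple(self.coefficients.index[self.coefficients != 0.0])

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        common = self.coefficients.index
        return X[common] @ self.coefficients + self.intercept

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "alpha": self.params.alpha,
            "lambda": self.params.lam,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        d = json.loads(Path(path).read_text())
        return cls(coefficients=pd.Series(d["coefficients"], dtype=float),
                   intercept=d["intercept"],
                   params=ElasticNetParams(d["alpha"], d["lambda"]))


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MixsigError("AUC undefined for single-class labels")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def lambda_path(Xs: np.ndarray, y: np.ndarray, alpha: float,
                n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalty path from the all-zero threshold downward."""
    n = len(y)
    grad = np.abs(Xs.T @ (y - y.mean())) / n
    lam_max = float(grad.max() / max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambda)


def _make_estimator(alpha: float, lam: float, n: int, warm: bool = False) -> LogisticRegression:
    C = 1.0 / (n * lam)
    if alpha == 0.0:
        return LogisticRegression(penalty="l2", C=C, solver="lbfgs",
                                  max_iter=2000, tol=1e-8, warm_start=warm)
    return LogisticRegression(penalty="elasticnet", l1_ratio=alpha, C=C,
                              solver="saga", max_iter=1000, tol=1e-5,
                              warm_start=warm, random_state=0)


def _fit_std(Xs: np.ndarray, y: np.ndarray, alpha: float, lam: float,
             est: LogisticRegression | None = None) -> tuple[np.ndarray, float, LogisticRegression]:
    """One elastic-net fit on standardized features; returns (coef, intercept, estimator)."""
    if est is None:
        est = _make_estimator(alpha, lam, len(y), warm=True)
    else:
        est.C = 1.0 / (len(y) * lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xs, y)
    return est.coef_[0].copy(), float(est.intercept_[0]), est


def split_cohort(X: pd.DataFrame, y: pd.Series,
                 config: TuningConfig = TuningConfig()) -> tuple[pd.Index, pd.Index]:
    """Deterministic stratified train/test split of sample ids."""
    counts = y.value_counts()
    if (counts < config.n_folds).any():
        raise MixsigError(
            f"class sizes {counts.to_dict()} too small to stratify with {config.n_folds} folds")
    train_idx, test_idx = train_test_split(
        X.index, test_size=1.0 - config.train_fraction, stratify=y,
        random_state=config.seed % (2 ** 31))
    return pd.Index(train_idx), pd.Index(test_idx)


def tune_parameters(X: pd.DataFrame, y: pd.Series,
                    config: TuningConfig = TuningConfig()
                    ) -> tuple[ElasticNetParams, pd.DataFrame]:
    """Grid-tune (alpha, lambda) by replicated stratified k-fold CV.

    For every alpha a fixed log-spaced lambda path is walked with warm
    starts; out-of-fold scores are pooled per lambda into a CV AUC, fold
    assignments are re-randomized per replicate, and AUCs are averaged over
    replicates.  Returns the argmax parameters and the full surface.
    """
    yv = np.asarray(y, dtype=float)
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    n = len(yv)
    if len(np.unique(yv)) < 2:
        raise MixsigError("single-class response in tuning set")

    rep_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_replicates) % (2 ** 31)
    paths = {a: lambda_path(Xs, yv, a, config.lambda_path_length, config.lambda_decades)
             for a in config.alpha_grid}
    auc_sum: dict[float, np.ndarray] = {a: np.zeros(config.lambda_path_length)
                                        for a in config.alpha_grid}

    for rep in range(config.n_replicates):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=int(rep_seeds[rep]))
        folds = list(skf.split(Xs, yv))
        for a in config.alpha_grid:
            path = paths[a]
            oof = np.empty((n, len(path)))
            for tr, te in folds:
                est = None
                for li, lam in enumerate(path):
                    coef, b0, est = _fit_std(Xs[tr], yv[tr], a, lam, est)
                    oof[te, li] = Xs[te] @ coef + b0
            auc_sum[a] += np.array([_rank_auc(oof[:, li], yv) for li in range(len(path))])

    rows = []
    for a in config.alpha_grid:
        mean_auc = auc_sum[a] / config.n_replicates
        for lam, auc in zip(paths[a], mean_auc):
            rows.append((a, float(lam), float(auc)))
    surface = pd.DataFrame(rows, columns=["alpha", "lambda", "mean_auc"])
    # argmax; ties resolved toward sparser (higher alpha, then higher lambda)
    best = surface.sort_values(["mean_auc", "alpha", "lambda"],
                               ascending=[False, False, False]).iloc[0]
    return ElasticNetParams(float(best["alpha"]), float(best["lambda"])), surface


def fit_enet(X: pd.DataFrame, y: pd.Series, params: ElasticNetParams) -> FittedModel:
    """Single elastic-net fit; coefficients returned on the expression scale."""
    yv = np.asarray(y, dtype=float)
    Xs, mean, sd = _standardize(X.to_numpy(dtype=float))
    coef_std, b0, _ = _fit_std(Xs, yv, params.alpha, params.lam)
    coef = coef_std / sd
    intercept = b0 - float(mean @ coef)
    return FittedModel(coefficients=pd.Series(coef, index=X.columns, name="coefficient"),
                       intercept=intercept, params=params)


def stability_select(X: pd.DataFrame, y: pd.Series, params: ElasticNetParams,
                     n_boot: int = 1000, seed: int = 0) -> StabilityResult:
    """Class-stratified bootstrap refits at fixed (alpha, lambda).

    Features are ranked by how often they receive a non-zero coefficient;
    the kept set size is the rounded-half-up median bootstrap model size.
    """
    yv = np.asarray(y, dtype=float)
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(yv == 1)
    neg = np.flatnonzero(yv == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise MixsigError("both classes required for stability selection")

    p = Xs.shape[1]
    freq = np.zeros(p, dtype=int)
    abs_sum = np.zeros(p)
    sizes = np.empty(n_boot, dtype=int)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, size=len(pos), replace=True),
                              rng.choice(neg, size=len(neg), replace=True)])
        coef, _, _ = _fit_std(Xs[idx], yv[idx], params.alpha, params.lam)
        nz = coef != 0.0
        freq += nz
        abs_sum += np.abs(coef)
        sizes[b] = int(nz.sum())

    if (sizes == 0).mean() > 0.5:
        log.warning("more than half of the bootstrap fits are empty; lambda may be too large")
    median_size = int(np.floor(np.median(sizes) + 0.5))
    frequency = pd.Series(freq, index=X.columns, name="selection_frequency")
    mean_abs = pd.Series(abs_sum / n_boot, index=X.columns)
    order = sorted(X.columns, key=lambda f: (-frequency[f], -mean_abs[f], f))
    top = tuple(order[:median_size])
    return StabilityResult(selection_frequency=frequency, model_sizes=sizes,
                           median_size=median_size, top_features=top)


def fit_final(X: pd.DataFrame, y: pd.Series, params: ElasticNetParams) -> FittedModel:
    """Final fit on the stability-selected feature set."""
    if X.shape[1] == 0:
        raise EmptyModelError("no features supplied to the final fit")
    model = fit_enet(X, y, params)
    if len(model.nonzero_features) == 0:
        raise EmptyModelError(
            "final elastic-net fit returned no non-zero coefficients (relax lambda)")
    return model


def write_tuning(surface: pd.DataFrame, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    surface.to_csv(out / "tuning_surface.tsv", sep="\t", index=False)


def write_stability(result: StabilityResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.selection_frequency.to_csv(out / "stability_frequency.tsv", sep="\t")
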