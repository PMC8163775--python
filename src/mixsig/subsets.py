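"""Consensus best-subset search over the final model's non-zero features.

Every K-subset of the final model's features is scored with the *fixed*
final-model coefficients (no refitting): score_i = sum_j b_j x_ij.  Subsets
are enumerated exhaustively while C(p, K) fits the Monte-Carlo budget and
otherwise sampled uniformly without repeats.  The ten best subsets by AUC
define a feature-frequency table whose K most frequent members form the
consensus set for that K; the first local peak of the consensus AUC over K
selects the final signature size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .config import SubsetSweepConfig
from .enet import FittedModel
from .errors import MixsigError
from .evaluate import classification_metrics, roc_auc, youden_cutpoint

log = logging.getLogger(__name__)

_CHUNK = 20_000  # subsets scored per vectorized block


@dataclass(frozen=True)
class ConsensusResult:
    k: int
    top_subsets: tuple[tuple[str, ...], ...]   # best-first
    top_aucs: tuple[float, ...]
    frequency: pd.Series                       # feature -> appearances in top subsets
    consensus: tuple[str, ...]
    metrics: dict[str, float | None]
    n_enumerated: int
    exhaustive: bool


@dataclass(frozen=True)
class SubsetSweepResult:
    per_k: dict[int, ConsensusResult]
    selected_k: int

    @property
    def auc_curve(self) -> pd.Series:
        ks = sorted(self.per_k)
        return pd.Series([self.per_k[k].metrics["auc"] for k in ks], index=ks, name="auc")


def enumerate_subsets(features: list[str] | tuple[str, ...], k: int,
                      config: SubsetSweepConfig = SubsetSweepConfig()):
    """Yield index tuples of unique K-subsets (exhaustive or Monte Carlo).

    Exhaustive lexicographic enumeration when C(p, K) is within the budget;
    otherwise exactly ``mc_cap`` distinct uniform K-subsets drawn by
    rejection sampling, deterministic for a given seed.
    """
    p = len(features)
    if k > p:
        raise MixsigError(f"subset size {k} exceeds feature count {p}")
    total = comb(p, k)
    if total <= config.mc_cap:
        yield from combinations(range(p), k)
        return
    rng = np.random.default_rng(config.seed)
    seen: set[tuple[int, ...]] = set()
    # draw in batches; sort each row so subsets are canonical
    while len(seen) < config.mc_cap:
        need = config.mc_cap - len(seen)
        batch = min(max(2 * need, 1000), 200_000)
        draws = np.argsort(rng.random((batch, p)), axis=1)[:, :k]
        draws.sort(axis=1)
        for row in draws:
            t = tuple(int(v) for v in row)
            if t not in seen:
                seen.add(t)
                yield t
                if len(seen) == config.mc_cap:
                    return


def score_subset(model: FittedModel, subset: list[str] | tuple[str, ...],
                 X: pd.DataFrame) -> pd.Series:
    """Signature score: sum of coefficient x expression, no intercept."""
    missing = [f for f in subset if f not in model.nonzero_features]
    if missing:
        raise MixsigError(f"subset feature(s) not in the model's non-zero set: {missing[:5]}")
    if len(subset) == 0:
        return pd.Series(0.0, index=X.index, name="score")
    beta = model.coefficients[list(subset)]
    return (X[list(subset)] @ beta).rename("score")


def _rank_auc_rows(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC per row of a (m, n_samples) score matrix, tie-corrected."""
    ranks = stats.rankdata(scores, axis=1)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return (ranks[:, y == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def consensus_for_k(model: FittedModel, features: list[str] | tuple[str, ...],
                    k: int, X: pd.DataFrame, y: pd.Series,
                    config: SubsetSweepConfig = SubsetSweepConfig()) -> ConsensusResult:
    """Best-subset consensus at one K.

    Top subsets are ranked by AUC (ties: larger total |coefficient|, then
    lexicographic member names); the consensus set is the K most frequent
    features across the top subsets (same tie rule per feature).
    """
    features = list(features)
    for f in features:
        if f not in model.nonzero_features:
            raise MixsigError(f"feature {f} is not in the model's non-zero set")
    yv = np.asarray(y, dtype=float)
    beta = model.coefficients[features].to_numpy()
    W = X[features].to_numpy(dtype=float) * beta  # n x p contribution matrix
    Wt = W.T

    total = comb(len(features), k)
    exhaustive = total <= config.mc_cap
    n_enum = 0
    candidates: list[tuple[float, float, tuple[str, ...], tuple[int, ...]]] = []
    abs_beta = np.abs(beta)

    gen = enumerate_subsets(features, k, config)
    while True:
        block = []
        for t in gen:
            block.append(t)
            if len(block) == _CHUNK:
                break
        if not block:
            break
        idx = np.asarray(block)                      # m x k
        n_enum += len(block)
        scores = np.zeros((len(block), Wt.shape[1]))
        for j in range(k):                           # avoid an m x k x n intermediate
            scores += Wt[idx[:, j]]
        aucs = _rank_auc_rows(scores, yv)
        order = np.argsort(-aucs, kind="stable")
        # shortlist every subset tying the top_n-th AUC so the global
        # tie rule (total |coefficient|, then names) stays exact
        cutoff_pos = min(config.top_n, len(order)) - 1
        cutoff = aucs[order[cutoff_pos]]
        keep = order[aucs[order] >= cutoff - 1e-12]
        for i in keep:
            t = tuple(int(v) for v in idx[i])
            names = tuple(features[j] for j in t)
            candidates.append((float(aucs[i]), float(abs_beta[list(t)].sum()), names, t))
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
        candidates = candidates[: config.top_n]
        if len(block) < _CHUNK:
            break

    top = candidates[: config.top_n]
    counts: dict[str, int] = {}
    for _, _, names, _ in top:
        for f in names:
            counts[f] = counts.get(f, 0) + 1
    frequency = pd.Series({f: counts.get(f, 0) for f in features},
                          name="frequency").sort_index()
    mean_abs = model.coefficients.abs()
    ranked = sorted(features, key=lambda f: (-frequency[f], -mean_abs[f], f))
    consensus = tuple(ranked[:k])

    cscore = score_subset(model, consensus, X)
    cut, j = youden_cutpoint(cscore.to_numpy(), yv)
    metrics = classification_metrics(cscore.to_numpy(), yv, cut)
    metrics["auc"] = roc_auc(cscore.to_numpy(), yv)
    metrics["cutpoint"] = cut
    metrics["youden_j"] = j

    return ConsensusResult(k=k,
                           top_subsets=tuple(c[2] for c in top),
                           top_aucs=tuple(c[0] for c in top),
                           frequency=frequency, consensus=consensus,
                           metrics=metrics, n_enumerated=n_enum,
                           exhaustive=exhaustive)


def first_peak(values: list[float] | np.ndarray) -> int:
    """Index of the first local maximum (endpoints compared one-sided)."""
    v = np.asarray(values, dtype=float)
    for i in range(len(v)):
        left_ok = i == 0 or v[i] >= v[i - 1]
        right_ok = i == len(v) - 1 or v[i] >= v[i + 1]
        if left_ok and right_ok:
            return i
    return len(v) - 1  # unreachable for finite input, kept for safety


def sweep_k(model: FittedModel, X: pd.DataFrame, y: pd.Series,
            config: SubsetSweepConfig = SubsetSweepConfig()) -> SubsetSweepResult:
    """Consensus search over K = k_min..k_max with first-peak selection."""
    features = list(model.nonzero_features)
    k_max = config.k_max
    if len(features) < k_max:
        log.warning("only %d non-zero features; clamping k_max from %d",
                    len(features), k_max)
        k_max = len(features)
    k_min = config.k_min
    if len(features) < k_min:
        log.warning("only %d non-zero features; clamping k_min from %d",
                    len(features), k_min)
        k_min = len(features)
    per_k = {}
    for k in range(k_min, k_max + 1):
        per_k[k] = consensus_for_k(model, features, k, X, y, config)
    ks = sorted(per_k)
    curve = [per_k[k].metrics["auc"] for k in ks]
    selected = ks[first_peak(curve)]
    return SubsetSweepResult(per_k=per_k, selected_k=selected)
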