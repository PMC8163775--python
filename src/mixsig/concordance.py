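"""Cross-modality concordance: joint feature clustering and per-target
mRNA-protein Spearman correlation.

The clustering view asks whether spatial protein features carry information
distinct from bulk transcripts (they tend to cluster apart); the
correlation table quantifies, per antibody target, how well each
compartment's protein signal tracks its cognate transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .errors import MixsigError
from .normalize import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureDendrogram:
    """Average-linkage merge tree over features (correlation distance)."""

    linkage: np.ndarray          # scipy linkage matrix
    feature_names: tuple[str, ...]
    dropped_constant: tuple[str, ...]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        names = self.feature_names

        def rec(node) -> str:
            if node.is_leaf():
                label = names[node.id].replace("(", "_").replace(")", "_").replace(",", "_")
                return label
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return rec(tree) + ";"


def hierarchical_cluster(matrix: ExpressionMatrix) -> FeatureDendrogram:
    """Cluster features with distance 1 - Pearson r, average linkage.

    Constant features (zero variance) cannot enter a correlation distance
    and are dropped with a warning.
    """
    values = matrix.values
    variances = values.var(axis=0, ddof=0)
    constant = values.columns[variances == 0.0]
    if len(constant) > 0:
        log.warning("dropping %d constant feature(s) before clustering: %s",
                    len(constant), list(constant[:5]))
        values = values.drop(columns=constant)
    if values.shape[1] < 2:
        raise MixsigError("hierarchical clustering needs at least 2 non-constant features")
    corr = np.corrcoef(values.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)  # symmetrize away fp noise
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return FeatureDendrogram(linkage=link,
                             feature_names=tuple(values.columns),
                             dropped_constant=tuple(constant))


def compartment_sum(matrix: ExpressionMatrix, target: str) -> pd.Series | None:
    """Protein signal of ``target`` summed over compartments (count scale,
    re-logged).  Returns None if the target has no protein columns."""
    mask = (matrix.features["modality"] == "protein") & (matrix.features["target"] == target)
    cols = matrix.features.index[mask]
    if len(cols) == 0:
        return None
    counts = (2.0 ** matrix.values[cols] - 1.0).sum(axis=1)
    return np.log2(counts + 1.0)


def mrna_protein_correlation(matrix: ExpressionMatrix,
                             pairing: dict[str, str]) -> pd.DataFrame:
    """Spearman rho of each protein target vs its cognate mRNA.

    ``pairing`` maps antibody target name -> mRNA feature id.  Columns are
    the compartments present plus "sum"; unavailable or undefined (constant
    vector) correlations are left as NaN.
    """
    if not pairing:
        raise MixsigError("pairing map is empty")
    prot_meta = matrix.features[matrix.features["modality"] == "protein"]
    compartments = list(dict.fromkeys(prot_meta["compartment"]))
    rows = {}
    for target, gene in pairing.items():
        if gene not in matrix.values.columns:
            log.warning("paired mRNA %s for target %s not in matrix; skipping", gene, target)
            continue
        x = matrix.values[gene]
        row = {}
        for comp in compartments:
            col = f"{target}@{comp}"
            if col not in matrix.values.columns:
                row[comp] = np.nan
                continue
            row[comp] = _spearman(x, matrix.values[col], f"{col} vs {gene}")
        s = compartment_sum(matrix, target)
        row["sum"] = _spearman(x, s, f"{target}@sum vs {gene}") if s is not None else np.nan
        rows[target] = row
    if not rows:
        raise MixsigError("no protein target in the pairing map matches the matrix")
    return pd.DataFrame.from_dict(rows, orient="index")[compartments + ["sum"]]


def _spearman(x: pd.Series, y: pd.Series, label: str) -> float:
    if x.nunique() < 2 or y.nunique() < 2:
        log.warning("constant vector, Spearman undefined for %s", label)
        return np.nan
    rho = spearmanr(x, y).statistic
    return float(rho)


def write_concordance(dendrogram: FeatureDendrogram, table: pd.DataFrame,
                      outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "feature_dendrogram.nwk").write_text(dendrogram.to_newick())
    table.to_csv(out / "mrna_protein_spearman.tsv", sep="\t")
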