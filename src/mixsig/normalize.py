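"""Count normalization and feature-matrix assembly.

Bulk mRNA counts are scaled per sample by geometric-mean factors — first
from internal-control probes (technical efficiency), then from housekeeping
genes (RNA content) — with the cohort geometric mean of the per-sample
control geomeans as the common reference, then log2(x+1) transformed.

Spatial protein counts are background-corrected per AOI by the geometric
mean of the negative-control (IgG) antibodies, scaled by a positive-control
geometric-mean factor (system variation), normalized to compartment area
relative to the cohort median area, then log2(x+1) transformed.

``assemble_feature_matrix`` concatenates the two modalities into the single
sample-by-feature matrix the models consume, with per-feature metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AssemblyError, NormalizationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized log2-scale sample-by-feature matrix with metadata.

    ``features`` is indexed like ``values.columns`` and carries, per
    feature: ``modality`` ("mRNA" | "protein"), ``target`` (source probe or
    antibody), ``compartment`` ("" for mRNA) and ``control`` (bool).
    """

    values: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.features.index):
            raise AssemblyError("feature metadata does not match value columns")
        if self.values.isna().any().any():
            raise AssemblyError("assembled matrix contains missing values")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise AssemblyError(f"duplicate feature identifiers: {dupes[:5]}")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, mask: pd.Series | np.ndarray | list[str]) -> "ExpressionMatrix":
        """Column-subset by boolean mask or explicit feature list."""
        if isinstance(mask, (pd.Series, np.ndarray)) and np.asarray(mask).dtype == bool:
            cols = self.values.columns[np.asarray(mask)]
        else:
            cols = pd.Index(mask)
        return ExpressionMatrix(self.values[cols], self.features.loc[cols])


def _geomean(block: pd.DataFrame, axis: int = 1) -> pd.Series:
    return np.exp(np.log(block.replace(0, np.nan)).mean(axis=axis)).fillna(0.0)


def normalize_mrna(raw_counts: pd.DataFrame, probe_classes: pd.Series) -> pd.DataFrame:
    """Two-step geometric-mean normalization of nCounter-style mRNA counts.

    Returns the log2(x+1) matrix of *endogenous* probes only.
    """
    classes = probe_classes.reindex(raw_counts.columns)
    if classes.isna().any():
        missing = raw_counts.columns[classes.isna()].tolist()
        raise NormalizationError(f"probes without a class label: {missing[:5]}")
    ic = raw_counts.columns[classes == "internal_control"]
    hk = raw_counts.columns[classes == "housekeeping"]
    if len(ic) == 0 or len(hk) == 0:
        raise NormalizationError("need at least one internal-control and one housekeeping probe")
    if (raw_counts < 0).any().any():
        raise NormalizationError("mRNA counts must be non-negative")

    adjusted = raw_counts.astype(float)
    for probes, step in ((ic, "internal-control"), (hk, "housekeeping")):
        g = _geomean(adjusted[probes])
        if (g <= 0).any():
            bad = g.index[g <= 0].tolist()
            raise NormalizationError(f"zero {step} geometric mean for sample(s) {bad}")
        reference = float(np.exp(np.log(g).mean()))
        adjusted = adjusted.mul(reference / g, axis=0)

    endog = raw_counts.columns[classes == "endogenous"]
    return np.log2(adjusted[endog] + 1.0)


def normalize_dsp(raw_counts: pd.DataFrame, control_roles: pd.Series,
                  areas: pd.Series, keep_controls: bool = False) -> pd.DataFrame:
    """Control- and area-normalize spatial protein counts.

    ``raw_counts`` is indexed by (sample, compartment); the result is a
    samples x "target@compartment" log2 matrix.  With ``keep_controls`` the
    control antibodies receive the same normalization and stay in the
    output (used for the joint clustering view).
    """
    roles = control_roles.reindex(raw_counts.columns)
    if roles.isna().any():
        missing = raw_counts.columns[roles.isna()].tolist()
        raise NormalizationError(f"antibodies without a role: {missing[:5]}")
    neg = raw_counts.columns[roles == "negative"]
    pos = raw_counts.columns[roles == "positive"]
    if len(neg) == 0 or len(pos) == 0:
        raise NormalizationError("need at least one positive and one negative control antibody")
    missing_area = raw_counts.index.difference(areas.index)
    if len(missing_area) > 0:
        raise NormalizationError(f"missing compartment area for AOI(s) {list(missing_area)[:5]}")
    area = areas.reindex(raw_counts.index).astype(float)
    if (area <= 0).any():
        bad = area.index[area <= 0].tolist()
        raise NormalizationError(f"non-positive area for AOI(s) {bad[:5]}")

    counts = raw_counts.astype(float)
    background = _geomean(counts[neg])
    corrected = (counts.sub(background, axis=0)).clip(lower=0.0)

    pos_g = _geomean(corrected[pos])
    if (pos_g <= 0).any():
        bad = pos_g.index[pos_g <= 0].tolist()
        raise NormalizationError(f"zero positive-control geometric mean for AOI(s) {bad[:5]}")
    reference = float(np.exp(np.log(pos_g).mean()))
    corrected = corrected.mul(reference / pos_g, axis=0)

    median_area = float(area.median())
    corrected = corrected.mul(median_area / area, axis=0)

    keep = raw_counts.columns if keep_controls else raw_counts.columns[roles == "endogenous"]
    logvals = np.log2(corrected[keep] + 1.0)

    # pivot (sample, compartment) rows into target@compartment columns
    wide = logvals.unstack("compartment")
    wide.columns = [f"{t}@{c}" for t, c in wide.columns]
    # restore target-major, panel-declared ordering
    compartments = raw_counts.index.get_level_values("compartment").unique()
    ordered = [f"{t}@{c}" for t in keep for c in compartments]
    return wide[ordered]


def assemble_feature_matrix(mrna: pd.DataFrame | None, dsp: pd.DataFrame | None,
                            control_roles: pd.Series | None = None) -> ExpressionMatrix:
    """Combine normalized modality submatrices into one ExpressionMatrix.

    Either submatrix may be None (single-modality models).  ``control_roles``
    is only needed to flag control antibodies retained by
    ``normalize_dsp(..., keep_controls=True)``.
    """
    blocks, metas = [], []
    if mrna is not None:
        blocks.append(mrna)
        metas.append(pd.DataFrame({
            "modality": "mRNA", "target": mrna.columns, "compartment": "",
            "control": False}, index=mrna.columns))
    if dsp is not None:
        split = [c.rsplit("@", 1) for c in dsp.columns]
        targets = [s[0] for s in split]
        comps = [s[1] for s in split]
        ctrl = [bool(control_roles is not None and control_roles.get(t, "endogenous") != "endogenous")
                for t in targets]
        blocks.append(dsp)
        metas.append(pd.DataFrame({
            "modality": "protein", "target": targets, "compartment": comps,
            "control": ctrl}, index=dsp.columns))
    if not blocks:
        raise AssemblyError("at least one modality submatrix required")
    if len(blocks) == 2:
        diff = blocks[0].index.symmetric_difference(blocks[1].index)
        if len(diff) > 0:
            raise AssemblyError(f"sample sets differ between modalities: {list(diff)[:5]}")
        blocks[1] = blocks[1].reindex(blocks[0].index)
    values = pd.concat(blocks, axis=1)
    features = pd.concat(metas, axis=0)
    features.index.name = "feature"
    values.columns.name = "feature"
    return ExpressionMatrix(values, features)


def write_expression(em: ExpressionMatrix, outdir: str | Path, stem: str = "expression") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    em.values.to_csv(out / f"{stem}.tsv", sep="\t")
    em.features.to_csv(out / f"{stem}_features.tsv", sep="\t")
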