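"""Configuration objects for every pipeline stage.

Defaults mirror the assay and modeling setup the pipeline emulates: a
770-plex bulk mRNA panel with housekeeping and internal-control probes, a
44-antibody spatial-protein panel (5 controls) read out in three
morphology-defined compartments, a 59-sample cohort, and the modeling
constants (p < 0.10 screen, |r| <= 0.7 pruning, alpha grid 0..1 step 0.05,
4-fold CV x 40 replicates, 1000 bootstraps, K = 4..13 with a 2,000,000
Monte-Carlo subset budget, top-10 consensus, 1000-draw smoothed-bootstrap
CIs, 1000 permutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

#: Antibody names excluded from modeling; roles follow the platform
#: convention: housekeeping-like positives, IgG isotype negatives.
DEFAULT_PROTEIN_CONTROLS: dict[str, str] = {
    "Histone H3": "positive",
    "S6": "positive",
    "Mouse IgG1": "negative",
    "Mouse IgG2a": "negative",
    "Rabbit IgG": "negative",
}

DEFAULT_COMPARTMENTS: tuple[str, ...] = ("s100/HMB45", "CD45", "CD68")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class PanelConfig:
    """Shape and generative parameters of a synthetic cohort.

    ``n_mrna`` counts *endogenous* probes (the modeling pool); housekeeping
    and internal-control probes are additional columns of the raw matrix.
    ``effect_size`` is the log-odds change in response per SD of an
    informative feature's latent expression.
    """

    n_samples: int = 59
    n_mrna: int = 770
    n_mrna_internal_controls: int = 6
    n_housekeeping: int = 20
    n_protein: int = 44
    protein_control_names: tuple[str, ...] = tuple(DEFAULT_PROTEIN_CONTROLS)
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    n_informative_mrna: int = 5
    n_informative_protein: int = 3
    effect_size: float = 1.0
    block_corr: float = 0.5
    block_size: int = 10
    censor_rate: float = 0.3
    seed: int = 0
    # generative nuisance parameters
    nb_dispersion: float = 0.2
    response_rate: float = 0.4
    protein_mrna_corr: float = 0.4
    biological_sd: float = 0.7
    technical_sd: float = 0.3
    content_sd: float = 0.2
    area_sd: float = 0.4
    median_pfs_months: float = 6.0
    median_os_months: float = 18.0

    def __post_init__(self) -> None:
        _require(self.n_samples > 0, "n_samples must be positive")
        _require(self.n_mrna > 0, "n_mrna must be positive")
        _require(self.n_protein > len(self.protein_control_names),
                 "n_protein must exceed the number of protein controls")
        _require(self.n_mrna > self.n_housekeeping + self.n_mrna_internal_controls,
                 "n_mrna must exceed housekeeping + internal-control probe count")
        _require(self.n_mrna_internal_controls >= 1, "need at least one internal-control probe")
        _require(self.n_housekeeping >= 1, "need at least one housekeeping probe")
        _require(0.0 <= self.block_corr < 1.0, "block_corr must lie in [0, 1)")
        _require(self.block_size >= 1, "block_size must be positive")
        _require(0.0 <= self.censor_rate < 1.0, "censor_rate must lie in [0, 1)")
        _require(self.n_informative_mrna >= 0 and self.n_informative_protein >= 0,
                 "informative feature counts must be non-negative")
        _require(self.n_informative_mrna <= self.n_mrna,
                 "n_informative_mrna exceeds n_mrna")
        n_endog_protein = (self.n_protein - len(self.protein_control_names)) * len(self.compartments)
        _require(self.n_informative_protein <= n_endog_protein,
                 "n_informative_protein exceeds endogenous protein feature count")
        _require(self.nb_dispersion > 0, "nb_dispersion must be positive")
        _require(0.0 < self.response_rate < 1.0, "response_rate must lie in (0, 1)")
        _require(len(self.compartments) >= 1, "need at least one compartment")

    @property
    def n_protein_endogenous(self) -> int:
        return self.n_protein - len(self.protein_control_names)

    @property
    def n_protein_features(self) -> int:
        """Endogenous (antibody, compartment) modeling features."""
        return self.n_protein_endogenous * len(self.compartments)


@dataclass(frozen=True)
class ScreenConfig:
    """Univariate screen and correlation-pruning thresholds."""

    p_max: float = 0.10
    r_max: float = 0.7
    #: statistic that orders the greedy pruning pass ("r2" or "auc")
    rank_by: str = "r2"
    #: interpret ``r_max`` as a threshold on |r| ("r") or on r**2 ("r2")
    corr_scale: str = "r"

    def __post_init__(self) -> None:
        _require(0.0 < self.p_max < 1.0, "p_max must lie in (0, 1)")
        _require(0.0 < self.r_max < 1.0, "r_max must lie in (0, 1)")
        _require(self.rank_by in ("r2", "auc"), "rank_by must be 'r2' or 'auc'")
        _require(self.corr_scale in ("r", "r2"), "corr_scale must be 'r' or 'r2'")


@dataclass(frozen=True)
class TuningConfig:
    """Replicated cross-validation grid for (alpha, lambda)."""

    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    n_folds: int = 4
    n_replicates: int = 40
    lambda_path_length: int = 100
    lambda_decades: float = 4.0
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        _require(all(0.0 <= a <= 1.0 for a in self.alpha_grid),
                 "alpha grid values must lie in [0, 1]")
        _require(len(self.alpha_grid) >= 1, "alpha grid must be non-empty")
        _require(self.n_folds >= 2, "n_folds must be at least 2")
        _require(self.n_replicates >= 1, "n_replicates must be positive")
        _require(self.lambda_path_length >= 2, "lambda path needs >= 2 values")
        _require(0.0 < self.train_fraction < 1.0, "train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SubsetSweepConfig:
    """Consensus best-subset sweep over model sizes K."""

    k_min: int = 4
    k_max: int = 13
    mc_cap: int = 2_000_000
    top_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.k_min >= 1, "k_min must be positive")
        _require(self.k_min <= self.k_max, "k_min must not exceed k_max")
        _require(self.mc_cap >= self.top_n, "mc_cap must be at least top_n")
        _require(self.top_n >= 1, "top_n must be positive")


@dataclass(frozen=True)
class EvaluationConfig:
    """Bootstrap/permutation budgets for metric uncertainty."""

    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_boot >= 1, "n_boot must be positive")
        _require(self.n_perm >= 1, "n_perm must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration (see :mod:`mixsig.pipeline`)."""

    panel: PanelConfig = field(default_factory=PanelConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    sweep: SubsetSweepConfig = field(default_factory=SubsetSweepConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    n_stability_boot: int = 1000
    modalities: tuple[str, ...] = ("mrna", "protein", "combined")
    #: cohort on which subset/consensus scores are evaluated: full/train/test
    subset_eval_set: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(all(m in ("mrna", "protein", "combined") for m in self.modalities),
                 "modalities must be drawn from {mrna, protein, combined}")
        _require(len(self.modalities) >= 1, "at least one modality required")
        _require(self.subset_eval_set in ("full", "train", "test"),
                 "subset_eval_set must be full, train, or test")
        _require(self.n_stability_boot >= 1, "n_stability_boot must be positive")
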