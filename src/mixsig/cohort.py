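"""Synthetic cohort generation with known ground truth.

The generator emulates the structure of a dual-platform melanoma
immunotherapy cohort: a bulk mRNA counting panel (endogenous probes plus
housekeeping and internal-control probes, negative-binomial counts around a
log-normal technical/content model) and a spatial protein readout (antibody
counts per morphology-defined compartment with positive/negative control
antibodies, compartment areas, and additive background).

A small set of *informative* features drives a latent logistic response
model and, through the same latent predictor, proportional-hazards PFS/OS
times.  Everything downstream of the raw counts can therefore be tested
against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_PROTEIN_CONTROLS, PanelConfig
from .errors import ConfigError

_DSP_BACKGROUND = 20.0  # mean background counts per AOI (arbitrary count units)


@dataclass(frozen=True)
class GroundTruth:
    """Planted signal of a synthetic cohort.

    ``true_coefficients`` is indexed by the informative feature ids; every
    feature absent from it has a true coefficient of exactly zero.
    """

    informative_features: tuple[str, ...]
    true_coefficients: pd.Series
    latent_predictor: np.ndarray
    response_probability: np.ndarray

    def coefficient(self, feature: str) -> float:
        return float(self.true_coefficients.get(feature, 0.0))


@dataclass(frozen=True)
class RawCohort:
    """Raw counts, clinical outcomes and ground truth for one cohort."""

    mrna_counts: pd.DataFrame          # samples x probes (endogenous + HK + IC)
    probe_classes: pd.Series           # probe -> endogenous|housekeeping|internal_control
    dsp_counts: pd.DataFrame           # (sample, compartment) x antibody
    control_roles: pd.Series           # antibody -> endogenous|positive|negative
    compartment_areas: pd.Series       # (sample, compartment) -> area
    clinical: pd.DataFrame             # per-sample outcomes
    truth: GroundTruth
    protein_gene_map: dict[str, str]   # antibody target -> cognate mRNA probe
    config: PanelConfig

    @property
    def samples(self) -> pd.Index:
        return self.mrna_counts.index

    @property
    def response(self) -> pd.Series:
        return self.clinical["response"]


def _blocked_normal(rng: np.random.Generator, n: int, p: int,
                    rho: float, block_size: int) -> np.ndarray:
    """n x p standard-normal matrix with equicorrelation rho inside
    consecutive blocks of ``block_size`` columns."""
    z = rng.standard_normal((n, p))
    if rho <= 0.0:
        return z
    n_blocks = int(np.ceil(p / block_size))
    shared = rng.standard_normal((n, n_blocks))
    block_of = np.minimum(np.arange(p) // block_size, n_blocks - 1)
    return np.sqrt(rho) * shared[:, block_of] + np.sqrt(1.0 - rho) * z


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = m + dispersion * m**2."""
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mean, dtype=float))
    return rng.negative_binomial(size, p)


def _evenly_spaced(n_pick: int, n_total: int) -> np.ndarray:
    """Deterministic, well-separated positions for planted features."""
    if n_pick == 0:
        return np.array([], dtype=int)
    return np.unique(np.round(np.linspace(0, n_total - 1, n_pick)).astype(int))


def generate_cohort(config: PanelConfig) -> RawCohort:
    """Draw one raw cohort from the generative model in ``config``.

    The draw is a pure function of the config (including its seed): two
    calls with identical configs return identical cohorts.
    """
    if not isinstance(config, PanelConfig):
        raise ConfigError("generate_cohort expects a PanelConfig")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample")

    # ---- feature naming -------------------------------------------------
    genes = [f"G{i + 1:04d}" for i in range(config.n_mrna)]
    hk = [f"HK{i + 1:02d}" for i in range(config.n_housekeeping)]
    ic = [f"IC{i + 1:02d}" for i in range(config.n_mrna_internal_controls)]
    probe_classes = pd.Series(
        ["endogenous"] * len(genes) + ["housekeeping"] * len(hk) + ["internal_control"] * len(ic),
        index=pd.Index(genes + hk + ic, name="probe"), name="probe_class")

    n_endog_prot = config.n_protein_endogenous
    targets = [f"P{i + 1:02d}" for i in range(n_endog_prot)]
    controls = list(config.protein_control_names)
    antibodies = targets + controls
    roles = pd.Series(
        ["endogenous"] * n_endog_prot
        + [DEFAULT_PROTEIN_CONTROLS.get(c, "negative") for c in controls],
        index=pd.Index(antibodies, name="antibody"), name="role")
    # each endogenous antibody tracks one cognate mRNA probe
    protein_gene_map = {t: genes[i] for i, t in enumerate(targets)}

    compartments = list(config.compartments)
    prot_features = [f"{t}@{c}" for t in targets for c in compartments]

    # ---- latent biology -------------------------------------------------
    # block correlation models redundant *noise* structure (it is what the
    # pruning stage removes); informative features are drawn independent of
    # the blocks so the planted signal is not confounded with noise proxies
    mrna_pick = _evenly_spaced(config.n_informative_mrna, config.n_mrna)
    z_mrna = _blocked_normal(rng, n, config.n_mrna, config.block_corr, config.block_size)
    if len(mrna_pick) > 0:
        z_mrna[:, mrna_pick] = rng.standard_normal((n, len(mrna_pick)))
    # protein latent: shares r with the cognate gene, plus a per-target and
    # per-compartment component (marginally standard normal)
    r = config.protein_mrna_corr
    base = r * z_mrna[:, :n_endog_prot] + np.sqrt(1 - r * r) * rng.standard_normal((n, n_endog_prot))
    w_shared = 0.5  # cross-compartment correlation of a target's signal
    # feature order is target-major: (t1,c1), (t1,c2), ..., (t2,c1), ...
    z_prot = np.empty((n, n_endog_prot * len(compartments)))
    for ci in range(len(compartments)):
        eps = rng.standard_normal((n, n_endog_prot))
        z_prot[:, ci::len(compartments)] = np.sqrt(w_shared) * base + np.sqrt(1 - w_shared) * eps

    # ---- planted signal -------------------------------------------------
    prot_pick = _evenly_spaced(config.n_informative_protein, len(prot_features))
    informative = [genes[i] for i in mrna_pick] + [prot_features[i] for i in prot_pick]
    signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(len(informative))])
    coefs = pd.Series(config.effect_size * signs, index=pd.Index(informative, name="feature"),
                      name="true_coefficient", dtype=float)

    z_info = np.hstack([z_mrna[:, mrna_pick], z_prot[:, prot_pick]]) if informative else np.zeros((n, 0))
    latent = z_info @ coefs.to_numpy() if informative else np.zeros(n)
    b0 = float(np.log(config.response_rate / (1.0 - config.response_rate)))
    prob = 1.0 / (1.0 + np.exp(-(b0 + latent)))
    response = (rng.random(n) < prob).astype(int)

    # ---- BOR categories -------------------------------------------------
    bor = np.empty(n, dtype=object)
    resp_mask = response == 1
    if resp_mask.any():
        hi = np.quantile(prob[resp_mask], 0.75)
        bor[resp_mask] = np.where(prob[resp_mask] >= hi, "CR", "PR")
    if (~resp_mask).any():
        lo = np.quantile(prob[~resp_mask], 0.25)
        bor[~resp_mask] = np.where(prob[~resp_mask] <= lo, "PD", "SD")

    # ---- survival -------------------------------------------------------
    def _survival(median_months: float) -> tuple[np.ndarray, np.ndarray]:
        h0 = np.log(2.0) / median_months
        hazard = h0 * np.exp(-latent)
        event_time = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0:
            c_rate = h0 * config.censor_rate / (1.0 - config.censor_rate)
            censor_time = rng.exponential(1.0 / c_rate, size=n)
        else:
            censor_time = np.full(n, np.inf)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        return time, event

    pfs_time, pfs_event = _survival(config.median_pfs_months)
    os_time, os_event = _survival(config.median_os_months)

    clinical = pd.DataFrame({
        "bor_category": bor,
        "response": response,
        "pfs_time": pfs_time,
        "pfs_event": pfs_event,
        "os_time": os_time,
        "os_event": os_event,
    }, index=samples)

    # ---- mRNA counts ----------------------------------------------------
    tech = np.exp(rng.normal(0.0, config.technical_sd, size=n))     # lane efficiency
    content = np.exp(rng.normal(0.0, config.content_sd, size=n))    # RNA content
    mu_genes = rng.normal(np.log(300.0), 0.8, size=config.n_mrna)
    mu_hk = rng.normal(np.log(800.0), 0.3, size=config.n_housekeeping)
    mu_ic = rng.normal(np.log(500.0), 0.3, size=config.n_mrna_internal_controls)

    mean_endog = (tech * content)[:, None] * np.exp(mu_genes[None, :] + config.biological_sd * z_mrna)
    mean_hk = (tech * content)[:, None] * np.exp(mu_hk)[None, :]
    mean_ic = tech[:, None] * np.exp(mu_ic)[None, :]
    mrna_counts = pd.DataFrame(
        _nb_counts(rng, np.hstack([mean_endog, mean_hk, mean_ic]), config.nb_dispersion),
        index=samples, columns=probe_classes.index)

    # ---- DSP counts -----------------------------------------------------
    aoi_index = pd.MultiIndex.from_product([samples, compartments],
                                           names=["sample", "compartment"])
    n_aoi = len(aoi_index)
    u = np.exp(rng.normal(0.0, config.technical_sd, size=n_aoi))    # per-AOI system factor
    areas = pd.Series(np.exp(rng.normal(0.0, config.area_sd, size=n_aoi)),
                      index=aoi_index, name="area")
    mu_prot = rng.normal(np.log(200.0), 0.6, size=n_endog_prot)
    mu_pos = rng.normal(np.log(600.0), 0.2, size=sum(roles == "positive"))

    # expand protein latent (n x features, target-major) to AOI rows
    z_aoi = z_prot.reshape(n, n_endog_prot, len(compartments)).transpose(0, 2, 1).reshape(n_aoi, n_endog_prot)
    signal = areas.to_numpy()[:, None] * np.exp(mu_prot[None, :] + config.biological_sd * z_aoi)
    mean_endog_p = u[:, None] * (signal + _DSP_BACKGROUND)
    mean_neg = u[:, None] * np.full((n_aoi, int((roles == "negative").sum())), _DSP_BACKGROUND)
    mean_pos = u[:, None] * np.exp(mu_pos)[None, :]
    dsp_mean = np.empty((n_aoi, len(antibodies)))
    dsp_mean[:, roles.to_numpy() == "endogenous"] = mean_endog_p
    dsp_mean[:, roles.to_numpy() == "positive"] = mean_pos
    dsp_mean[:, roles.to_numpy() == "negative"] = mean_neg
    dsp_counts = pd.DataFrame(_nb_counts(rng, dsp_mean, config.nb_dispersion),
                              index=aoi_index, columns=roles.index)

    truth = GroundTruth(
        informative_features=tuple(informative),
        true_coefficients=coefs,
        latent_predictor=latent,
        response_probability=prob,
    )
    return RawCohort(mrna_counts=mrna_counts, probe_classes=probe_classes,
                     dsp_counts=dsp_counts, control_roles=roles,
                     compartment_areas=areas, clinical=clinical, truth=truth,
                     protein_gene_map=protein_gene_map, config=config)


def write_cohort(cohort: RawCohort, outdir: str | Path) -> dict[str, Path]:
    """Persist a cohort as plain-text tables (TSV/CSV/JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna_counts": out / "mrna_counts.tsv",
        "probe_classes": out / "probe_classes.tsv",
        "dsp_counts": out / "dsp_counts.tsv",
        "areas": out / "compartment_areas.tsv",
        "clinical": out / "clinical.csv",
        "truth": out / "ground_truth.json",
    }
    cohort.mrna_counts.to_csv(paths["mrna_counts"], sep="\t")
    cohort.probe_classes.to_csv(paths["probe_classes"], sep="\t")
    cohort.dsp_counts.to_csv(paths["dsp_counts"], sep="\t")
    cohort.compartment_areas.to_csv(paths["areas"], sep="\t")
    cohort.clinical.to_csv(paths["clinical"])
    truth = {
        "informative_features": list(cohort.truth.informative_features),
        "true_coefficients": {k: float(v) for k, v in cohort.truth.true_coefficients.items()},
        "latent_predictor": [float(x) for x in cohort.truth.latent_predictor],
        "protein_gene_map": cohort.protein_gene_map,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
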