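"""End-to-end orchestration: simulate -> normalize -> screen -> prune ->
split -> tune -> stability-select -> final fit -> subset consensus sweep ->
evaluation -> survival, for each requested modality (mRNA-only,
protein-only, combined).

A single global seed deterministically derives every stage seed, so a rerun
with the same config produces a bit-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import enet, evaluate, normalize, screen, subsets, survival
from .cohort import RawCohort, generate_cohort
from .config import (EvaluationConfig, PanelConfig, PipelineConfig, ScreenConfig,
                     SubsetSweepConfig, TuningConfig)
from .errors import ConfigError, MixsigError

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

REQUIRED_MODEL_KEYS = {
    "n_candidates", "n_screen_survivors", "n_pruned", "alpha", "lambda",
    "stability_median_size", "n_nonzero", "selected_k", "consensus_sets",
    "k_curve", "evaluation", "importance", "survival_pfs", "survival_os",
}


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, MixsigError):
                raise MixsigError(f"stage '{name}' failed: {exc}") from exc
            if isinstance(exc, MixsigError) and not str(exc).startswith("stage '"):
                raise MixsigError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


def _derive_seeds(config: PipelineConfig) -> PipelineConfig:
    """Propagate the global seed into every stochastic sub-config."""
    s = int(config.seed) % (2 ** 31 - 16)
    return dataclasses.replace(
        config,
        panel=dataclasses.replace(config.panel, seed=s),
        tuning=dataclasses.replace(config.tuning, seed=s + 1),
        sweep=dataclasses.replace(config.sweep, seed=s + 2),
        evaluation=dataclasses.replace(config.evaluation, seed=s + 3),
    )


def _assemble_modality(cohort: RawCohort, modality: str) -> normalize.ExpressionMatrix:
    mrna = dsp = None
    if modality in ("mrna", "combined"):
        mrna = normalize.normalize_mrna(cohort.mrna_counts, cohort.probe_classes)
    if modality in ("protein", "combined"):
        dsp = normalize.normalize_dsp(cohort.dsp_counts, cohort.control_roles,
                                      cohort.compartment_areas)
    return normalize.assemble_feature_matrix(mrna, dsp, cohort.control_roles)


def run_modality(cohort: RawCohort, modality: str, config: PipelineConfig,
                 outdir: Path | None = None) -> dict[str, Any]:
    """Run the modeling cascade for one modality; returns its report block."""
    y = cohort.response
    out = (outdir / modality) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    with _stage(f"{modality}:normalize"):
        em = _assemble_modality(cohort, modality)
        if out is not None:
            normalize.write_expression(em, out)
    log.info("[%s] candidate pool: %d features", modality, em.n_features)

    with _stage(f"{modality}:screen"):
        screened = screen.univariate_screen(em, y, config.screen)
        kept = screen.prune_correlated(em, screened.stats, config.screen,
                                       candidates=list(screened.survivors))
        if out is not None:
            screen.write_screen(screened, kept, out)
    log.info("[%s] screen: %d -> %d survivors -> %d pruned", modality,
             em.n_features, len(screened.survivors), len(kept))
    if len(kept) == 0:
        raise MixsigError(f"stage '{modality}:screen' failed: no features survive the screen")

    X = em.values[kept]
    with _stage(f"{modality}:split"):
        train_ids, test_ids = enet.split_cohort(X, y, config.tuning)

    with _stage(f"{modality}:tune"):
        params, surface = enet.tune_parameters(X.loc[train_ids], y.loc[train_ids],
                                               config.tuning)
        if out is not None:
            enet.write_tuning(surface, out)
    log.info("[%s] tuned alpha=%.2f lambda=%.4g", modality, params.alpha, params.lam)

    with _stage(f"{modality}:stability"):
        stab = enet.stability_select(X.loc[train_ids], y.loc[train_ids], params,
                                     n_boot=config.n_stability_boot,
                                     seed=config.tuning.seed + 7)
        if out is not None:
            enet.write_stability(stab, out)

    with _stage(f"{modality}:final_fit"):
        model = enet.fit_final(X.loc[train_ids, list(stab.top_features)],
                               y.loc[train_ids], params)
        if out is not None:
            model.to_json(out / "final_model.json")
    log.info("[%s] stability M=%d, non-zero=%d", modality, stab.median_size,
             len(model.nonzero_features))

    eval_ids = {"full": X.index, "train": train_ids, "test": test_ids}[config.subset_eval_set]
    X_eval = X.loc[eval_ids, list(model.nonzero_features)]
    y_eval = y.loc[eval_ids]

    with _stage(f"{modality}:subset_sweep"):
        sweep = subsets.sweep_k(model, X_eval, y_eval, config.sweep)
        if out is not None:
            _write_sweep(sweep, out)

    sel = sweep.per_k[sweep.selected_k]
    score = subsets.score_subset(model, sel.consensus, X_eval).to_numpy()
    with _stage(f"{modality}:evaluation"):
        report = evaluate.evaluate_scores(score, y_eval.to_numpy(),
                                          n_boot=config.evaluation.n_boot,
                                          seed=config.evaluation.seed)
        importance = evaluate.permutation_importance(
            model, sel.consensus, X_eval, y_eval,
            n_perm=config.evaluation.n_perm, seed=config.evaluation.seed + 11)
        if out is not None:
            importance.to_csv(out / "permutation_importance.tsv", sep="\t")

    with _stage(f"{modality}:survival"):
        clin = cohort.clinical.loc[eval_ids]
        surv_pfs = survival.compare_survival(score, report.cutpoint,
                                             clin["pfs_time"].to_numpy(),
                                             clin["pfs_event"].to_numpy())
        surv_os = survival.compare_survival(score, report.cutpoint,
                                            clin["os_time"].to_numpy(),
                                            clin["os_event"].to_numpy())
        if out is not None:
            _write_survival(surv_pfs, out, "pfs")
            _write_survival(surv_os, out, "os")

    return {
        "n_candidates": em.n_features,
        "n_screen_survivors": len(screened.survivors),
        "n_pruned": len(kept),
        "train_samples": list(map(str, train_ids)),
        "test_samples": list(map(str, test_ids)),
        "alpha": params.alpha,
        "lambda": params.lam,
        "stability_median_size": stab.median_size,
        "stability_top_features": list(stab.top_features),
        "n_nonzero": len(model.nonzero_features),
        "nonzero_features": list(model.nonzero_features),
        "selected_k": sweep.selected_k,
        "k_curve": {str(k): sweep.per_k[k].metrics for k in sweep.per_k},
        "consensus_sets": {str(k): list(sweep.per_k[k].consensus) for k in sweep.per_k},
        "evaluation": report.to_dict(),
        "importance": {f: float(v) for f, v in importance["auc_decrease"].items()},
        "survival_pfs": surv_pfs.to_dict(),
        "survival_os": surv_os.to_dict(),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 cohort: RawCohort | None = None) -> dict[str, Any]:
    """Run every requested modality and return the machine-readable report.

    A pre-generated cohort may be supplied; otherwise one is drawn from the
    (seed-derived) panel config.
    """
    config = _derive_seeds(config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        with _stage("simulate"):
            cohort = generate_cohort(config.panel)

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": int(config.seed),
        "n_samples": int(cohort.config.n_samples),
        "modalities": {},
    }
    for modality in config.modalities:
        report["modalities"][modality] = run_modality(cohort, modality, config, out)
    if out is not None:
        write_report(report, out / "report.json")
    return report


def validate_report(report: dict[str, Any]) -> None:
    """Schema check used before writing and by report round-trip tests."""
    for key in ("schema_version", "seed", "modalities"):
        if key not in report:
            raise ConfigError(f"report missing required key '{key}'")
    if not report["modalities"]:
        raise ConfigError("report contains no modality results")
    for name, block in report["modalities"].items():
        missing = REQUIRED_MODEL_KEYS - set(block)
        if missing:
            raise ConfigError(f"modality '{name}' report missing {sorted(missing)}")


def write_report(report: dict[str, Any], path: str | Path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def summarize_report(report: dict[str, Any]) -> str:
    """Human-readable digest of a pipeline report."""
    lines = [f"mixsig report (schema {report['schema_version']}, seed {report['seed']}, "
             f"n={report.get('n_samples', '?')})"]
    for name, b in report["modalities"].items():
        ev = b["evaluation"]
        lines.append(
            f"  {name}: pool {b['n_candidates']} -> screen {b['n_screen_survivors']} "
            f"-> pruned {b['n_pruned']}; alpha={b['alpha']:.2f} lambda={b['lambda']:.3g}; "
            f"M={b['stability_median_size']} nonzero={b['n_nonzero']}; K*={b['selected_k']}")
        lines.append(
            f"    signature AUC={ev['auc']:.3f} [{ev['auc_ci'][0]:.3f}, {ev['auc_ci'][1]:.3f}]"
            f" sens={_fmt(ev['sensitivity'])} spec={_fmt(ev['specificity'])}"
            f" ppv={_fmt(ev['ppv'])} npv={_fmt(ev['npv'])}")
        pfs, osr = b["survival_pfs"], b["survival_os"]
        lines.append(
            f"    PFS HR={pfs['hazard_ratio']:.3f} (log-rank p={pfs['logrank_p']:.2g}); "
            f"OS HR={osr['hazard_ratio']:.3f} (log-rank p={osr['logrank_p']:.2g})")
        lines.append(f"    consensus K={b['selected_k']}: "
                     + ", ".join(b["consensus_sets"][str(b["selected_k"])]))
    return "\n".join(lines)


def _fmt(v: float | None) -> str:
    return "NA" if v is None else f"{v:.3f}"


def _write_sweep(sweep: subsets.SubsetSweepResult, out: Path) -> None:
    rows = []
    for k, res in sorted(sweep.per_k.items()):
        m = res.metrics
        rows.append({"k": k, "auc": m["auc"], "sensitivity": m["sensitivity"],
                     "specificity": m["specificity"], "ppv": m["ppv"], "npv": m["npv"],
                     "n_enumerated": res.n_enumerated, "exhaustive": res.exhaustive,
                     "consensus": ";".join(res.consensus)})
    pd.DataFrame(rows).to_csv(out / "subset_sweep.tsv", sep="\t", index=False)
    freq = pd.DataFrame({k: res.frequency for k, res in sorted(sweep.per_k.items())})
    freq.to_csv(out / "subset_frequency.tsv", sep="\t")


def _write_survival(comp: survival.SurvivalComparison, out: Path, stem: str) -> None:
    for g, curve in comp.km_curves.items():
        tag = g.replace("/", "_")
        curve.to_csv(out / f"km_{stem}_{tag}.tsv", sep="\t", index=False)
    (out / f"survival_{stem}.json").write_text(json.dumps(comp.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# YAML config loading

_SECTION_TYPES = {
    "panel": PanelConfig,
    "screen": ScreenConfig,
    "tuning": TuningConfig,
    "sweep": SubsetSweepConfig,
    "evaluation": EvaluationConfig,
}


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a (possibly partial) YAML file.

    Unknown keys are rejected so typos fail loudly; list-valued fields are
    converted to the tuples the dataclasses expect.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a YAML mapping")
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            sub = raw.pop(section)
            if not isinstance(sub, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(sub) - fields
            if unknown:
                raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
            sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
            kwargs[section] = cls(**sub)
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    return PipelineConfig(**kwargs, **raw)
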