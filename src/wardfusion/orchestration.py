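"""End-to-end study runner at synthetic scale.

Mirrors the two-site study design: a development cohort is generated and
used to fit every artifact (imputation medians, PLE bins, CUI vocabulary,
ICD rollup, embedding clusters, model weights); a second-seed "external"
cohort — optionally with shifted prevalence or demographics — is evaluated
with those artifacts applied frozen. Per-mode metrics, operating points,
Brier scores, subgroup tables and (for the ST model) the attribution table
are written with full config/seed provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import attribution as attr_mod
from . import cui_param, evaluation, model as model_mod, structured_preprocess as sp
from . import synthetic_cohort as sc

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "DevArtifacts", "fit_dev_artifacts", "run_experiment"]


@dataclass
class ExperimentConfig:
    dev_generator: sc.GeneratorConfig
    external_generator: sc.GeneratorConfig
    modes: tuple[str, ...] = model_mod.MODES
    model_spec: model_mod.ModelSpec = field(
        default_factory=model_mod.ModelSpec)
    window: int = 60               # CUI window at synthetic scale
    ple_bins: int = 8
    min_admissions: int = 5
    limited_features: tuple[int, ...] = ()
    max_epochs: int = 15
    tuning: bool = False
    n_trials: int = 20
    flag_fractions: tuple[float, ...] = evaluation.FLAG_FRACTIONS
    bootstrap_iterations: int = 200
    ig_config: attr_mod.IgConfig = field(default_factory=attr_mod.IgConfig)
    cluster_target: int | None = 40
    output_dir: str | None = None

    def __post_init__(self):
        if self.dev_generator.seed == self.external_generator.seed:
            raise ValueError("development and external seeds must differ")


@dataclass
class DevArtifacts:
    """Everything fit on the development cohort, applied frozen elsewhere."""

    policy: sp.ImputationPolicy
    ple: sp.PleSpec
    vocab: cui_param.CuiVocabulary
    rollup: cui_param.IcdRollupMap
    cmap: cui_param.ClusterMap
    fit_hash: str = ""

    def __post_init__(self):
        if not self.fit_hash:
            self.fit_hash = self.vocab.content_hash()


def fit_dev_artifacts(dev_cohort, config: ExperimentConfig,
                      metadata: cui_param.CuiVocabulary) -> DevArtifacts:
    n_feat = config.dev_generator.n_structured_features
    medians = sp.compute_dev_medians(dev_cohort, n_feat)
    policy = sp.ImputationPolicy.from_classes(
        n_feat, medians, limited_features=config.limited_features)
    ple = sp.fit_ple_spec(dev_cohort, n_feat, n_bins=config.ple_bins)
    vocab = cui_param.build_vocabulary(
        dev_cohort, min_admissions=config.min_admissions, metadata=metadata)
    rollup = cui_param.build_icd_rollup(vocab)
    if config.cluster_target:
        thr = cui_param.threshold_for_cluster_count(
            vocab, config.cluster_target, pca_dim=min(100, len(vocab) - 1))
    else:
        thr = 0.5
    cmap = cui_param.cluster_embeddings(
        vocab, pca_dim=min(100, len(vocab) - 1), distance_threshold=thr)
    return DevArtifacts(policy=policy, ple=ple, vocab=vocab, rollup=rollup,
                        cmap=cmap)


def _mode_model(mode: str, spec: model_mod.ModelSpec, structured_dim: int,
                art: DevArtifacts) -> model_mod.FusionModel:
    spec = spec.replace(mode=mode,
                        batch_size=model_mod.ModelSpec.default_batch_size(mode))
    if mode == "structured_only":
        return model_mod.build_model(spec, structured_dim)
    if mode in ("ST",):
        return model_mod.build_model(spec, structured_dim,
                                     cui_dim=art.vocab.n_tokens)
    if mode == "ICDR_T":
        return model_mod.build_model(
            spec, structured_dim,
            cui_dim=cui_param.FIRST_CUI_TOKEN + art.rollup.n_groups)
    if mode == "SE":
        return model_mod.build_model(
            spec, structured_dim, frozen_embeddings=art.vocab.embedding_matrix())
    if mode == "ICDR_BV":
        return model_mod.build_model(spec, structured_dim,
                                     cui_dim=art.rollup.n_groups)
    if mode == "CC":
        return model_mod.build_model(spec, structured_dim,
                                     cui_dim=art.cmap.n_clusters)
    raise ValueError(f"unknown mode {mode}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Generate, fit, externally validate and explain; return the report."""
    t0 = time.time()
    metadata = sc.generate_vocabulary(config.dev_generator)
    dev_cohort, dev_signal = sc.generate_cohort(config.dev_generator, metadata)
    ext_meta = sc.generate_vocabulary(
        config.external_generator.replace(seed=config.dev_generator.seed))
    ext_cohort, _ = sc.generate_cohort(config.external_generator, ext_meta)

    art = fit_dev_artifacts(dev_cohort, config, metadata)
    ext_cohort = cui_param.harmonize(art.vocab, ext_cohort)

    dev_oms = sp.assemble_cohort(dev_cohort, art.policy, art.ple)
    ext_oms = sp.assemble_cohort(ext_cohort, art.policy, art.ple)

    report: dict = {
        "config": {
            "dev_seed": config.dev_generator.seed,
            "external_seed": config.external_generator.seed,
            "modes": list(config.modes),
            "window": config.window,
            "fit_hash": art.fit_hash,
        },
        "signal_cuis": sorted(dev_signal.signal_cui_ids),
        "models": {},
    }
    structured_dim = dev_oms[0].structured_encoded.shape[1]

    for mode in config.modes:
        t_mode = time.time()
        try:
            dev_items = model_mod.prepare_inputs(
                dev_oms, mode, encounters=dev_cohort, vocab=art.vocab,
                rollup=art.rollup, cmap=art.cmap, window=config.window)
            ext_items = model_mod.prepare_inputs(
                ext_oms, mode, encounters=ext_cohort, vocab=art.vocab,
                rollup=art.rollup, cmap=art.cmap, window=config.window)
            spec = config.model_spec.replace(mode=mode)
            tr, val = model_mod.train_val_split(
                dev_items, seed=config.model_spec.seed)
            if config.tuning:
                spec, trial_log = model_mod.tune(
                    dev_items, spec,
                    lambda s: _mode_model(mode, s, structured_dim, art),
                    n_trials=config.n_trials, seed=config.model_spec.seed,
                    max_epochs=config.max_epochs)
            net = _mode_model(mode, spec, structured_dim, art)
            res = model_mod.train(net, tr, val, max_epochs=config.max_epochs)
            preds = model_mod.predict(net, ext_items)
            section = evaluation.evaluate_predictions(
                preds, flag_fractions=config.flag_fractions,
                n_iterations=config.bootstrap_iterations,
                seed=config.model_spec.seed)
            section["best_val_auroc"] = res.best_val_auroc
            section["stopped_epoch"] = res.stopped_epoch
            section["wall_time_s"] = round(time.time() - t_mode, 2)
            report["models"][mode] = section
            if mode == "ST":
                token_to_cui = art.vocab.token_to_cui
                table = attr_mod.global_importance(
                    net, ext_items, token_to_cui,
                    preferred_text=art.vocab.preferred_text,
                    config=config.ig_config)
                report["attribution_top20"] = table.head(20).to_dict(
                    orient="records")
                report["_attribution_table"] = table
        except Exception as exc:  # isolate per-mode failures
            logger.exception("mode %s failed", mode)
            report["models"][mode] = {"failed": True, "error": str(exc)}
    report["wall_time_s"] = round(time.time() - t0, 2)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in report.items()
                        if not k.startswith("_")}
        (out / "report.json").write_text(json.dumps(serializable, indent=2))
        (out / "experiment_config.json").write_text(json.dumps(
            {"dev_generator": dataclasses.asdict(config.dev_generator),
             "external_generator": dataclasses.asdict(config.external_generator),
             "model_spec": dataclasses.asdict(config.model_spec),
             "modes": list(config.modes)}, indent=2))
        if "_attribution_table" in report:
            report["_attribution_table"].to_csv(
                out / "attribution_table.csv", index=False)
    return report
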