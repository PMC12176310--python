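"""Shared fixtures: small generated cohorts and (session-scoped) trained models.

The expensive fixtures — trained networks on strong-signal, separable,
noise-CUI and fully-null cohorts — are session-scoped so the discrimination,
equivalence and attribution tests share one set of trainings.
"""

from __future__ import annotations

import numpy as np
import pytest

from wardfusion import (
    attribution as att,
    cui_param as cp,
    model as mm,
    structured_preprocess as sp,
    synthetic_cohort as sc,
)

WINDOW = 60  # CUI window at synthetic scale


def build_pipeline(config: sc.GeneratorConfig, ple_bins: int = 8):
    """Generate a cohort and fit its preprocessing + vocabulary artifacts."""
    meta = sc.generate_vocabulary(config)
    cohort, signal = sc.generate_cohort(config, meta)
    medians = sp.compute_dev_medians(cohort, config.n_structured_features)
    policy = sp.ImputationPolicy.from_classes(
        config.n_structured_features, medians)
    ple = sp.fit_ple_spec(cohort, config.n_structured_features, n_bins=ple_bins)
    oms = sp.assemble_cohort(cohort, policy, ple)
    vocab = cp.build_vocabulary(cohort, min_admissions=5, metadata=meta)
    return {
        "config": config, "meta": meta, "cohort": cohort, "signal": signal,
        "policy": policy, "ple": ple, "oms": oms, "vocab": vocab,
    }


def small_spec(mode: str, seed: int = 0) -> mm.ModelSpec:
    return mm.ModelSpec(
        mode=mode, hidden_units=16, dense_units=16, embedding_dim=8,
        time2vec_dim=4, dropout_rate=0.1, seed=seed,
    )


# wider concept branch used for the attribution study
def attribution_spec(seed: int = 0) -> mm.ModelSpec:
    return mm.ModelSpec(
        mode="ST", hidden_units=24, dense_units=16, embedding_dim=32,
        time2vec_dim=4, dropout_rate=0.1, learning_rate=0.015, seed=seed,
    )


def train_mode(pipe: dict, mode: str, seed: int = 0, max_epochs: int = 12,
               eval_pipe: dict | None = None, spec: mm.ModelSpec | None = None,
               window: int = WINDOW):
    """Train one mode on a pipeline; return model, internal-val predictions
    and (if ``eval_pipe`` is given) external-test predictions."""
    oms, cohort, vocab = pipe["oms"], pipe["cohort"], pipe["vocab"]
    structured_dim = oms[0].structured_encoded.shape[1]
    rollup = cp.build_icd_rollup(vocab) if mode in ("ICDR_T", "ICDR_BV") else None
    cmap = (cp.cluster_embeddings(vocab, pca_dim=min(20, len(vocab) - 1),
                                  distance_threshold=0.5)
            if mode == "CC" else None)
    items = mm.prepare_inputs(oms, mode, encounters=cohort, vocab=vocab,
                              rollup=rollup, cmap=cmap, window=window)
    tr, val = mm.train_val_split(items, seed=seed)
    spec = spec or small_spec(mode, seed=seed)
    kw = {}
    if mode in ("ST", "ICDR_T"):
        kw["cui_dim"] = (vocab.n_tokens if mode == "ST"
                         else cp.FIRST_CUI_TOKEN + rollup.n_groups)
    elif mode == "SE":
        kw["frozen_embeddings"] = vocab.embedding_matrix()
    elif mode == "ICDR_BV":
        kw["cui_dim"] = rollup.n_groups
    elif mode == "CC":
        kw["cui_dim"] = cmap.n_clusters
    net = mm.build_model(spec, structured_dim, **kw)
    result = mm.train(net, tr, val, max_epochs=max_epochs)
    val_preds = mm.predict(net, val)
    test_preds = None
    if eval_pipe is not None:
        ext_cohort = cp.harmonize(vocab, eval_pipe["cohort"])
        ext_oms = sp.assemble_cohort(ext_cohort, pipe["policy"], pipe["ple"])
        ext_items = mm.prepare_inputs(ext_oms, mode, encounters=ext_cohort,
                                      vocab=vocab, rollup=rollup, cmap=cmap,
                                      window=window)
        test_preds = mm.predict(net, ext_items)
    return {"model": net, "result": result, "items": items,
            "val_preds": val_preds, "test_preds": test_preds}


@pytest.fixture(scope="session")
def tiny_pipeline():
    """120-encounter default-condition cohort for structural tests."""
    return build_pipeline(sc.GeneratorConfig(seed=7, n_encounters=120))


@pytest.fixture(scope="session")
def attribution_runs():
    """One CUI-rich strong-signal cohort (2000 encounters), three training
    seeds of the ST model, each with its importance table. Median
    aggregation across training runs is what the attribution study reports."""
    pipe = build_pipeline(sc.strong_signal_config(seed=11, n_encounters=2000))
    runs = []
    for mseed in (0, 1, 2):
        # window 120 covers the unique-CUI accumulation of nearly every
        # encounter, so persistent concepts stay visible to the model
        run = train_mode(pipe, "ST", seed=mseed, max_epochs=15,
                         spec=attribution_spec(mseed), window=120)
        run["table"] = att.global_importance(
            run["model"], run["items"], pipe["vocab"].token_to_cui,
            preferred_text=pipe["vocab"].preferred_text,
            config=att.IgConfig(n_steps=10, sample_size=600, seed=mseed))
        runs.append(run)
    return {"pipe": pipe, "runs": runs}


@pytest.fixture(scope="session")
def separable_runs():
    """3 seeds of near-separable cohorts, ST models evaluated on external
    same-condition cohorts."""
    runs = []
    for seed in (11, 12, 13):
        pipe = build_pipeline(sc.separable_config(seed=seed, n_encounters=2000))
        ext = build_pipeline(sc.separable_config(seed=seed + 1000,
                                                 n_encounters=800))
        runs.append(train_mode(pipe, "ST", seed=seed, max_epochs=12,
                               eval_pipe=ext))
    return runs


@pytest.fixture(scope="session")
def noise_cui_run():
    """Structured signal only; CUIs carry no information. Both models
    trained on the same cohort and seed, evaluated on a second-seed
    external cohort."""
    dev = build_pipeline(sc.noise_cui_config(seed=21, n_encounters=1000))
    ext = build_pipeline(sc.noise_cui_config(seed=22, n_encounters=1000))
    structured = train_mode(dev, "structured_only", seed=21, max_epochs=12,
                            eval_pipe=ext)
    st = train_mode(dev, "ST", seed=21, max_epochs=12, eval_pipe=ext)
    return {"structured": structured, "st": st, "dev": dev, "ext": ext}


@pytest.fixture(scope="session")
def null_runs():
    """3 seeds of fully-null cohorts (no signal anywhere), structured-only
    models evaluated on larger external null cohorts."""
    runs = []
    for seed in (31, 32, 33):
        dev = build_pipeline(sc.null_config(seed=seed, n_encounters=600))
        ext = build_pipeline(sc.null_config(seed=seed + 100,
                                            n_encounters=1500))
        runs.append(train_mode(dev, "structured_only", seed=seed,
                               max_epochs=6, eval_pipe=ext))
    return runs
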