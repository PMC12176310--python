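"""Concept-level model explanation via integrated gradients + IDF weighting.

Integrated gradients (IG) attributes a differentiable model's output to its
inputs by integrating the gradient along the straight path from a baseline
input to the actual input; the integral is approximated with a Riemann sum:

    attribution_i = (x_i − b_i) · (1/m) Σ_{k=1..m} ∂F/∂x_i |_{b + (k/m)(x − b)}

For token inputs the attribution is taken at the embedding layer's output
(the standard practice for IG on embeddings), with a zero-embedding
baseline — the padding token's pinned representation. IG satisfies
*completeness*: attributions sum to F(x) − F(baseline) as m → ∞.

A single global importance score per CUI is built by summing signed
attributions over every embedding dimension, timestep and encounter where
the CUI occupies a window slot, then multiplying by the CUI's inverse
document frequency over the attribution sample,

    IDF(CUI_j) = ln(N / df_j),

which down-weights ubiquitous concepts. The sample is balanced: equal
numbers of ever-positive (case) and never-positive (control) encounters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Tensor
from .model import FusionModel, EncounterInputs, collate

logger = logging.getLogger(__name__)

__all__ = [
    "IgConfig",
    "integrated_gradients",
    "integrated_gradients_model",
    "idf",
    "global_importance",
    "rank_cuis",
]


@dataclass(frozen=True)
class IgConfig:
    n_steps: int = 50
    baseline: str = "zero_input"  # zero embedding == padding representation
    sample_size: int = 5000
    seed: int = 0
    convergence_warn_gap: float = 1e-2

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def integrated_gradients(f, x: np.ndarray, baseline: np.ndarray | None = None,
                         n_steps: int = 50) -> np.ndarray:
    """IG for any differentiable scalar function built on the package engine.

    ``f`` maps a Tensor of x's shape to a scalar Tensor. Uses right-endpoint
    Riemann evaluation points baseline + (k/m)(x − baseline), k = 1..m.
    """
    x = np.asarray(x, dtype=float)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=float)
    total = np.zeros_like(x)
    for k in range(1, n_steps + 1):
        point = Tensor(b + (k / n_steps) * (x - b), requires_grad=True)
        out = f(point)
        out.backward()
        total += point.grad
    return (x - b) * total / n_steps


def integrated_gradients_batch(
    model: FusionModel,
    items: list[EncounterInputs],
    n_steps: int = 50,
) -> np.ndarray:
    """Per-slot, per-dimension attributions (B, T, W, E) for a batch.

    The attributed input is the embedded CUI window; the scalar output is
    the masked sum of per-timestep risk scores over the batch. Encounters do
    not interact inside the network, so the batched path integral decouples
    into each encounter's own attribution (and, by linearity, summing a
    timestep's attributions over the window equals summing each score's own
    attributions). Baseline: zero embeddings with the structured and
    temporal inputs held at their actual values, so the attribution isolates
    the note-concept contribution.
    """
    if items[0].tokens is None:
        raise ValueError("integrated gradients needs a token-window mode (ST/SE)")
    batch = collate(items)
    x = model.embed_tokens(batch["tokens"])  # (B, T, W, E)

    def f(emb: Tensor) -> Tensor:
        scores = model.forward(batch, embedded_override=emb)
        return (scores * Tensor(batch["mask"])).sum()

    return integrated_gradients(f, x, baseline=np.zeros_like(x), n_steps=n_steps)


def integrated_gradients_model(
    model: FusionModel,
    item: EncounterInputs,
    n_steps: int = 50,
) -> np.ndarray:
    """Attributions (T, W, E) for a single encounter."""
    return integrated_gradients_batch(model, [item], n_steps=n_steps)[0]


def completeness_gap(model: FusionModel, item: EncounterInputs,
                     n_steps: int = 50) -> float:
    """|Σ attributions − (F(x) − F(baseline))| for the self-check."""
    batch = collate([item])
    x = model.embed_tokens(batch["tokens"])

    def f_np(emb_data: np.ndarray) -> float:
        scores = model.forward(batch, embedded_override=Tensor(emb_data))
        return float((scores.data * batch["mask"]).sum())

    attr = integrated_gradients_model(model, item, n_steps=n_steps)
    return abs(attr.sum() - (f_np(x) - f_np(np.zeros_like(x))))


def idf(n_encounters: int, df: int) -> float:
    """Inverse document frequency ln(N / df) (natural log)."""
    if not (1 <= df <= n_encounters):
        raise ValueError("df must lie in [1, N]")
    return float(np.log(n_encounters / df))


def _balanced_sample(items: list[EncounterInputs], n: int,
                     rng: np.random.Generator) -> list[EncounterInputs]:
    cases = [it for it in items if it.label.any()]
    controls = [it for it in items if not it.label.any()]
    half = n // 2
    k = min(half, len(cases), len(controls))
    if k < half:
        logger.info("balanced sample reduced to %d per arm (requested %d)", k, half)
    if k == 0:
        raise ValueError("cannot form a balanced case/control sample")
    chosen = (
        [cases[i] for i in rng.choice(len(cases), size=k, replace=False)]
        + [controls[i] for i in rng.choice(len(controls), size=k, replace=False)]
    )
    return chosen


def global_importance(
    model: FusionModel,
    items: list[EncounterInputs],
    token_to_cui: dict[int, str],
    preferred_text: dict[str, str] | None = None,
    config: IgConfig = IgConfig(),
) -> pd.DataFrame:
    """The IDF-weighted global CUI importance table.

    For each CUI j: sum signed IG attributions over every (encounter,
    timestep, embedding dimension) where j occupies a window slot in the
    balanced sample; multiply by IDF_j = ln(N / df_j), where N is the sample
    size and df_j the number of sampled encounters containing j. Returns a
    table sorted by importance descending.
    """
    rng = np.random.default_rng(config.seed)
    sample = _balanced_sample(items, config.sample_size, rng)
    N = len(sample)

    raw: dict[int, float] = {}
    df_counts: dict[int, int] = {}
    chunk = 32
    for start in range(0, N, chunk):
        part = sample[start:start + chunk]
        attrs = integrated_gradients_batch(model, part, n_steps=config.n_steps)
        for bi, item in enumerate(part):
            T = item.tokens.shape[0]
            per_slot = attrs[bi, :T].sum(axis=-1)  # (T, W) over embedding dims
            toks = item.tokens
            for tok in np.unique(toks):
                if tok < 2:  # padding / OOV carry no concept
                    continue
                raw[tok] = raw.get(tok, 0.0) + float(per_slot[toks == tok].sum())
                df_counts[tok] = df_counts.get(int(tok), 0) + 1

    rows = []
    for tok, total in raw.items():
        df_j = df_counts[tok]
        w = idf(N, df_j)
        cui = token_to_cui.get(int(tok), f"token_{tok}")
        rows.append(
            {"cui": cui,
             "preferred_text": (preferred_text or {}).get(cui, ""),
             "df": df_j,
             "idf": w,
             "raw_attribution_sum": total,
             "importance_score": total * w}
        )
    table = pd.DataFrame(rows).sort_values(
        ["importance_score", "cui"], ascending=[False, True]
    ).reset_index(drop=True)
    return table


def rank_cuis(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k CUIs by importance, ties broken by CUI string."""
    if len(table) == 0:
        raise ValueError("empty attribution table")
    ordered = table.sort_values(["importance_score", "cui"],
                                ascending=[False, True])
    return ordered.head(min(k, len(ordered))).reset_index(drop=True)
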