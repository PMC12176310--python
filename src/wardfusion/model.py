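"""Intermediate-fusion recurrent models for 24-hour deterioration risk.

Six variants share one architecture skeleton. At every timestep the model
sees three inputs: the encoded structured vector, hours since admission, and
(in multimodal modes) a representation of the recent-note CUI window.

* structured branch: fully connected layer + dropout;
* temporal branch: Time2Vec (one linear component, sinusoidal components);
* these two are concatenated and passed through a recurrent stack (GRU or
  LSTM), emitting a hidden state at every timestep;
* CUI branch (mode-dependent): ST / ICDR-T — learned embeddings, dropout,
  average/max pooling over the window, dropout, recurrent stack; SE — the
  same but with a frozen pretrained embedding matrix; ICDR-BV / CC — the
  binary presence vector, dropout, recurrent stack; structured-only — no
  branch;
* the per-timestep representations are concatenated and a single dense unit
  with sigmoid yields one risk score per observation.

Training uses per-timestep binary cross-entropy masked over padding, an
adaptive first-order optimizer (Adam), and early stopping on validation
AUROC (stop when no epoch in the last ``patience`` improved the best by at
least ``min_delta``; the best-epoch weights are returned). The recurrence is
strictly causal: the score at timestep t never depends on later inputs.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor, concat, stack
from .cui_param import (
    ClusterMap,
    CuiVocabulary,
    IcdRollupMap,
    FIRST_CUI_TOKEN,
    DEFAULT_WINDOW,
    align_cuis_to_timesteps,
    apply_rollup_tokens,
    cluster_matrix,
    rollup_matrix,
)
from .structured_preprocess import ObservationMatrix

logger = logging.getLogger(__name__)

MODES = ("structured_only", "ST", "ICDR_T", "ICDR_BV", "SE", "CC")

__all__ = [
    "ModelSpec",
    "TrainResult",
    "FusionModel",
    "time2vec",
    "build_model",
    "prepare_inputs",
    "train",
    "tune",
    "predict",
    "train_val_split",
    "DEFAULT_SEARCH_SPACE",
]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one model variant."""

    mode: str = "structured_only"
    recurrent_cell: str = "gru"
    n_recurrent_layers: int = 1
    hidden_units: int = 32
    dense_units: int = 32
    dropout_rate: float = 0.1
    pooling: str = "average"
    time2vec_dim: int = 8
    embedding_dim: int = 16
    batch_size: int = 32
    learning_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.recurrent_cell not in ("gru", "lstm"):
            raise ValueError("recurrent_cell must be 'gru' or 'lstm'")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.pooling not in ("average", "max"):
            raise ValueError("pooling must be 'average' or 'max'")
        if self.time2vec_dim < 2:
            raise ValueError("time2vec_dim must be >= 2")

    @staticmethod
    def default_batch_size(mode: str) -> int:
        # the frozen-embedding mode carries the widest inputs
        return 16 if mode == "SE" else 32

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class TrainResult:
    model: "FusionModel"
    history: list[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_val_auroc: float = float("nan")


def time2vec(tau: np.ndarray | float, omega: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Reference Time2Vec: component 1 linear, components >1 sinusoidal."""
    tau = np.asarray(tau, dtype=float)[..., None]
    lin = omega[0] * tau[..., 0:1] + phi[0]
    per = np.sin(tau * omega[1:] + phi[1:])
    return np.concatenate([lin, per], axis=-1)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class FusionModel:
    """One intermediate-fusion recurrent network (all six modes)."""

    def __init__(self, spec: ModelSpec, structured_dim: int,
                 cui_dim: int | None = None,
                 frozen_embeddings: np.ndarray | None = None):
        """`cui_dim` is the vocabulary token count for ST/ICDR_T, the binary
        vector width for ICDR_BV/CC, and ignored for structured_only; SE
        requires `frozen_embeddings` of shape (n_tokens, E)."""
        self.spec = spec
        self.structured_dim = structured_dim
        self.cui_dim = cui_dim
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(spec.seed)
        H, D, K = spec.hidden_units, spec.dense_units, spec.time2vec_dim

        def par(name, arr):
            self.params[name] = Tensor(arr, requires_grad=True)

        par("struct_W", _glorot(rng, structured_dim, D))
        par("struct_b", np.zeros(D))
        par("t2v_omega", rng.normal(scale=0.5, size=K))
        par("t2v_phi", rng.normal(scale=0.5, size=K))

        self._add_rnn("main", D + K, H, rng)
        fused = H

        self.frozen_embeddings = None
        if spec.mode in ("ST", "ICDR_T"):
            emb0 = rng.normal(scale=0.01, size=(cui_dim, spec.embedding_dim))
            emb0[0] = 0.0  # padding row pinned to zero (masked in pooling)
            par("cui_emb", emb0)
            self._add_rnn("cui", spec.embedding_dim, H, rng)
            fused += H
        elif spec.mode == "SE":
            if frozen_embeddings is None:
                raise ValueError("SE mode requires a frozen embedding matrix")
            self.frozen_embeddings = np.asarray(frozen_embeddings, dtype=float)
            self._add_rnn("cui", self.frozen_embeddings.shape[1], H, rng)
            fused += H
        elif spec.mode in ("ICDR_BV", "CC"):
            if cui_dim is None:
                raise ValueError(f"{spec.mode} requires the binary-vector width")
            self._add_rnn("cui", cui_dim, H, rng)
            fused += H

        par("head_W", _glorot(rng, fused, 1))
        par("head_b", np.zeros(1))

    # -- parameter plumbing ---------------------------------------------------
    def _add_rnn(self, branch: str, input_dim: int, hidden: int,
                 rng: np.random.Generator) -> None:
        gates = 3 if self.spec.recurrent_cell == "gru" else 4
        d = input_dim
        for layer in range(self.spec.n_recurrent_layers):
            p = f"{branch}_l{layer}"
            self.params[f"{p}_W"] = Tensor(_glorot(rng, d, gates * hidden),
                                           requires_grad=True)
            self.params[f"{p}_U"] = Tensor(_glorot(rng, hidden, gates * hidden),
                                           requires_grad=True)
            self.params[f"{p}_b"] = Tensor(np.zeros(gates * hidden),
                                           requires_grad=True)
            d = hidden

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    # -- forward --------------------------------------------------------------
    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.spec.dropout_rate
        if rng is None or p == 0.0:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def _rnn(self, branch: str, x: Tensor) -> Tensor:
        """Run the branch's recurrent stack over (B, T, d) → (B, T, H)."""
        H = self.spec.hidden_units
        B, T = x.shape[0], x.shape[1]
        out = x
        for layer in range(self.spec.n_recurrent_layers):
            p = f"{branch}_l{layer}"
            W, U, b = (self.params[f"{p}_W"], self.params[f"{p}_U"],
                       self.params[f"{p}_b"])
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            steps = []
            for t in range(T):
                xt = out[:, t, :]
                pre = xt @ W + h @ U + b
                if self.spec.recurrent_cell == "gru":
                    z = pre[:, 0:H].sigmoid()
                    r = pre[:, H:2 * H].sigmoid()
                    # candidate uses the reset-gated hidden state
                    n = (xt @ W[:, 2 * H:3 * H]
                         + (r * h) @ U[:, 2 * H:3 * H]
                         + b[2 * H:3 * H]).tanh()
                    h = (Tensor(1.0) - z) * n + z * h
                else:
                    i = pre[:, 0:H].sigmoid()
                    f = pre[:, H:2 * H].sigmoid()
                    g = pre[:, 2 * H:3 * H].tanh()
                    o = pre[:, 3 * H:4 * H].sigmoid()
                    c = f * c + i * g
                    h = o * c.tanh()
                steps.append(h)
            out = stack(steps, axis=1)
        return out

    def _time2vec(self, hours: np.ndarray) -> Tensor:
        K = self.spec.time2vec_dim
        omega, phi = self.params["t2v_omega"], self.params["t2v_phi"]
        tau = Tensor(hours[..., None])  # (B, T, 1)
        lin = tau @ omega[0:1].reshape(1, 1) + phi[0:1]
        per = (tau @ omega[1:K].reshape(1, K - 1) + phi[1:K]).sin()
        return concat([lin, per], axis=-1)

    def forward(self, batch: dict, rng: np.random.Generator | None = None,
                embedded_override: Tensor | None = None) -> Tensor:
        """Risk scores (B, T). `rng` enables dropout (training mode).

        `embedded_override` replaces the CUI embedding lookup with an
        explicit (B, T, W, E) tensor — the hook integrated gradients uses to
        differentiate with respect to the embedded CUI input.
        """
        spec = self.spec
        structured = Tensor(batch["structured"])
        s = (structured @ self.params["struct_W"] + self.params["struct_b"]).relu()
        s = self._dropout(s, rng)
        tv = self._time2vec(batch["hours"])
        main = self._rnn("main", concat([s, tv], axis=-1))
        reps = [main]

        if spec.mode in ("ST", "ICDR_T", "SE"):
            if embedded_override is not None:
                emb = embedded_override
            elif spec.mode == "SE":
                emb = Tensor(self.frozen_embeddings[batch["tokens"]])
            else:
                B, T, W = batch["tokens"].shape
                emb = self.params["cui_emb"].gather_rows(
                    batch["tokens"].reshape(-1)
                ).reshape(B, T, W, spec.embedding_dim)
            # padding slots contribute zero rows (row 0 of every embedding
            # table is pinned to zero), so max pooling saturates at >= 0 and
            # average pooling — dividing by the fixed window length — keeps
            # the pooled vector proportional to the *sum* of present-concept
            # embeddings: additive concept effects stay linearly representable
            emb = self._dropout(emb, rng)
            if spec.pooling == "average":
                pooled = emb.sum(axis=2) * (1.0 / emb.shape[2])
            else:
                pooled = emb.max(axis=2)
            pooled = self._dropout(pooled, rng)
            reps.append(self._rnn("cui", pooled))
        elif spec.mode in ("ICDR_BV", "CC"):
            bv = self._dropout(Tensor(batch["binary"]), rng)
            reps.append(self._rnn("cui", bv))

        fused = concat(reps, axis=-1) if len(reps) > 1 else reps[0]
        logits = fused @ self.params["head_W"] + self.params["head_b"]
        return logits.reshape(logits.shape[0], logits.shape[1]).sigmoid()

    def embed_tokens(self, tokens: np.ndarray) -> np.ndarray:
        """Embedded CUI windows (B, T, W, E) for the current mode."""
        if self.spec.mode == "SE":
            return self.frozen_embeddings[tokens]
        return self.params["cui_emb"].data[tokens]


def build_model(spec: ModelSpec, structured_dim: int, cui_dim: int | None = None,
                frozen_embeddings: np.ndarray | None = None) -> FusionModel:
    return FusionModel(spec, structured_dim, cui_dim, frozen_embeddings)


# ---------------------------------------------------------------------------
# input preparation and batching
# ---------------------------------------------------------------------------


@dataclass
class EncounterInputs:
    encounter_id: str
    structured: np.ndarray          # (T, S)
    hours: np.ndarray               # (T,)
    label: np.ndarray               # (T,)
    tokens: np.ndarray | None       # (T, W) for ST/ICDR_T/SE
    binary: np.ndarray | None       # (T, G) for ICDR_BV/CC
    subgroups: dict = field(default_factory=dict)


def prepare_inputs(
    oms: Sequence[ObservationMatrix],
    mode: str,
    encounters=None,
    vocab: CuiVocabulary | None = None,
    rollup: IcdRollupMap | None = None,
    cmap: ClusterMap | None = None,
    window: int = DEFAULT_WINDOW,
) -> list[EncounterInputs]:
    """Attach the mode's CUI representation to each observation matrix."""
    by_id = {e.encounter_id: e for e in (encounters or [])}
    out = []
    for om in oms:
        tokens = binary = None
        if mode != "structured_only":
            enc = by_id.get(om.encounter_id)
            if enc is None:
                raise ValueError(f"no encounter record for {om.encounter_id}")
            win = align_cuis_to_timesteps(enc, vocab, om.timesteps, window=window)
            if mode in ("ST", "SE"):
                tokens = win
            elif mode == "ICDR_T":
                tokens = apply_rollup_tokens(win, rollup)
            elif mode == "ICDR_BV":
                binary = rollup_matrix(win, rollup)
            elif mode == "CC":
                binary = cluster_matrix(win, cmap)
            else:
                raise ValueError(f"unknown mode {mode}")
        out.append(
            EncounterInputs(
                encounter_id=om.encounter_id,
                structured=om.structured_encoded,
                hours=om.hours_since_admission,
                label=om.label,
                tokens=tokens,
                binary=binary,
                subgroups={"sex": om.sex, "race": om.race,
                           "ethnicity": om.ethnicity, "age_band": om.age_band},
            )
        )
    return out


def collate(items: Sequence[EncounterInputs]) -> dict:
    """Pad a list of encounters to a batch (mask marks real timesteps)."""
    B = len(items)
    T = max(it.structured.shape[0] for it in items)
    S = items[0].structured.shape[1]
    batch = {
        "structured": np.zeros((B, T, S)),
        "hours": np.zeros((B, T)),
        "label": np.zeros((B, T)),
        "mask": np.zeros((B, T)),
    }
    if items[0].tokens is not None:
        W = items[0].tokens.shape[1]
        batch["tokens"] = np.zeros((B, T, W), dtype=np.int64)
    if items[0].binary is not None:
        G = items[0].binary.shape[1]
        batch["binary"] = np.zeros((B, T, G))
    for i, it in enumerate(items):
        t = it.structured.shape[0]
        batch["structured"][i, :t] = it.structured
        batch["hours"][i, :t] = it.hours
        batch["label"][i, :t] = it.label
        batch["mask"][i, :t] = 1.0
        if it.tokens is not None:
            batch["tokens"][i, :t] = it.tokens
        if it.binary is not None:
            batch["binary"][i, :t] = it.binary
    return batch


def masked_bce(scores: Tensor, label: np.ndarray, mask: np.ndarray) -> Tensor:
    eps = 1e-12
    y = Tensor(label)
    m = Tensor(mask)
    ll = y * (scores + eps).log() + (Tensor(1.0) - y) * (Tensor(1.0) - scores + eps).log()
    return -(ll * m).sum() * (1.0 / max(mask.sum(), 1.0))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_val_split(items: Sequence, val_fraction: float = 0.2,
                    seed: int = 0) -> tuple[list, list]:
    """Split disjointly by encounter, deterministically."""
    idx = np.arange(len(items))
    np.random.default_rng(seed).shuffle(idx)
    n_val = max(1, int(round(val_fraction * len(items))))
    val = [items[i] for i in idx[:n_val]]
    tr = [items[i] for i in idx[n_val:]]
    return tr, val


def _eval_auroc(model: FusionModel, items: Sequence[EncounterInputs],
                batch_size: int = 64) -> float:
    from .evaluation import auroc_arrays

    scores, labels = [], []
    for i in range(0, len(items), batch_size):
        batch = collate(items[i:i + batch_size])
        s = model.forward(batch).data
        m = batch["mask"] > 0
        scores.append(s[m])
        labels.append(batch["label"][m])
    y = np.concatenate(labels)
    p = np.concatenate(scores)
    if y.min() == y.max():
        return float("nan")
    return auroc_arrays(y, p)


def train(
    model: FusionModel,
    train_items: Sequence[EncounterInputs],
    val_items: Sequence[EncounterInputs],
    max_epochs: int = 50,
    min_delta: float = 0.005,
    patience: int = 5,
) -> TrainResult:
    """Fit with Adam + early stopping on validation AUROC.

    Stops when no epoch among the last ``patience`` improved the running
    best by at least ``min_delta``; weights from the best-AUROC epoch are
    restored before returning.
    """
    if not train_items or not val_items:
        raise ValueError("train and validation splits must be nonempty")
    ids_tr = {it.encounter_id for it in train_items}
    if ids_tr & {it.encounter_id for it in val_items}:
        raise ValueError("train/validation splits share encounters")
    spec = model.spec
    opt = nn.Adam(model.params, lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    drop_rng = np.random.default_rng(spec.seed + 2)

    result = TrainResult(model=model)
    best = -np.inf
    best_state = model.state_dict()
    since_improve = 0
    order = np.arange(len(train_items))
    for epoch in range(1, max_epochs + 1):
        rng.shuffle(order)
        losses = []
        for i in range(0, len(order), spec.batch_size):
            batch = collate([train_items[j] for j in order[i:i + spec.batch_size]])
            opt.zero_grad()
            scores = model.forward(batch, rng=drop_rng)
            loss = masked_bce(scores, batch["label"], batch["mask"])
            loss.backward()
            emb_par = model.params.get("cui_emb")
            if emb_par is not None and emb_par.grad is not None:
                emb_par.grad[0] = 0.0  # keep the padding row pinned at zero
            opt.step()
            losses.append(float(loss.data))
        val_auroc = _eval_auroc(model, val_items)
        result.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_auroc": val_auroc}
        )
        improved = np.isfinite(val_auroc) and val_auroc >= best + min_delta
        if np.isfinite(val_auroc) and val_auroc > best:
            best = val_auroc
            best_state = model.state_dict()
            result.best_epoch = epoch
        since_improve = 0 if improved else since_improve + 1
        if since_improve >= patience:
            break
    result.stopped_epoch = len(result.history)
    result.best_val_auroc = best if np.isfinite(best) else float("nan")
    model.load_state_dict(best_state)
    return result


def predict(
    model: FusionModel, items: Sequence[EncounterInputs], batch_size: int = 64
) -> pd.DataFrame:
    """Per-observation risk scores with labels and subgroup attributes."""
    rows = []
    for i in range(0, len(items), batch_size):
        chunk = items[i:i + batch_size]
        batch = collate(chunk)
        s = model.forward(batch).data
        for bi, it in enumerate(chunk):
            t = it.structured.shape[0]
            for ti in range(t):
                rows.append(
                    {"encounter_id": it.encounter_id,
                     "timestep": float(it.hours[ti]),
                     "score": float(s[bi, ti]),
                     "label": int(it.label[ti]),
                     **it.subgroups}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE = {
    "recurrent_cell": ["gru", "lstm"],
    "n_recurrent_layers": [1, 2],
    "hidden_units": (16, 64),
    "dense_units": (16, 64),
    "dropout_rate": (0.0, 0.5),
    "time2vec_dim": [4, 8, 16],
    "pooling": ["average", "max"],
    "learning_rate": (1e-3, 3e-2, "log"),
}


def _sample_spec(space: dict, base: ModelSpec, rng: np.random.Generator) -> ModelSpec:
    kw = {}
    for key, choices in space.items():
        if isinstance(choices, list):
            kw[key] = choices[rng.integers(len(choices))]
        elif len(choices) == 3 and choices[2] == "log":
            lo, hi = np.log(choices[0]), np.log(choices[1])
            kw[key] = float(np.exp(rng.uniform(lo, hi)))
        elif isinstance(choices[0], int):
            kw[key] = int(rng.integers(choices[0], choices[1] + 1))
        else:
            kw[key] = float(rng.uniform(choices[0], choices[1]))
    return base.replace(**kw)


def _encode_spec(spec: ModelSpec, space: dict) -> np.ndarray:
    vec = []
    for key, choices in space.items():
        v = getattr(spec, key)
        if isinstance(choices, list):
            vec.append(choices.index(v) / max(len(choices) - 1, 1))
        elif len(choices) == 3 and choices[2] == "log":
            vec.append((np.log(v) - np.log(choices[0]))
                       / (np.log(choices[1]) - np.log(choices[0])))
        else:
            vec.append((v - choices[0]) / (choices[1] - choices[0]))
    return np.asarray(vec, dtype=float)


def tune(
    items: Sequence[EncounterInputs],
    base_spec: ModelSpec,
    build_fn,
    search_space: dict | None = None,
    n_trials: int = 20,
    seed: int = 0,
    max_epochs: int = 15,
    strategy: str = "random",
    val_fraction: float = 0.2,
) -> tuple[ModelSpec, list[dict]]:
    """Hyperparameter search maximizing validation AUROC on an 80/20 split.

    ``strategy='random'`` draws every trial from the space; ``'smbo'`` runs
    sequential model-based optimization (Gaussian-process surrogate with
    expected improvement over random candidates) after 5 seeding trials.
    ``build_fn(spec) -> FusionModel`` constructs the model for a spec.
    Deterministic given ``seed``. Returns (best spec, trial log).
    """
    space = search_space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed)
    tr, val = train_val_split(list(items), val_fraction, seed=seed)
    log: list[dict] = []
    evaluated: list[tuple[np.ndarray, float]] = []
    best_spec, best_score = base_spec, -np.inf

    for trial in range(n_trials):
        if strategy == "smbo" and trial >= 5:
            spec = _propose_smbo(space, base_spec, evaluated, rng)
        else:
            spec = _sample_spec(space, base_spec, rng)
        spec = spec.replace(seed=base_spec.seed + trial)
        model = build_fn(spec)
        res = train(model, tr, val, max_epochs=max_epochs)
        score = res.best_val_auroc
        log.append({"trial": trial, "spec": dataclasses.asdict(spec),
                    "val_auroc": score, "epochs": res.stopped_epoch})
        evaluated.append((_encode_spec(spec, space), score))
        if np.isfinite(score) and score > best_score:
            best_spec, best_score = spec, score
    return best_spec, log


def _propose_smbo(space, base, evaluated, rng, n_candidates: int = 64) -> ModelSpec:
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    X = np.stack([x for x, _ in evaluated])
    y = np.asarray([s for _, s in evaluated])
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return _sample_spec(space, base, rng)
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-4,
                                  normalize_y=True, random_state=0)
    gp.fit(X[ok], y[ok])
    candidates = [_sample_spec(space, base, rng) for _ in range(n_candidates)]
    Xc = np.stack([_encode_spec(c, space) for c in candidates])
    mu, sd = gp.predict(Xc, return_std=True)
    best = y[ok].max()
    sd = np.maximum(sd, 1e-9)
    z = (mu - best) / sd
    ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
    return candidates[int(np.argmax(ei))]
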