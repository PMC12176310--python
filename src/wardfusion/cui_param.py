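"""Parameterizing note-derived UMLS concepts (CUIs) for sequence models.

Clinical NLP pipelines reduce free-text notes to timestamped sets of concept
unique identifiers (CUIs). Before a neural model can consume them, CUIs need
a numerical parameterization. This module implements the vocabulary layer and
the five strategies compared by the package:

* **ST** — standard tokenization: bijective CUI → integer map, tokens feed a
  learned embedding table.
* **ICDR-T** — ICD rollup + tokenization: CUIs whose ICD codes share a
  3-character prefix collapse to one token; code-less CUIs share one group.
* **ICDR-BV** — the rollup groups as a sparse presence/absence binary vector.
* **SE** — tokens index a *frozen* pretrained embedding matrix (one vector
  per CUI, e.g. a 768-dim transformer sentence embedding of its preferred
  text).
* **CC** — CUIs clustered in embedding space (PCA + agglomerative clustering
  on cosine distances); clusters become a presence/absence binary vector.

Token conventions: 0 = padding, 1 = out-of-vocabulary, real tokens ≥ 2.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.cluster import AgglomerativeClustering

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_cohort import EncounterRecord

logger = logging.getLogger(__name__)

PAD_TOKEN = 0
OOV_TOKEN = 1
FIRST_CUI_TOKEN = 2
DEFAULT_WINDOW = 360  # most-recent unique CUIs pulled forward per timestep

__all__ = [
    "CuiVocabulary",
    "IcdRollupMap",
    "ClusterMap",
    "build_vocabulary",
    "harmonize",
    "align_cuis_to_timesteps",
    "tokenize",
    "build_icd_rollup",
    "binarize",
    "embed_lookup",
    "cluster_embeddings",
    "cluster_binarize",
    "threshold_for_cluster_count",
]


@dataclass
class CuiVocabulary:
    """CUI ↔ token bijection plus per-CUI metadata.

    ``admission_df`` counts distinct admissions containing the CUI (document
    frequency at encounter level), the quantity both the vocabulary filter
    and the attribution IDF are built on.
    """

    cui_to_token: dict[str, int]
    preferred_text: dict[str, str] = field(default_factory=dict)
    icd_code: dict[str, str] = field(default_factory=dict)
    embedding: dict[str, np.ndarray] = field(default_factory=dict)
    admission_df: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        tokens = list(self.cui_to_token.values())
        if len(set(tokens)) != len(tokens):
            raise ValueError("cui_to_token must be one-to-one")
        if any(t < FIRST_CUI_TOKEN for t in tokens):
            raise ValueError("tokens 0 (padding) and 1 (OOV) are reserved")
        self.token_to_cui = {t: c for c, t in self.cui_to_token.items()}

    @classmethod
    def from_metadata(cls, cuis: Sequence[str], preferred_text=None, icd_code=None,
                      embedding=None, admission_df=None) -> "CuiVocabulary":
        """Assign tokens by descending admission_df, ties by CUI string."""
        admission_df = admission_df or {}
        order = sorted(cuis, key=lambda c: (-admission_df.get(c, 0), c))
        mapping = {c: FIRST_CUI_TOKEN + i for i, c in enumerate(order)}
        return cls(
            cui_to_token=mapping,
            preferred_text=dict(preferred_text or {}),
            icd_code=dict(icd_code or {}),
            embedding={k: np.asarray(v, dtype=float)
                       for k, v in (embedding or {}).items()},
            admission_df=dict(admission_df or {}),
        )

    def __len__(self) -> int:
        return len(self.cui_to_token)

    def __contains__(self, cui: str) -> bool:
        return cui in self.cui_to_token

    @property
    def cuis(self) -> list[str]:
        return sorted(self.cui_to_token, key=self.cui_to_token.get)

    @property
    def n_tokens(self) -> int:
        """Total token-index space including padding and OOV."""
        return FIRST_CUI_TOKEN + len(self.cui_to_token)

    def embedding_matrix(self, dim: int | None = None) -> np.ndarray:
        """(n_tokens, E) matrix; padding and OOV rows are zero."""
        dims = {v.shape[0] for v in self.embedding.values()}
        if not dims:
            raise ValueError("vocabulary has no embeddings")
        if len(dims) != 1:
            raise ValueError("inconsistent embedding dimensions")
        E = dim or dims.pop()
        mat = np.zeros((self.n_tokens, E))
        for cui, tok in self.cui_to_token.items():
            if cui not in self.embedding:
                raise ValueError(f"CUI {cui} has no embedding")
            mat[tok] = self.embedding[cui]
        return mat

    def content_hash(self) -> str:
        payload = json.dumps(
            {"map": self.cui_to_token, "icd": self.icd_code,
             "df": self.admission_df},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "cui_to_token": self.cui_to_token,
            "preferred_text": self.preferred_text,
            "icd_code": self.icd_code,
            "embedding": {k: v.tolist() for k, v in self.embedding.items()},
            "admission_df": self.admission_df,
            "content_hash": self.content_hash(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "CuiVocabulary":
        obj = json.loads(Path(path).read_text())
        vocab = cls(
            cui_to_token={k: int(v) for k, v in obj["cui_to_token"].items()},
            preferred_text=obj["preferred_text"],
            icd_code=obj["icd_code"],
            embedding={k: np.asarray(v) for k, v in obj["embedding"].items()},
            admission_df={k: int(v) for k, v in obj["admission_df"].items()},
        )
        if obj.get("content_hash") and obj["content_hash"] != vocab.content_hash():
            raise ValueError("vocabulary content hash mismatch")
        return vocab


@dataclass(frozen=True)
class IcdRollupMap:
    """Total map token → rollup group; group 0 holds code-less CUIs."""

    token_to_group: dict[int, int]
    n_groups: int

    def __getitem__(self, token: int) -> int:
        return self.token_to_group[token]


@dataclass(frozen=True)
class ClusterMap:
    """Total map token → embedding cluster."""

    token_to_cluster: dict[int, int]
    n_clusters: int
    pca_dim: int
    distance_threshold: float
    linkage: str

    def __getitem__(self, token: int) -> int:
        return self.token_to_cluster[token]


# ---------------------------------------------------------------------------
# vocabulary construction and harmonization
# ---------------------------------------------------------------------------


def build_vocabulary(
    dev_cohort: Iterable["EncounterRecord"],
    min_admissions: int = 5,
    metadata: CuiVocabulary | None = None,
) -> CuiVocabulary:
    """Build the development vocabulary from note events.

    Document frequency counts *distinct admissions* containing a CUI, not
    mentions; CUIs below ``min_admissions`` are dropped. Token order is
    deterministic: descending df, ties broken by CUI string. Optional
    ``metadata`` supplies preferred text / ICD codes / embeddings for the
    retained CUIs.
    """
    df: dict[str, int] = {}
    any_notes = False
    for enc in dev_cohort:
        seen: set[str] = set()
        for _, cset in enc.note_events:
            any_notes = True
            seen.update(cset)
        for c in seen:
            df[c] = df.get(c, 0) + 1
    if not any_notes:
        logger.warning("empty note stream: building empty vocabulary")
    kept = {c: n for c, n in df.items() if n >= min_admissions}
    meta_text = meta_icd = meta_emb = {}
    if metadata is not None:
        meta_text = {c: metadata.preferred_text[c] for c in kept
                     if c in metadata.preferred_text}
        meta_icd = {c: metadata.icd_code[c] for c in kept if c in metadata.icd_code}
        meta_emb = {c: metadata.embedding[c] for c in kept if c in metadata.embedding}
    return CuiVocabulary.from_metadata(
        cuis=list(kept),
        preferred_text=meta_text,
        icd_code=meta_icd,
        embedding=meta_emb,
        admission_df=kept,
    )


def harmonize(
    dev_vocab: CuiVocabulary, external_cohort: Iterable["EncounterRecord"]
) -> list["EncounterRecord"]:
    """Keep only development-vocabulary CUIs in an external cohort's notes."""
    import dataclasses as _dc

    out, dropped = [], 0
    for enc in external_cohort:
        new_notes = []
        for t, cset in enc.note_events:
            kept = frozenset(c for c in cset if c in dev_vocab)
            dropped += len(cset) - len(kept)
            new_notes.append((t, kept))
        out.append(_dc.replace(enc, note_events=new_notes))
    if dropped:
        logger.info("harmonize: dropped %d out-of-vocabulary CUI mentions", dropped)
    return out


def align_cuis_to_timesteps(
    encounter: "EncounterRecord",
    vocab: CuiVocabulary,
    timesteps: Sequence[float],
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Pull forward the most recent `window` unique CUIs before each timestep.

    For each structured timestep t, all note CUIs with note timestamp ≤ t
    contribute; duplicates keep their *latest* occurrence, ranking is by that
    occurrence time descending (most recent first), truncated to ``window``
    and padded with token 0. Returns an int array (T, window).
    """
    T = len(timesteps)
    out = np.full((T, window), PAD_TOKEN, dtype=np.int64)
    notes = sorted(encounter.note_events, key=lambda nc: nc[0])
    latest: dict[str, float] = {}
    order: dict[str, int] = {}  # tie-break: later note event index wins
    ni = 0
    counter = 0
    for ti, t in enumerate(sorted(timesteps)):
        while ni < len(notes) and notes[ni][0] <= t:
            for c in sorted(notes[ni][1]):
                latest[c] = notes[ni][0]
                order[c] = counter
                counter += 1
            ni += 1
        if not latest:
            continue
        ranked = sorted(latest, key=lambda c: (-latest[c], -order[c]))[:window]
        toks = [vocab.cui_to_token.get(c, OOV_TOKEN) for c in ranked]
        out[ti, : len(toks)] = toks
    return out


def tokenize(cuis: Sequence[str], vocab: CuiVocabulary,
             rollup: IcdRollupMap | None = None) -> list[int]:
    """Map CUI strings to integer tokens (optionally composed with a rollup).

    Unknown CUIs map to the OOV token; under a rollup, tokens are rollup
    group indices shifted past the reserved padding/OOV slots.
    """
    toks = [vocab.cui_to_token.get(c, OOV_TOKEN) for c in cuis]
    if rollup is None:
        return toks
    return [
        t if t in (PAD_TOKEN, OOV_TOKEN) else FIRST_CUI_TOKEN + rollup[t]
        for t in toks
    ]


def apply_rollup_tokens(tokens: np.ndarray, rollup: IcdRollupMap) -> np.ndarray:
    """Vectorized rollup of a token array (padding/OOV pass through)."""
    lut = np.arange(max(tokens.max() + 1 if tokens.size else 2,
                        max(rollup.token_to_group, default=1) + 1))
    for t, g in rollup.token_to_group.items():
        lut[t] = FIRST_CUI_TOKEN + g
    lut[PAD_TOKEN] = PAD_TOKEN
    lut[OOV_TOKEN] = OOV_TOKEN
    return lut[tokens]


def build_icd_rollup(vocab: CuiVocabulary) -> IcdRollupMap:
    """Group CUIs by the first 3 characters of their ICD code.

    Code-less CUIs all land in group 0. Coded groups are indexed 1..G-1 in
    sorted key order. Codes shorter than 3 characters keep their full string
    as the key (logged). Built on the development vocabulary and then applied
    frozen to any external data.
    """
    keys: dict[str, str | None] = {}
    for cui in vocab.cui_to_token:
        code = vocab.icd_code.get(cui)
        if code is None:
            keys[cui] = None
        elif len(code) < 3:
            logger.info("ICD code %r shorter than 3 chars; using full string", code)
            keys[cui] = code
        else:
            keys[cui] = code[:3]
    group_keys = sorted({k for k in keys.values() if k is not None})
    group_index = {k: i + 1 for i, k in enumerate(group_keys)}
    token_to_group = {
        vocab.cui_to_token[cui]: (0 if k is None else group_index[k])
        for cui, k in keys.items()
    }
    return IcdRollupMap(token_to_group=token_to_group,
                        n_groups=len(group_keys) + 1)


def binarize(tokens: Sequence[int] | np.ndarray, dim: int,
             mask_special: bool = True) -> np.ndarray:
    """Presence/absence vector of length `dim` from integer tokens."""
    tokens = np.asarray(tokens, dtype=np.int64).ravel()
    if tokens.size and tokens.max() >= dim:
        raise ValueError(f"token {tokens.max()} out of range for dim {dim}")
    out = np.zeros(dim)
    out[tokens] = 1.0
    if mask_special:
        out[PAD_TOKEN] = 0.0
        if dim > OOV_TOKEN:
            out[OOV_TOKEN] = 0.0
    return out


def embed_lookup(tokens: Sequence[int] | np.ndarray,
                 embedding_matrix: np.ndarray) -> np.ndarray:
    """Row lookup into a frozen (n_tokens, E) embedding matrix."""
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.size and tokens.max() >= embedding_matrix.shape[0]:
        raise ValueError("token outside embedding matrix")
    return embedding_matrix[tokens]


# ---------------------------------------------------------------------------
# embedding clustering (the CC parameterization)
# ---------------------------------------------------------------------------


def _reduced_embeddings(vocab: CuiVocabulary, pca_dim: int) -> tuple[list[int], np.ndarray]:
    tokens = sorted(vocab.cui_to_token.values())
    X = np.stack([vocab.embedding[vocab.token_to_cui[t]] for t in tokens])
    n, E = X.shape
    k = min(pca_dim, E, n - 1) if n > 1 else 1
    if k < pca_dim:
        logger.info("PCA dim reduced from %d to %d (only %d CUIs)", pca_dim, k, n)
    if k < min(n, E):
        pca = PCA(n_components=k, svd_solver="full", random_state=0)
        Z = pca.fit_transform(X)
        # deterministic sign: largest-|loading| component of each PC positive
        for j in range(Z.shape[1]):
            col = pca.components_[j]
            if col[np.argmax(np.abs(col))] < 0:
                Z[:, j] *= -1
    else:
        Z = X - X.mean(axis=0)
    return tokens, Z


def _cosine_distance_matrix(Z: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances with a zero-norm guard.

    Centering can collapse coincident points onto the origin, where cosine
    distance is undefined: pairs of zero vectors get distance 0 (they are
    identical), mixed zero/non-zero pairs get the maximal distance 1.
    """
    norms = np.linalg.norm(Z, axis=1)
    zero = norms < 1e-12
    safe = np.where(zero, 1.0, norms)
    unit = Z / safe[:, None]
    D = 1.0 - unit @ unit.T
    if zero.any():
        D[np.ix_(zero, ~zero)] = 1.0
        D[np.ix_(~zero, zero)] = 1.0
        D[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2, 0.0, None)


def cluster_embeddings(
    vocab: CuiVocabulary,
    pca_dim: int = 100,
    distance_threshold: float = 0.5,
    linkage: str = "average",
) -> ClusterMap:
    """PCA-reduce embeddings, then agglomerative clustering on cosine distance.

    The tree is cut at ``distance_threshold``; cluster indices are relabeled
    deterministically by each cluster's smallest member token.
    """
    tokens, Z = _reduced_embeddings(vocab, pca_dim)
    n = len(tokens)
    if n == 1:
        return ClusterMap({tokens[0]: 0}, 1, pca_dim, distance_threshold, linkage)
    D = _cosine_distance_matrix(Z)
    if distance_threshold <= 0:
        labels = np.arange(n)
    else:
        model = AgglomerativeClustering(
            n_clusters=None,
            distance_threshold=distance_threshold,
            metric="precomputed",
            linkage=linkage,
        )
        labels = model.fit_predict(D)
    # relabel by smallest member token
    first_token: dict[int, int] = {}
    for tok, lab in zip(tokens, labels):
        first_token.setdefault(lab, tok)
    order = sorted(first_token, key=first_token.get)
    relabel = {lab: i for i, lab in enumerate(order)}
    mapping = {tok: relabel[lab] for tok, lab in zip(tokens, labels)}
    return ClusterMap(
        token_to_cluster=mapping,
        n_clusters=len(order),
        pca_dim=pca_dim,
        distance_threshold=distance_threshold,
        linkage=linkage,
    )


def threshold_for_cluster_count(
    vocab: CuiVocabulary,
    target_clusters: int,
    pca_dim: int = 100,
    linkage: str = "average",
) -> float:
    """Find a cut height yielding (as close as possible to) a target count.

    Uses the scipy linkage merge heights directly, so the returned threshold
    is exact for the fitted tree.
    """
    from scipy.cluster.hierarchy import linkage as scipy_linkage
    from scipy.spatial.distance import squareform

    tokens, Z = _reduced_embeddings(vocab, pca_dim)
    D = _cosine_distance_matrix(Z)
    heights = scipy_linkage(squareform(D, checks=False), method=linkage)[:, 2]
    n = len(tokens)
    target_clusters = max(1, min(target_clusters, n))
    # cutting just above merge i leaves n - 1 - i clusters
    i = n - 1 - target_clusters
    if i < 0:
        return 0.0
    hi = heights[i]
    return float(hi + 1e-12)


def cluster_binarize(tokens: Sequence[int] | np.ndarray, cmap: ClusterMap) -> np.ndarray:
    """Presence/absence over clusters for one CUI window."""
    out = np.zeros(cmap.n_clusters)
    for t in np.asarray(tokens, dtype=np.int64).ravel():
        if t == PAD_TOKEN or t == OOV_TOKEN:
            continue
        if int(t) not in cmap.token_to_cluster:
            raise ValueError(f"token {t} has no cluster")
        out[cmap.token_to_cluster[int(t)]] = 1.0
    return out


def rollup_matrix(windows: np.ndarray, rollup: IcdRollupMap) -> np.ndarray:
    """(T, W) token windows → (T, G) binary rollup-presence matrix."""
    T = windows.shape[0]
    out = np.zeros((T, rollup.n_groups))
    rolled = apply_rollup_tokens(windows, rollup)
    for ti in range(T):
        toks = rolled[ti]
        toks = toks[(toks != PAD_TOKEN) & (toks != OOV_TOKEN)]
        out[ti, toks - FIRST_CUI_TOKEN] = 1.0
    return out


def cluster_matrix(windows: np.ndarray, cmap: ClusterMap) -> np.ndarray:
    """(T, W) token windows → (T, C) binary cluster-presence matrix."""
    T = windows.shape[0]
    out = np.zeros((T, cmap.n_clusters))
    for ti in range(T):
        for t in windows[ti]:
            if t == PAD_TOKEN or t == OOV_TOKEN:
                continue
            out[ti, cmap.token_to_cluster[int(t)]] = 1.0
    return out
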