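"""Synthetic ward cohorts with known deterioration signal.

Real early-warning-score studies run on private hospital EHR extracts. This
module generates cohorts with the same statistical shape — irregular
timestamped vitals/labs with missingness, note events carrying bursts of
UMLS concept identifiers (CUIs), and a low-prevalence composite outcome
(death or direct ward-to-ICU transfer) — but with *known* ground truth:

* a latent severity random walk per encounter, expressed through a set of
  "signal" structured features;
* a designated minority of signal CUIs whose recent presence raises the
  short-term event hazard;
* a logistic per-timestep hazard whose intercept is calibrated by bisection
  so the realized observation-level label prevalence hits a target.

Everything is deterministic given (config, seed), so downstream model,
evaluation and attribution code can be tested against injected effects.

Timestamps are real-valued hours; ``admission_time`` is 0 for every
encounter and all other times are hours since admission.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cui_param import CuiVocabulary

__all__ = [
    "GeneratorConfig",
    "EncounterRecord",
    "SignalSpec",
    "CalibrationError",
    "generate_vocabulary",
    "generate_cohort",
    "null_config",
    "noise_cui_config",
    "strong_signal_config",
    "separable_config",
    "write_jsonl",
    "read_jsonl",
    "to_long_table",
    "from_long_table",
]

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("White", "Black", "Asian or Mideast Indian", "Other")
ETHNICITY_LEVELS = ("Hispanic or Latino", "Not Hispanic or Latino")
AGE_BAND_EDGES = (18, 34, 49, 65, 79)
AGE_BAND_LABELS = ("18-33", "34-48", "49-64", "65-78", ">79")

HORIZON_HOURS = 24.0  # lookahead of the deterioration label
RECENT_NOTE_HOURS = 24.0  # CUI presence window feeding the hazard


class CalibrationError(RuntimeError):
    """Prevalence calibration could not bracket or converge."""


def age_band(age_years: int) -> str:
    idx = int(np.searchsorted(AGE_BAND_EDGES, age_years, side="right")) - 1
    return AGE_BAND_LABELS[idx]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Effect sizes are log-odds contributions to the per-timestep hazard.
    ``structured_effect_log_odds[j]`` applies to the j-th *signal* structured
    feature (features 0..len-1), which observe the latent severity walk;
    ``signal_cui_log_odds`` applies when any signal CUI appeared in a note
    within the last 24 hours.
    """

    seed: int = 0
    n_encounters: int = 1000
    n_structured_features: int = 10
    observation_cadence_hours: float = 4.0
    mean_length_of_stay_hours: float = 72.0
    vocabulary_size: int = 300
    n_signal_cuis: int = 10
    signal_cui_log_odds: float = 2.0
    structured_effect_log_odds: tuple[float, ...] = (1.5, 1.5, 1.5)
    target_prevalence: float = 0.05
    missingness_rate: float = 0.3
    never_measured_rate: float = 0.03
    icd_code_fraction: float = 0.7
    embedding_dim: int = 32
    n_embedding_blobs: int = 8
    blob_separation: float = 6.0
    # severity walk and feature noise
    severity_step_sd: float = 0.25
    feature_noise_sd: float = 0.5
    note_interval_hours: float = 12.0
    cuis_per_note: int = 8
    signal_cui_prob: float = 0.08
    death_fraction: float = 0.15
    subgroup_effect_log_odds: float = 0.0  # optional male-sex hazard shift

    def __post_init__(self):
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie in (0, 1)")
        if not (0.0 <= self.icd_code_fraction <= 1.0):
            raise ValueError("icd_code_fraction must lie in [0, 1]")
        if not (0.0 <= self.missingness_rate < 1.0):
            raise ValueError("missingness_rate must lie in [0, 1)")
        if self.n_signal_cuis > self.vocabulary_size:
            raise ValueError("n_signal_cuis cannot exceed vocabulary_size")
        for name in ("n_encounters", "n_structured_features", "vocabulary_size",
                     "embedding_dim", "n_embedding_blobs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.structured_effect_log_odds) > self.n_structured_features:
            raise ValueError("more structured effects than features")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EncounterRecord:
    """One hospital ward encounter."""

    encounter_id: str
    admission_time: float
    sex: str
    race: str
    ethnicity: str
    age_years: int
    structured_obs: list[tuple[float, int, float]]  # (hours, feature_index, value)
    note_events: list[tuple[float, frozenset[str]]]  # (hours, CUI strings)
    outcome_time: float | None = None
    outcome_type: str = "none"  # {icu_transfer, death, none}

    @property
    def age_band(self) -> str:
        return age_band(self.age_years)


@dataclass(frozen=True)
class SignalSpec:
    """Ground truth injected into a generated cohort."""

    signal_cui_ids: frozenset[str]
    signal_feature_indices: frozenset[int]
    effect_sizes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

_ICD_CHAPTERS = "ABCDEFGHIJKLMNQRSTZ"


def _cui_id(i: int) -> str:
    return f"C{i + 1:07d}"


def generate_vocabulary(config: GeneratorConfig) -> CuiVocabulary:
    """Synthesize per-CUI metadata emulating a clinical NLP extraction table.

    A fraction ``icd_code_fraction`` of CUIs receive ICD codes; codes are
    drawn from a small pool of 3-character prefixes so distinct CUIs share
    rollup groups, and sub-codes (".0".. ) make most full codes unique.
    Embeddings come from a mixture of ``n_embedding_blobs`` Gaussian
    components with centers ``blob_separation`` apart, and each CUI's vector
    is a deterministic function of (seed, CUI index).
    """
    V = config.vocabulary_size
    rng = np.random.default_rng([config.seed, 7919])
    centers_rng = np.random.default_rng([config.seed, 104729])
    centers = centers_rng.normal(size=(config.n_embedding_blobs, config.embedding_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= config.blob_separation

    n_prefixes = max(3, V // 12)
    prefixes = [
        f"{_ICD_CHAPTERS[i % len(_ICD_CHAPTERS)]}{i // len(_ICD_CHAPTERS):02d}"
        for i in range(n_prefixes)
    ]
    has_code = rng.random(V) < config.icd_code_fraction
    prefix_choice = rng.integers(0, n_prefixes, size=V)

    cuis, texts, icds, embeddings = [], [], {}, {}
    for i in range(V):
        cui = _cui_id(i)
        cuis.append(cui)
        texts.append(f"synthetic concept {i:04d}")
        if has_code[i]:
            icds[cui] = f"{prefixes[prefix_choice[i]]}.{i % 10}"
        cui_rng = np.random.default_rng([config.seed, 15485863, i])
        blob = i % config.n_embedding_blobs
        embeddings[cui] = centers[blob] + cui_rng.normal(
            scale=1.0, size=config.embedding_dim
        )

    # Zipf-ish document frequencies purely for token ordering; the model-facing
    # vocabulary rebuilds df from actual cohorts via cui_param.build_vocabulary.
    df = {c: max(1, int(round(V / (i + 1) ** 0.7))) for i, c in enumerate(cuis)}
    return CuiVocabulary.from_metadata(
        cuis=cuis,
        preferred_text=dict(zip(cuis, texts)),
        icd_code=icds,
        embedding=embeddings,
        admission_df=df,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _draw_static(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "sex": rng.choice(SEX_LEVELS, size=n, p=[0.55, 0.45]),
        "race": rng.choice(RACE_LEVELS, size=n, p=[0.55, 0.3, 0.05, 0.1]),
        "ethnicity": rng.choice(ETHNICITY_LEVELS, size=n, p=[0.06, 0.94]),
        "age": rng.integers(18, 96, size=n),
    }


class _LatentEncounter:
    """Pre-drawn randomness for one encounter, before calibration."""

    __slots__ = (
        "times", "severity", "feature_values", "observed_mask", "note_times",
        "note_cuis", "note_has_signal", "event_u", "event_offset", "logit_wo_intercept",
    )


def _simulate_latents(config: GeneratorConfig, vocab_cuis: Sequence[str],
                      signal_cuis: frozenset[str], rng: np.random.Generator,
                      sexes: np.ndarray) -> list[_LatentEncounter]:
    n_sig_feat = len(config.structured_effect_log_odds)
    effects = np.asarray(config.structured_effect_log_odds)
    nonsignal = [c for c in vocab_cuis if c not in signal_cuis]
    signal_list = sorted(signal_cuis)
    # Zipf weights over non-signal CUIs: a few very common concepts, long tail
    w = 1.0 / np.arange(1, len(nonsignal) + 1) ** 1.1
    w /= w.sum()

    latents = []
    for e in range(config.n_encounters):
        lat = _LatentEncounter()
        # shifted exponential: 8h minimum, memoryless beyond (no point
        # masses from hard clipping, which would make label rates
        # time-dependent even under a null hazard)
        los = 8.0 + rng.exponential(max(config.mean_length_of_stay_hours - 8.0, 1.0))
        cad = config.observation_cadence_hours
        base = np.arange(1.0, los, cad)
        jitter = rng.uniform(-0.2 * cad, 0.2 * cad, size=base.size)
        times = np.sort(base + jitter)
        times = times[times > 0]
        if times.size == 0:
            times = np.array([1.0])
        T = times.size
        steps = rng.normal(scale=config.severity_step_sd, size=T)
        steps[0] = rng.normal()
        severity = np.cumsum(steps)

        feat = np.empty((T, config.n_structured_features))
        feat[:, :n_sig_feat] = severity[:, None] + rng.normal(
            scale=config.feature_noise_sd, size=(T, n_sig_feat)
        )
        feat[:, n_sig_feat:] = rng.normal(
            size=(T, config.n_structured_features - n_sig_feat)
        )
        observed = rng.random(feat.shape) >= config.missingness_rate
        never = rng.random(config.n_structured_features) < config.never_measured_rate
        observed[:, never] = False

        # every encounter opens with admission documentation, then notes
        # accrue at roughly the configured interval
        n_notes = rng.poisson(los / config.note_interval_hours)
        note_times = np.sort(
            np.r_[0.25, rng.uniform(0.0, los, size=n_notes)])
        n_notes += 1
        note_cuis, has_sig = [], []
        for _ in range(n_notes):
            k = max(1, rng.poisson(config.cuis_per_note))
            chosen = set(rng.choice(len(nonsignal), size=min(k, len(nonsignal)),
                                    replace=False))
            cset = {nonsignal[i] for i in chosen}
            sig_draw = rng.random(len(signal_list)) < config.signal_cui_prob
            cset.update(c for c, s in zip(signal_list, sig_draw) if s)
            note_cuis.append(frozenset(cset))
            has_sig.append(bool(sig_draw.any()))

        # hazard covariate part (intercept added during calibration): signal
        # CUIs mark persistent high-risk conditions — each distinct signal
        # CUI contributes its own log-odds from its first mention onward,
        # matching how notes carry chronic risk factors forward
        sig_noted = np.zeros(T)
        for t_idx, t in enumerate(times):
            noted: set[str] = set()
            for nt, cset in zip(note_times, note_cuis):
                if nt <= t:
                    noted.update(c for c in cset if c in signal_cuis)
            sig_noted[t_idx] = len(noted)
        logit = feat[:, :n_sig_feat] @ effects + config.signal_cui_log_odds * sig_noted
        if config.subgroup_effect_log_odds and sexes[e] == "male":
            logit = logit + config.subgroup_effect_log_odds

        lat.times = times
        lat.severity = severity
        lat.feature_values = feat
        lat.observed_mask = observed
        lat.note_times = note_times
        lat.note_cuis = note_cuis
        lat.note_has_signal = np.asarray(has_sig)
        lat.event_u = rng.random(T)
        lat.event_offset = rng.uniform(1.0, HORIZON_HOURS - 1.0)
        lat.logit_wo_intercept = logit
        latents.append(lat)
    return latents


def _event_time(lat: _LatentEncounter, intercept: float) -> float | None:
    p = 1.0 / (1.0 + np.exp(-(lat.logit_wo_intercept + intercept)))
    hit = np.nonzero(lat.event_u < p)[0]
    if hit.size == 0:
        return None
    return float(lat.times[hit[0]] + lat.event_offset)


def _realized_prevalence(latents: list[_LatentEncounter], intercept: float) -> float:
    pos = tot = 0
    for lat in latents:
        ev = _event_time(lat, intercept)
        if ev is None:
            tot += lat.times.size
        else:
            kept = lat.times[lat.times < ev]
            tot += kept.size
            pos += int(np.sum((ev - kept > 0) & (ev - kept <= HORIZON_HOURS)))
    return pos / max(tot, 1)


def _calibrate_intercept(latents, target: float, tol: float = 0.002,
                         max_iter: int = 60) -> float:
    lo, hi = -80.0, 5.0
    p_lo, p_hi = _realized_prevalence(latents, lo), _realized_prevalence(latents, hi)
    if not (p_lo <= target <= p_hi):
        raise CalibrationError(
            f"cannot reach prevalence {target:.3f}: achievable range "
            f"[{p_lo:.4f}, {p_hi:.4f}] — effect sizes too large or cohort too small"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = _realized_prevalence(latents, mid)
        if abs(p - target) <= tol:
            return mid
        if p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    config: GeneratorConfig, vocab: CuiVocabulary
) -> tuple[list[EncounterRecord], SignalSpec]:
    """Draw a cohort of encounters with calibrated outcome prevalence.

    The per-timestep hazard is logistic in the signal structured features
    (noisy views of a latent severity walk) and, additively, in the number
    of distinct signal CUIs noted so far (persistent high-risk conditions,
    each contributing ``signal_cui_log_odds`` from first mention onward);
    the intercept is found by bisection on pre-drawn uniforms so
    the realized 24-hour-label prevalence approximates
    ``config.target_prevalence``. Events truncate the encounter: no
    observation or note carries a timestamp at or after ``outcome_time``.
    """
    rng = np.random.default_rng([config.seed, 2_147_483_029])
    all_cuis = vocab.cuis
    sig_rng = np.random.default_rng([config.seed, 9973])
    sig_idx = sig_rng.choice(len(all_cuis), size=config.n_signal_cuis, replace=False)
    signal_cuis = frozenset(all_cuis[i] for i in sorted(sig_idx))

    static = _draw_static(rng, config.n_encounters)
    latents = _simulate_latents(config, all_cuis, signal_cuis, rng, static["sex"])
    intercept = _calibrate_intercept(latents, config.target_prevalence)

    encounters = []
    type_rng = np.random.default_rng([config.seed, 33331])
    for e, lat in enumerate(latents):
        ev = _event_time(lat, intercept)
        if ev is None:
            times, feat, obs = lat.times, lat.feature_values, lat.observed_mask
            keep_notes = np.ones(len(lat.note_times), dtype=bool)
            otype = "none"
        else:
            keep = lat.times < ev
            times, feat, obs = lat.times[keep], lat.feature_values[keep], lat.observed_mask[keep]
            keep_notes = lat.note_times < ev
            otype = "death" if type_rng.random() < config.death_fraction else "icu_transfer"
        if times.size == 0:
            continue
        structured = [
            (float(t), int(j), float(feat[ti, j]))
            for ti, t in enumerate(times)
            for j in range(config.n_structured_features)
            if obs[ti, j]
        ]
        notes = [
            (float(nt), cset)
            for nt, cset, k in zip(lat.note_times, lat.note_cuis, keep_notes)
            if k
        ]
        encounters.append(
            EncounterRecord(
                encounter_id=f"E{e:06d}",
                admission_time=0.0,
                sex=str(static["sex"][e]),
                race=str(static["race"][e]),
                ethnicity=str(static["ethnicity"][e]),
                age_years=int(static["age"][e]),
                structured_obs=structured,
                note_events=notes,
                outcome_time=ev,
                outcome_type=otype,
            )
        )

    spec = SignalSpec(
        signal_cui_ids=signal_cuis,
        signal_feature_indices=frozenset(range(len(config.structured_effect_log_odds))),
        effect_sizes={
            **{c: config.signal_cui_log_odds for c in sorted(signal_cuis)},
            **{f"feature_{j}": w for j, w in enumerate(config.structured_effect_log_odds)},
        },
    )
    return encounters, spec


# ---------------------------------------------------------------------------
# preset study conditions
# ---------------------------------------------------------------------------


def strong_signal_config(seed: int = 0, n_encounters: int = 2000) -> GeneratorConfig:
    """Near-separable cohort with strongly identifiable injected effects.

    Severity loadings are large with low noise. Signal CUIs are rare but
    strong (presence 0.08 per note, 4.0 log-odds each from first mention):
    minority high-risk conditions, the regime the inverse-document-frequency
    weighting of the importance score is designed for.
    """
    return GeneratorConfig(
        seed=seed,
        n_encounters=n_encounters,
        mean_length_of_stay_hours=60.0,
        structured_effect_log_odds=(4.0, 4.0, 4.0),
        signal_cui_log_odds=4.0,
        signal_cui_prob=0.08,
        feature_noise_sd=0.15,
        severity_step_sd=0.15,
        missingness_rate=0.15,
        target_prevalence=0.05,
    )


def separable_config(seed: int = 0, n_encounters: int = 2000) -> GeneratorConfig:
    """Near-linearly-separable cohort for discrimination sanity checks.

    The outcome is dominated by the structured channel (large severity
    loadings, low feature and walk noise), which the models observe almost
    directly, with a modest persistent concept effect on top; a well-trained
    model should approach the generating process's discrimination.
    """
    return GeneratorConfig(
        seed=seed,
        n_encounters=n_encounters,
        mean_length_of_stay_hours=60.0,
        structured_effect_log_odds=(4.0, 4.0, 4.0),
        signal_cui_log_odds=1.0,
        feature_noise_sd=0.1,
        severity_step_sd=0.1,
        missingness_rate=0.15,
        target_prevalence=0.05,
    )


def noise_cui_config(seed: int = 0, n_encounters: int = 1000) -> GeneratorConfig:
    """Structured signal present, CUIs pure noise (zero CUI effect)."""
    return GeneratorConfig(
        seed=seed,
        n_encounters=n_encounters,
        mean_length_of_stay_hours=60.0,
        structured_effect_log_odds=(2.5, 2.5, 2.5),
        signal_cui_log_odds=0.0,
        feature_noise_sd=0.3,
        target_prevalence=0.05,
    )


def null_config(seed: int = 0, n_encounters: int = 600) -> GeneratorConfig:
    """No covariate signal: labels independent of features and concepts.

    Stays are long (mean 120h) so the admission-boundary depression of the
    24-hour label window — observations in the first day cannot be labeled
    by triggers that would have preceded admission — covers a small share
    of observations and residual time-discrimination stays near chance.
    """
    return GeneratorConfig(
        seed=seed,
        n_encounters=n_encounters,
        mean_length_of_stay_hours=120.0,
        structured_effect_log_odds=(0.0, 0.0, 0.0),
        signal_cui_log_odds=0.0,
        target_prevalence=0.05,
    )


# ---------------------------------------------------------------------------
# serialization: JSON-lines and long-format table
# ---------------------------------------------------------------------------


def _enc_to_dict(enc: EncounterRecord) -> dict:
    return {
        "encounter_id": enc.encounter_id,
        "admission_time": enc.admission_time,
        "sex": enc.sex,
        "race": enc.race,
        "ethnicity": enc.ethnicity,
        "age_years": enc.age_years,
        "structured_obs": [[t, j, v] for t, j, v in enc.structured_obs],
        "note_events": [[t, sorted(c)] for t, c in enc.note_events],
        "outcome_time": enc.outcome_time,
        "outcome_type": enc.outcome_type,
    }


def _enc_from_dict(d: dict) -> EncounterRecord:
    return EncounterRecord(
        encounter_id=d["encounter_id"],
        admission_time=float(d["admission_time"]),
        sex=d["sex"],
        race=d["race"],
        ethnicity=d["ethnicity"],
        age_years=int(d["age_years"]),
        structured_obs=[(float(t), int(j), float(v)) for t, j, v in d["structured_obs"]],
        note_events=[(float(t), frozenset(c)) for t, c in d["note_events"]],
        outcome_time=None if d["outcome_time"] is None else float(d["outcome_time"]),
        outcome_type=d["outcome_type"],
    )


def write_jsonl(encounters: Iterable[EncounterRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for enc in encounters:
            fh.write(json.dumps(_enc_to_dict(enc)) + "\n")


def read_jsonl(path: str | Path) -> list[EncounterRecord]:
    with open(path) as fh:
        return [_enc_from_dict(json.loads(line)) for line in fh if line.strip()]


def to_long_table(encounters: Iterable[EncounterRecord]) -> pd.DataFrame:
    """Long format: one row per observation / note CUI / outcome / static."""
    rows = []
    for enc in encounters:
        for key in ("sex", "race", "ethnicity"):
            rows.append((enc.encounter_id, enc.admission_time, "static", key,
                         getattr(enc, key)))
        rows.append((enc.encounter_id, enc.admission_time, "static", "age_years",
                     str(enc.age_years)))
        for t, j, v in enc.structured_obs:
            rows.append((enc.encounter_id, t, "structured", str(j), repr(v)))
        for t, cset in enc.note_events:
            for c in sorted(cset):
                rows.append((enc.encounter_id, t, "note", c, ""))
        if enc.outcome_time is not None:
            rows.append((enc.encounter_id, enc.outcome_time, "outcome",
                         enc.outcome_type, ""))
    return pd.DataFrame(rows, columns=["encounter_id", "timestamp", "stream",
                                       "key", "value"])


def from_long_table(table: pd.DataFrame) -> list[EncounterRecord]:
    encounters = []
    for eid, grp in table.groupby("encounter_id", sort=True):
        static = grp[grp.stream == "static"].set_index("key")["value"]
        structured = [
            (float(r.timestamp), int(r.key), float(r.value))
            for r in grp[grp.stream == "structured"].itertuples()
        ]
        notes: dict[float, set] = {}
        for r in grp[grp.stream == "note"].itertuples():
            notes.setdefault(float(r.timestamp), set()).add(r.key)
        out = grp[grp.stream == "outcome"]
        otime, otype = None, "none"
        if len(out):
            otime = float(out.iloc[0].timestamp)
            otype = out.iloc[0].key
        adm = float(grp.timestamp[grp.stream == "static"].iloc[0])
        encounters.append(
            EncounterRecord(
                encounter_id=str(eid),
                admission_time=adm,
                sex=static["sex"],
                race=static["race"],
                ethnicity=static["ethnicity"],
                age_years=int(static["age_years"]),
                structured_obs=sorted(structured),
                note_events=sorted((t, frozenset(c)) for t, c in notes.items()),
                outcome_time=otime,
                outcome_type=otype,
            )
        )
    return encounters
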