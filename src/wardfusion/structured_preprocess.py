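"""Imputation, encoding and labeling of irregular structured observations.

Ward vitals and labs arrive irregularly and with heavy missingness. The
models consume a per-timestep matrix built as follows:

1. **Carry-forward imputation** — each missing value takes the most recent
   prior observed value for that feature; lab classes with short clinical
   shelf life (lactate, blood gases) carry at most 24 hours. Remaining gaps
   take the feature's development-cohort median, which validation cohorts
   reuse unchanged. Imputation never looks at future values.
2. **Piecewise-linear encoding (PLE)** — each scalar becomes a K-vector of
   saturating per-bin activations over ordered boundaries (quantile bins fit
   on the development cohort), a representation known to help deep models on
   numeric tabular data.
3. **Hours since admission** — an explicit temporal input per timestep.
4. **24-hour lookahead label** — label(t) = 1 iff the deterioration event
   (death or direct ward-to-ICU transfer) occurs in (t, t + 24h].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthetic_cohort import EncounterRecord

logger = logging.getLogger(__name__)

HORIZON_HOURS = 24.0
CARRY_LIMIT_HOURS = 24.0

STANDARD = "standard_carry_forward"
LIMITED_24H = "limited_24h"

__all__ = [
    "ImputationPolicy",
    "PleSpec",
    "ObservationMatrix",
    "compute_dev_medians",
    "carry_forward_impute",
    "piecewise_linear_encode",
    "fit_ple_spec",
    "assemble_observation_matrix",
    "assemble_cohort",
]


@dataclass
class ImputationPolicy:
    """Per-feature variable class plus development-cohort medians."""

    variable_class: dict[int, str]
    dev_medians: dict[int, float]

    def __post_init__(self):
        for j, cls in self.variable_class.items():
            if cls not in (STANDARD, LIMITED_24H):
                raise ValueError(f"unknown variable class {cls!r} for feature {j}")
        missing = set(self.variable_class) - set(self.dev_medians)
        if missing:
            raise ValueError(f"features without a dev median: {sorted(missing)}")

    @classmethod
    def from_classes(cls, n_features: int, medians: dict[int, float],
                     limited_features: Iterable[int] = ()) -> "ImputationPolicy":
        limited = set(limited_features)
        return cls(
            variable_class={j: (LIMITED_24H if j in limited else STANDARD)
                            for j in range(n_features)},
            dev_medians=dict(medians),
        )


@dataclass
class PleSpec:
    """Per-feature strictly increasing bin boundaries b_0 < ... < b_K."""

    boundaries: dict[int, np.ndarray]

    def __post_init__(self):
        for j, b in self.boundaries.items():
            b = np.asarray(b, dtype=float)
            if b.size < 2 or np.any(np.diff(b) <= 0):
                raise ValueError(f"feature {j}: boundaries must be strictly increasing "
                                 "with at least one bin")
            self.boundaries[j] = b

    def n_bins(self, feature: int) -> int:
        return len(self.boundaries[feature]) - 1

    @property
    def encoded_dim(self) -> int:
        return sum(len(b) - 1 for b in self.boundaries.values())


@dataclass
class ObservationMatrix:
    """Model-ready per-timestep view of one encounter."""

    encounter_id: str
    timesteps: np.ndarray                 # strictly increasing hours
    structured_encoded: np.ndarray        # (T, encoded_dim)
    hours_since_admission: np.ndarray     # (T,)
    label: np.ndarray                     # (T,) in {0, 1}
    sex: str = ""
    race: str = ""
    ethnicity: str = ""
    age_band: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.timesteps) <= 0):
            raise ValueError("timesteps must be strictly increasing")
        if np.isnan(self.structured_encoded).any():
            raise ValueError("missing values survived preprocessing")


def compute_dev_medians(
    dev_cohort: Iterable[EncounterRecord], n_features: int
) -> dict[int, float]:
    """Median of all observed (pre-imputation) values, pooled across patients.

    Even counts use the midpoint convention. A feature never observed in the
    development cohort is an error, named explicitly.
    """
    pools: dict[int, list[float]] = {j: [] for j in range(n_features)}
    for enc in dev_cohort:
        for _, j, v in enc.structured_obs:
            pools[j].append(v)
    medians = {}
    for j, vals in pools.items():
        if not vals:
            raise ValueError(f"feature {j} never observed in development cohort")
        medians[j] = float(np.median(vals))
    return medians


def carry_forward_impute(
    series: Sequence[tuple[float, float | None]],
    variable_class: str,
    dev_median: float,
) -> list[float]:
    """Fill a time-ordered (timestamp, value-or-None) series.

    Standard class: any missing entry takes the most recent prior observed
    value, else the development median. Limited class: the carried value is
    used only if its source observation is ≤ 24h older than the target
    timestep; otherwise the median. Future values are never consulted.
    """
    times = [t for t, _ in series]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("series timestamps must be non-decreasing")
    out = []
    last_val: float | None = None
    last_time: float | None = None
    for t, v in series:
        if v is not None:
            out.append(float(v))
            last_val, last_time = float(v), t
        elif last_val is None:
            out.append(float(dev_median))
        elif variable_class == LIMITED_24H and t - last_time > CARRY_LIMIT_HOURS:
            out.append(float(dev_median))
        else:
            out.append(last_val)
    return out


def piecewise_linear_encode(x: float, boundaries: np.ndarray) -> np.ndarray:
    """PLE of a scalar: component k = clip((x − b_{k−1})/(b_k − b_{k−1}), 0, 1).

    The result is 1 in every bin fully below x, fractional in the bin
    containing x, and 0 above; clipping handles out-of-range inputs.
    """
    b = np.asarray(boundaries, dtype=float)
    return np.clip((x - b[:-1]) / np.diff(b), 0.0, 1.0)


def fit_ple_spec(
    dev_cohort: Iterable[EncounterRecord], n_features: int, n_bins: int = 16
) -> PleSpec:
    """Quantile bin boundaries per feature from development-cohort values.

    Duplicate quantiles are collapsed; features with fewer distinct values
    than bins get correspondingly fewer bins (minimum one, widened by a small
    epsilon for constant features).
    """
    pools: dict[int, list[float]] = {j: [] for j in range(n_features)}
    for enc in dev_cohort:
        for _, j, v in enc.structured_obs:
            pools[j].append(v)
    boundaries = {}
    for j, vals in pools.items():
        if not vals:
            raise ValueError(f"feature {j} never observed in development cohort")
        qs = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
        b = np.unique(qs)
        if b.size < 2:
            b = np.array([b[0] - 0.5, b[0] + 0.5])
        boundaries[j] = b
    return PleSpec(boundaries=boundaries)


def _impute_grid(
    enc: EncounterRecord, n_features: int, policy: ImputationPolicy
) -> tuple[np.ndarray, np.ndarray]:
    """Union-of-timestamps grid with per-feature causal imputation."""
    times = sorted({t for t, _, _ in enc.structured_obs})
    grid = np.asarray(times)
    observed: dict[int, dict[float, float]] = {j: {} for j in range(n_features)}
    for t, j, v in enc.structured_obs:
        observed[j][t] = v  # same-timestamp duplicates: last one wins
    values = np.empty((len(grid), n_features))
    for j in range(n_features):
        series = [(t, observed[j].get(t)) for t in grid]
        values[:, j] = carry_forward_impute(
            series, policy.variable_class[j], policy.dev_medians[j]
        )
    return grid, values


def assemble_observation_matrix(
    enc: EncounterRecord,
    policy: ImputationPolicy,
    ple: PleSpec,
    horizon_hours: float = HORIZON_HOURS,
) -> ObservationMatrix | None:
    """Impute, PLE-encode and label one encounter.

    Timesteps are the union of the encounter's observation timestamps;
    observations at or after ``outcome_time`` are excluded (the event
    truncates the encounter). Encounters with zero usable timesteps are
    skipped with a warning. The label is 1 iff the outcome falls in
    (t, t + horizon].
    """
    n_features = len(policy.variable_class)
    grid, values = _impute_grid(enc, n_features, policy)
    if enc.outcome_time is not None:
        keep = grid < enc.outcome_time
        grid, values = grid[keep], values[keep]
    if grid.size == 0:
        logger.warning("encounter %s has no usable timesteps; skipped",
                       enc.encounter_id)
        return None
    encoded = np.concatenate(
        [
            np.stack([piecewise_linear_encode(v, ple.boundaries[j])
                      for v in values[:, j]])
            for j in range(n_features)
        ],
        axis=1,
    )
    hours = grid - enc.admission_time
    if enc.outcome_time is None:
        label = np.zeros(grid.size, dtype=np.int64)
    else:
        delta = enc.outcome_time - grid
        label = ((delta > 0) & (delta <= horizon_hours)).astype(np.int64)
    return ObservationMatrix(
        encounter_id=enc.encounter_id,
        timesteps=grid,
        structured_encoded=encoded,
        hours_since_admission=hours,
        label=label,
        sex=enc.sex,
        race=enc.race,
        ethnicity=enc.ethnicity,
        age_band=enc.age_band,
    )


def assemble_cohort(
    cohort: Iterable[EncounterRecord],
    policy: ImputationPolicy,
    ple: PleSpec,
    horizon_hours: float = HORIZON_HOURS,
) -> list[ObservationMatrix]:
    out = []
    for enc in cohort:
        om = assemble_observation_matrix(enc, policy, ple, horizon_hours)
        if om is not None:
            out.append(om)
    return out


def save_preprocessing(path: str | Path, policy: ImputationPolicy, ple: PleSpec) -> None:
    """JSON sidecar so validation cohorts reuse dev-fit parameters bit-exactly."""
    obj = {
        "variable_class": {str(k): v for k, v in policy.variable_class.items()},
        "dev_medians": {str(k): v for k, v in policy.dev_medians.items()},
        "ple_boundaries": {str(k): v.tolist() for k, v in ple.boundaries.items()},
    }
    Path(path).write_text(json.dumps(obj))


def load_preprocessing(path: str | Path) -> tuple[ImputationPolicy, PleSpec]:
    obj = json.loads(Path(path).read_text())
    policy = ImputationPolicy(
        variable_class={int(k): v for k, v in obj["variable_class"].items()},
        dev_medians={int(k): float(v) for k, v in obj["dev_medians"].items()},
    )
    ple = PleSpec(boundaries={int(k): np.asarray(v)
                              for k, v in obj["ple_boundaries"].items()})
    return policy, ple
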