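"""Discrimination, calibration, operating-point and subgroup evaluation.

With ~5% outcome prevalence the area under the precision-recall curve
(AUPRC) is the primary metric — AUROC can look flattering when negatives
dominate — with AUROC secondary. Confidence intervals come from a percentile
bootstrap (1000 iterations, each resample sized at 20% of the population,
drawn with replacement at observation level). Alert-burden operating points
flag the top 1/5/10/15% of scores and report sensitivity, specificity, PPV
and NPV. The Brier score tracks calibration, and every metric can be
stratified over sex, race, ethnicity and age band.

Conventions (documented because they matter to the third decimal): AUROC is
the Mann-Whitney statistic P(score_pos > score_neg) + 0.5 P(tie); AUPRC is
average precision (no trapezoidal interpolation, which is optimistic on PR
curves); thresholds flag all observations tied at the cut score, with the
realized flag count reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

FLAG_FRACTIONS = (0.01, 0.05, 0.10, 0.15)
SUBGROUP_ATTRIBUTES = ("sex", "race", "ethnicity", "age_band")

__all__ = [
    "OperatingPoint",
    "BootstrapCi",
    "auroc",
    "auprc",
    "auroc_arrays",
    "auprc_arrays",
    "brier",
    "bootstrap_ci",
    "operating_points",
    "subgroup_eval",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class OperatingPoint:
    flag_fraction: float
    threshold: float
    n_flagged: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float


@dataclass(frozen=True)
class BootstrapCi:
    point: float
    lower: float
    upper: float
    n_iterations: int
    resample_fraction: float
    seed: int


def _check_preds(preds: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    y = preds["label"].to_numpy(dtype=float)
    s = preds["score"].to_numpy(dtype=float)
    return y, s


def auroc_arrays(y: np.ndarray, s: np.ndarray) -> float:
    """Mann-Whitney AUROC via midranks (ties count half)."""
    y = np.asarray(y, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc_arrays(y: np.ndarray, s: np.ndarray) -> float:
    """Average precision: sum over positives of precision at each recall step.

    Ties in score are handled by treating each tied block as one PR step
    (precision evaluated after including the whole block), matching the
    standard average-precision convention.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("AUPRC requires both classes")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    n = np.arange(1, y.size + 1)
    precision = tp / n
    # collapse tied blocks: only the last index of each tied score counts
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    ap = 0.0
    prev_tp = 0.0
    for i in np.nonzero(last_of_block)[0]:
        ap += (tp[i] - prev_tp) * precision[i]
        prev_tp = tp[i]
    return float(ap / n_pos)


def auroc(preds: pd.DataFrame) -> float:
    y, s = _check_preds(preds)
    return auroc_arrays(y, s)


def auprc(preds: pd.DataFrame) -> float:
    y, s = _check_preds(preds)
    return auprc_arrays(y, s)


def brier(preds: pd.DataFrame) -> float:
    """Mean squared difference between predicted risk and outcome."""
    y, s = _check_preds(preds)
    return float(np.mean((s - y) ** 2))


def bootstrap_ci(
    preds: pd.DataFrame,
    metric,
    n_iterations: int = 1000,
    resample_fraction: float = 0.20,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapCi:
    """Percentile 95% CI over resamples of size ceil(fraction * n).

    Resampling is with replacement at observation level; single-class
    resamples (on which discrimination metrics are undefined) are redrawn
    and the redraw count logged.
    """
    y, s = _check_preds(preds)
    n = y.size
    m = int(np.ceil(resample_fraction * n))
    rng = np.random.default_rng(seed)
    point = metric(preds)
    # array fast path for the built-in metrics (the bootstrap dominates runtime)
    array_fn = {id(auroc): auroc_arrays, id(auprc): auprc_arrays,
                id(brier): lambda yy, ss: float(np.mean((ss - yy) ** 2))
                }.get(id(metric))
    vals = np.empty(n_iterations)
    redraws = 0
    for i in range(n_iterations):
        while True:
            idx = rng.integers(0, n, size=m)
            yi = y[idx]
            if 0 < yi.sum() < m:
                break
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("could not draw a two-class bootstrap resample")
        if array_fn is not None:
            vals[i] = array_fn(yi, s[idx])
        else:
            vals[i] = metric(pd.DataFrame({"label": yi, "score": s[idx]}))
    if redraws:
        logger.info("bootstrap: redrew %d single-class resamples", redraws)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapCi(point=float(point), lower=float(lo), upper=float(hi),
                       n_iterations=n_iterations,
                       resample_fraction=resample_fraction, seed=seed)


def operating_points(
    preds: pd.DataFrame, flag_fractions=FLAG_FRACTIONS
) -> list[OperatingPoint]:
    """Sensitivity/specificity/PPV/NPV at fixed alert-fraction cut points.

    The threshold is the score at rank ceil(f*n) of the descending sort; all
    observations tied at the threshold are flagged, and the realized flag
    count is reported.
    """
    y, s = _check_preds(preds)
    n = y.size
    P = y.sum()
    N = n - P
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    out = []
    for f in flag_fractions:
        k = int(np.ceil(f * n))
        k = min(max(k, 0), n)
        if k == 0:
            out.append(OperatingPoint(f, float("inf"), 0, 0.0, 1.0, None,
                                      float((N) / n) if n else 0.0))
            continue
        thr = s_sorted[k - 1]
        flagged = s >= thr
        nf = int(flagged.sum())
        tp = float(y[flagged].sum())
        tn = float((1 - y)[~flagged].sum())
        out.append(
            OperatingPoint(
                flag_fraction=f,
                threshold=float(thr),
                n_flagged=nf,
                sensitivity=tp / P if P else 0.0,
                specificity=tn / N if N else 0.0,
                ppv=(tp / nf) if nf else None,
                npv=tn / (n - nf) if n > nf else 0.0,
            )
        )
    return out


def subgroup_eval(
    preds: pd.DataFrame,
    attribute: str,
    n_iterations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """AUROC/AUPRC with bootstrap CIs per level of a subgroup attribute.

    Groups missing a class are reported absent with a logged reason.
    """
    rows = []
    for level, grp in preds.groupby(attribute, sort=True):
        y = grp["label"].to_numpy()
        if y.min() == y.max():
            logger.info("subgroup %s=%s skipped: single-class labels",
                        attribute, level)
            continue
        ci_roc = bootstrap_ci(grp, auroc, n_iterations=n_iterations, seed=seed)
        ci_prc = bootstrap_ci(grp, auprc, n_iterations=n_iterations, seed=seed)
        rows.append(
            {attribute: level, "n": len(grp), "prevalence": float(y.mean()),
             "auroc": ci_roc.point, "auroc_lo": ci_roc.lower,
             "auroc_hi": ci_roc.upper,
             "auprc": ci_prc.point, "auprc_lo": ci_prc.lower,
             "auprc_hi": ci_prc.upper}
        )
    return pd.DataFrame(rows)


def evaluate_predictions(
    preds: pd.DataFrame,
    flag_fractions=FLAG_FRACTIONS,
    n_iterations: int = 1000,
    seed: int = 0,
    subgroups: tuple[str, ...] = SUBGROUP_ATTRIBUTES,
) -> dict:
    """The full report for one model's prediction set."""
    ci_prc = bootstrap_ci(preds, auprc, n_iterations=n_iterations, seed=seed)
    ci_roc = bootstrap_ci(preds, auroc, n_iterations=n_iterations, seed=seed)
    report = {
        "n_observations": int(len(preds)),
        "prevalence": float(preds["label"].mean()),
        "auprc": ci_prc.point,
        "auprc_ci": [ci_prc.lower, ci_prc.upper],
        "auroc": ci_roc.point,
        "auroc_ci": [ci_roc.lower, ci_roc.upper],
        "brier": brier(preds),
        "operating_points": [vars(op) for op in operating_points(preds, flag_fractions)],
    }
    report["subgroups"] = {
        attr: subgroup_eval(preds, attr, n_iterations=n_iterations,
                            seed=seed).to_dict(orient="records")
        for attr in subgroups
        if attr in preds.columns
    }
    return report
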