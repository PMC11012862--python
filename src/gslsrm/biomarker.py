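"""Urinary biomarker evaluation: creatinine correction, group comparison, ROC.

Orientation convention throughout: a higher score indicates the case
(disease) group, matching an elevated urinary marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSample",
    "ROCResult",
    "creatinine_correct",
    "compare_groups",
    "roc",
    "trapezoidal_auc",
    "youden_cutoff",
    "auc_confidence_interval",
    "read_cohort",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class CohortSample:
    """One urine sample: group label, raw analyte intensity, urinary creatinine."""

    sample_id: str
    group: str
    intensity: float
    creatinine: float
    creatinine_unit: str = "mg/dL"


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve plus pair-counting AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def creatinine_correct(sample: CohortSample) -> float:
    """Dilution-normalized intensity: raw intensity / urinary creatinine."""
    if sample.creatinine <= 0:
        raise ValueError(
            f"sample {sample.sample_id!r} has non-positive creatinine {sample.creatinine}"
        )
    return sample.intensity / sample.creatinine


def compare_groups(
    cases: Sequence[float],
    controls: Sequence[float],
    test: str = "mannwhitney",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-group comparison; returns (statistic, p-value).

    Default is the Mann-Whitney U test (exact when both groups have
    <= 10 tie-free values, otherwise normal approximation with tie
    correction). ``test="ttest"`` selects Welch's t-test instead.
    """
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 values per group")
    if test == "ttest":
        res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if test != "mannwhitney":
        raise ValueError(f"unknown test {test!r}")
    tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _case_mask(labels: Sequence[str], case_label: str) -> np.ndarray:
    labels_arr = np.asarray(labels)
    mask = labels_arr == case_label
    if mask.all() or not mask.any():
        raise ValueError("both case and control labels must be present")
    return mask


def roc(scores: Sequence[float], labels: Sequence[str], case_label: str = "case") -> ROCResult:
    """Empirical ROC; AUC by pair counting: (concordant + 0.5 x ties) / (n1 x n0)."""
    s = np.asarray(scores, dtype=float)
    mask = _case_mask(labels, case_label)
    cases, controls = s[mask], s[~mask]

    # pair-counting AUC via midranks (equivalent to U / (n1*n0))
    ranks = stats.rankdata(s)
    n1, n0 = cases.size, controls.size
    u = ranks[mask].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.array([(cases >= t).mean() for t in thresholds])
    spec = np.array([(controls < t).mean() for t in thresholds])
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def trapezoidal_auc(result: ROCResult) -> float:
    """Area under the empirical ROC polygon (independent of pair counting)."""
    fpr = 1.0 - result.specificity
    return float(np.trapezoid(result.sensitivity, fpr))


def youden_cutoff(result: ROCResult) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity - 1; ties favor specificity."""
    j = result.sensitivity + result.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    # among tied Youden indices, pick the highest-specificity point
    i = best[np.argmax(result.specificity[best])]
    return float(result.thresholds[i]), float(result.sensitivity[i]), float(result.specificity[i])


def auc_confidence_interval(
    scores: Sequence[float],
    labels: Sequence[str],
    case_label: str = "case",
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI for the pair-counting AUC."""
    s = np.asarray(scores, dtype=float)
    mask = _case_mask(labels, case_label)
    cases, controls = s[mask], s[~mask]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        xs = rng.choice(cases, size=cases.size, replace=True)
        ys = rng.choice(controls, size=controls.size, replace=True)
        ranks = stats.rankdata(np.concatenate([xs, ys]))
        u = ranks[: xs.size].sum() - xs.size * (xs.size + 1) / 2.0
        aucs[b] = u / (xs.size * ys.size)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def read_cohort(path: str | Path) -> list[CohortSample]:
    """Read a cohort CSV with columns sample_id, group, intensity, creatinine."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "intensity", "creatinine"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {sorted(missing)}")
    unit_col = df["creatinine_unit"] if "creatinine_unit" in df.columns else None
    return [
        CohortSample(
            sample_id=str(row.sample_id),
            group=str(row.group),
            intensity=float(row.intensity),
            creatinine=float(row.creatinine),
            creatinine_unit=str(unit_col.iloc[i]) if unit_col is not None else "mg/dL",
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def evaluate_cohort(
    samples: Sequence[CohortSample],
    case_label: str = "case",
    correct_creatinine: bool = True,
    seed: int | None = None,
) -> dict:
    """Full evaluation: correction, Mann-Whitney comparison, ROC/AUC with CI, Youden cutoff."""
    scores = np.array(
        [creatinine_correct(s) if correct_creatinine else s.intensity for s in samples]
    )
    labels = [s.group for s in samples]
    mask = _case_mask(labels, case_label)
    stat, p = compare_groups(scores[mask], scores[~mask])
    result = roc(scores, labels, case_label)
    cutoff, sens, spec = youden_cutoff(result)
    ci_lo, ci_hi = auc_confidence_interval(scores, labels, case_label, seed=seed)
    return {
        "n_case": int(mask.sum()),
        "n_control": int((~mask).sum()),
        "creatinine_corrected": correct_creatinine,
        "mannwhitney_u": stat,
        "p_value": p,
        "auc": result.auc,
        "auc_ci95": [ci_lo, ci_hi],
        "youden_cutoff": cutoff,
        "sensitivity": sens,
        "specificity": spec,
    }
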