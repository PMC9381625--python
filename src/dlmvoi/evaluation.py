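"""Test-set evaluation: ROC analysis, DeLong intervals, model comparison,
operating-threshold selection, and the VOI-diameter sweep experiment.

AUC is the Mann-Whitney U statistic normalized by n1*n0 with ties counted
one half.  Confidence intervals use the DeLong structural-components
variance with a normal approximation, clipped to [0, 1]; paired model
comparison is the two-sided paired DeLong test.  The operating threshold
maximizes Youden's J (sensitivity + specificity - 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import ExtractionParams, extract_case
from .modeling import SplitSpec, split_cohort, optimize, predict
from .voi import build_dlm_voi, ClickPoint, sweep_diameters

__all__ = [
    "EvalResult", "ComparisonResult", "roc_auc", "auc_ci", "compare_models",
    "youden_threshold", "evaluate_scores", "diameter_sweep_report",
]


@dataclass(frozen=True)
class EvalResult:
    """ROC summary for one model on one evaluated set."""

    model_id: str
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    roc_fpr: tuple[float, ...]
    roc_tpr: tuple[float, ...]
    diameter_mm: float | None = None
    n_cases: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "EvalResult":
        d = json.loads(s)
        d["roc_fpr"] = tuple(d["roc_fpr"])
        d["roc_tpr"] = tuple(d["roc_tpr"])
        return cls(**d)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired AUC comparison between two models on the same cases."""

    auc_a: float
    auc_b: float
    difference: float
    p_value: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.size != y.size:
        raise ValueError("scores and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    return s, y


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U; tied pairs count one half."""
    s, y = _check_scores_labels(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimate)."""
    s, y = _check_scores_labels(scores, labels)
    auc, v10, v01 = _delong_components(s, y)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return float(auc), float(var)


def auc_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation DeLong interval, clipped to [0, 1].

    Degenerate (zero) variance collapses to a point interval at the AUC.
    """
    auc, var = delong_variance(scores, labels)
    if var <= 0:
        return (auc, auc)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def compare_models(scores_a: np.ndarray, scores_b: np.ndarray,
                   labels: np.ndarray, level: float = 0.95) -> ComparisonResult:
    """Two-sided paired DeLong test for a difference in correlated AUCs."""
    a, y = _check_scores_labels(scores_a, labels)
    b, y2 = _check_scores_labels(scores_b, labels)
    if a.size != b.size or not np.array_equal(y, y2):
        raise ValueError("inputs are not paired on the same cases")
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    m, n = v10a.size, v01a.size

    def cov(u, v):
        return np.cov(u, v, ddof=1)[0, 1] if u.size > 1 else 0.0

    var_diff = (
        (np.var(v10a, ddof=1) + np.var(v10b, ddof=1) - 2 * cov(v10a, v10b)) / m
        + (np.var(v01a, ddof=1) + np.var(v01b, ddof=1) - 2 * cov(v01a, v01b)) / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        auc_a=float(auc_a), auc_b=float(auc_b), difference=float(diff),
        p_value=p, ci_a=auc_ci(a, y, level), ci_b=auc_ci(b, y, level),
    )


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing Youden's J.

    A case is called positive when its score is >= the threshold; among
    maximizers the lowest threshold is returned.
    """
    s, y = _check_scores_labels(scores, labels)
    cand = np.unique(s)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best = None
    for t in cand:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), float(sens), float(spec))
    assert best is not None
    return best[1], best[2], best[3]


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    tpr = np.r_[0.0, tps / max(1, (labels == 1).sum())]
    fpr = np.r_[0.0, fps / max(1, (labels == 0).sum())]
    return fpr, tpr


def evaluate_scores(scores: np.ndarray, labels: np.ndarray, model_id: str,
                    diameter_mm: float | None = None) -> EvalResult:
    """Full ROC summary for one score vector."""
    s, y = _check_scores_labels(scores, labels)
    auc = roc_auc(s, y)
    lo, hi = auc_ci(s, y)
    t, sens, spec = youden_threshold(s, y)
    fpr, tpr = _roc_points(s, y)
    return EvalResult(
        model_id=model_id, auc=auc, ci_low=lo, ci_high=hi, threshold=t,
        sensitivity=sens, specificity=spec,
        roc_fpr=tuple(float(v) for v in fpr),
        roc_tpr=tuple(float(v) for v in tpr),
        diameter_mm=diameter_mm, n_cases=int(s.size),
    )


def extract_cohort_table(cases, clicks: dict[str, tuple[int, int, int]],
                         diameter_mm: float,
                         params: ExtractionParams | None = None) -> pd.DataFrame:
    """Feature table (lesions x features + ids/label) for one VOI diameter."""
    params = params or ExtractionParams()
    rows = []
    for case in cases:
        adc = case.volumes["ADC"]
        for lesion in case.lesions:
            click = ClickPoint(clicks[lesion.lesion_id])
            voi = build_dlm_voi(adc, click, case.prostate_mask, diameter_mm)
            feats = extract_case(case.volumes, voi, params)
            rows.append({"case_id": case.case_id, "lesion_id": lesion.lesion_id,
                         "label": int(lesion.is_cs), **feats})
    return pd.DataFrame(rows)


def diameter_sweep_report(
    cases,
    clicks: dict[str, tuple[int, int, int]],
    diameters: Sequence[float] | None = None,
    budget: int = 10,
    seed: int = 0,
    params: ExtractionParams | None = None,
) -> list[EvalResult]:
    """Optimize and evaluate one model per candidate VOI diameter.

    The train/test split is fixed across diameters so the AUC-vs-diameter
    curve reflects only the VOI size, not split noise.
    """
    diameters = list(diameters) if diameters is not None else sweep_diameters()
    labels_all = np.array([int(l.is_cs) for c in cases for l in c.lesions])
    n = labels_all.size
    train_idx, test_idx = split_cohort(n, labels_all, SplitSpec(seed=seed))
    results = []
    for d in diameters:
        table = extract_cohort_table(cases, clicks, d, params)
        feats = table.drop(columns=["case_id", "lesion_id", "label"])
        y = table["label"].to_numpy()
        _, model, _ = optimize(feats.iloc[train_idx], y[train_idx],
                               budget=budget, seed=seed)
        scores = predict(model, feats.iloc[test_idx])
        results.append(evaluate_scores(scores, y[test_idx],
                                       model_id=f"dlm_voi_{d:g}mm",
                                       diameter_mm=float(d)))
    return results
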