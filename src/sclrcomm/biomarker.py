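"""ROC/AUC biomarker analysis.

AUC uses the Mann-Whitney estimator (ties credited 0.5), the ROC curve
enumerates thresholds at the unique score values, and paired AUC
comparison implements the DeLong placement-value test with a stratified
bootstrap as the secondary method.  The screen computes, per protein,
one AUC for diagnosis (e.g. control vs heart failure) and one for
severity (e.g. non-advanced vs advanced disease) so that markers strong
at one task but not the other can be dissociated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .containers import ProteomeTable

__all__ = [
    "ROCResult",
    "AUCComparison",
    "auc",
    "roc_curve",
    "compare_auc_paired",
    "severity_vs_diagnosis_screen",
]


@dataclass
class ROCResult:
    auc: float
    curve: pd.DataFrame  # fpr, tpr, one row per threshold plus (0,0) origin
    n_pos: int
    n_neg: int


@dataclass
class AUCComparison:
    auc_1: float
    auc_2: float
    delta: float
    p_value: float
    method: str


def _check_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative")
    return s, y


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive > random negative), ties 0.5."""
    s, y = _check_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # average ranks handle ties with 0.5 credit
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve(scores, labels) -> ROCResult:
    """ROC curve over thresholds at the unique score values, descending.

    The curve starts at (0, 0), ends at (1, 1), and its trapezoidal area
    matches :func:`auc` to numerical precision.
    """
    s, y = _check_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    # cumulative counts at each unique threshold (score >= threshold -> positive call)
    distinct = np.flatnonzero(np.diff(ss) != 0)
    last_of_threshold = np.concatenate([distinct, [len(ss) - 1]])
    tp = np.cumsum(ys)[last_of_threshold]
    fp = np.cumsum(1 - ys)[last_of_threshold]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    area = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ROCResult(auc=area, curve=curve, n_pos=n_pos, n_neg=n_neg)


def _placements(s, y):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = s[y == 1]
    neg = s[y == 0]
    v10 = np.array(
        [(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos]
    )
    v01 = np.array(
        [(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos) for q in neg]
    )
    return v10, v01


def compare_auc_paired(
    scores_1,
    scores_2,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCComparison:
    """Paired two-sided comparison of two markers' AUCs on the same samples.

    ``method="delong"`` (default) uses the DeLong placement-value
    covariance estimate and a normal reference; ``method="bootstrap"``
    uses a stratified bootstrap (positives and negatives resampled
    separately) of the AUC difference.
    """
    s1, y = _check_labels(scores_1, labels)
    s2, y2 = _check_labels(scores_2, labels)
    if not np.array_equal(y, y2):
        raise ValueError("labels must be identical for both score vectors")
    a1, a2 = auc(s1, y), auc(s2, y)
    delta = a1 - a2
    if method == "delong":
        v10_1, v01_1 = _placements(s1, y)
        v10_2, v01_2 = _placements(s2, y)
        m, n = len(v10_1), len(v01_1)
        s10 = np.cov(np.vstack([v10_1, v10_2])) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.vstack([v01_1, v01_2])) if n > 1 else np.zeros((2, 2))
        cov = s10 / m + s01 / n
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        if var <= 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            z = delta / np.sqrt(var)
            p = float(2 * stats.norm.sf(abs(z)))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        deltas = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [
                    rng.choice(pos, size=len(pos), replace=True),
                    rng.choice(neg, size=len(neg), replace=True),
                ]
            )
            deltas[b] = auc(s1[idx], y[idx]) - auc(s2[idx], y[idx])
        sd = deltas.std(ddof=1)
        if sd == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            p = float(2 * stats.norm.sf(abs(delta / sd)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return AUCComparison(
        auc_1=a1, auc_2=a2, delta=float(delta), p_value=min(p, 1.0), method=method
    )


def severity_vs_diagnosis_screen(
    proteome: ProteomeTable,
    diagnosis_split: tuple,
    severity_split: tuple,
) -> pd.DataFrame:
    """Per-protein diagnosis AUC and severity AUC.

    Each split is ``(negative_groups, positive_groups)`` — group names
    or collections of group names from the proteome's group labels.
    Returns a DataFrame (protein, auc_diagnosis, auc_severity) sorted by
    diagnosis AUC descending.
    """
    out = {}
    for task, split in (("diagnosis", diagnosis_split), ("severity", severity_split)):
        neg, pos = split
        neg_samples = proteome.samples_in(neg)
        pos_samples = proteome.samples_in(pos)
        if len(neg_samples) == 0 or len(pos_samples) == 0:
            raise ValueError(f"{task} split has an empty class")
        cols = list(neg_samples) + list(pos_samples)
        y = np.concatenate([np.zeros(len(neg_samples)), np.ones(len(pos_samples))])
        vals = proteome.values.loc[:, cols].to_numpy(dtype=float)
        out[task] = np.array([auc(row, y) for row in vals])
    table = pd.DataFrame(
        {
            "protein": proteome.proteins,
            "auc_diagnosis": out["diagnosis"],
            "auc_severity": out["severity"],
        }
    )
    return table.sort_values(
        "auc_diagnosis", ascending=False, kind="stable"
    ).reset_index(drop=True)
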