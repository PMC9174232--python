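"""QC filtering, normalization and differential expression.

Filtering conventions follow common full-length scRNA-seq practice:
cells are kept when they detect strictly more than ``min_genes`` genes
("detected" meaning any value > 0), and genes enter the network stage
when they reach an expression value of at least ``min_value`` (default
10, an FPKM-scale floor) in at least ``min_cells`` cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "EmptyResultError",
    "filter_cells_by_detected_genes",
    "filter_genes_by_expression",
    "log_transform",
    "differential_expression",
]

LOG2FC_EPS = 1e-9
#: number of observations per side up to which the exact rank-sum null is used
EXACT_RANKSUM_MAX_N = 10


class EmptyResultError(ValueError):
    """A filter removed everything."""


def filter_cells_by_detected_genes(X: ExpressionMatrix, min_genes: int) -> ExpressionMatrix:
    """Keep cells detecting strictly more than ``min_genes`` genes."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    detected = (X.values.to_numpy() > 0).sum(axis=0)
    keep = detected > min_genes
    if not keep.any():
        raise EmptyResultError(
            f"no cell detects more than {min_genes} genes (max {detected.max() if len(detected) else 0})"
        )
    return X.subset_cells(X.cell_ids[keep])


def filter_genes_by_expression(
    X: ExpressionMatrix, min_value: float = 10.0, min_cells: int = 1
) -> ExpressionMatrix:
    """Keep genes with value >= ``min_value`` in at least ``min_cells`` cells."""
    if min_value < 0:
        raise ValueError("min_value must be >= 0")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_hit = (X.values.to_numpy() >= min_value).sum(axis=1)
    keep = n_hit >= min_cells
    if not keep.any():
        raise EmptyResultError(
            f"no gene reaches {min_value} in at least {min_cells} cell(s)"
        )
    return X.subset_genes(X.gene_ids[keep])


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log2(x + 1)``; monotone and zero-preserving."""
    vals = X.values.to_numpy()
    if vals.size and vals.min() < 0:
        raise ValueError("log_transform requires non-negative values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(vals + 1.0), index=X.gene_ids, columns=X.cell_ids),
        X.cell_meta.copy(),
    )


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both sides have <= EXACT_RANKSUM_MAX_N
    observations and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: the statistic is constant
        return 1.0
    ties = len(np.unique(pooled)) < len(a) + len(b)
    small = len(a) <= EXACT_RANKSUM_MAX_N and len(b) <= EXACT_RANKSUM_MAX_N
    method = "exact" if (small and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def differential_expression(
    X: ExpressionMatrix,
    group_a,
    group_b,
    lfc_threshold: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene rank-sum test of group A vs group B.

    Returns a DataFrame with columns ``gene, log2_fold_change, p_value,
    adjusted_p, mean_a, mean_b, significant``; log2FC is
    ``log2((mean_a + eps) / (mean_b + eps))`` and a gene is significant
    when ``adjusted_p < alpha`` and ``|log2FC| > lfc_threshold``.
    """
    group_a = pd.Index(group_a)
    group_b = pd.Index(group_b)
    if len(group_a.intersection(group_b)):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    missing = group_a.union(group_b).difference(X.cell_ids)
    if len(missing):
        raise ValueError(f"unknown cells: {list(missing[:5])}")
    A = X.values.loc[:, group_a].to_numpy()
    B = X.values.loc[:, group_b].to_numpy()
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    lfc = np.log2((mean_a + LOG2FC_EPS) / (mean_b + LOG2FC_EPS))
    pvals = np.array([_ranksum_p(A[i], B[i]) for i in range(A.shape[0])])
    adj = multipletests(pvals, method="fdr_bh")[1]
    sig = (adj < alpha) & (np.abs(lfc) > lfc_threshold)
    return pd.DataFrame(
        {
            "gene": X.gene_ids,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adjusted_p": adj,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "significant": sig,
        }
    ).reset_index(drop=True)
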