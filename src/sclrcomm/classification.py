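"""Random-forest permutation importance and cross-species module overlap.

Feature importance is the classic mean decrease in accuracy (MDA): a
bagged ensemble of decision trees is trained on bootstrap samples, and
for every tree the out-of-bag (OOB) accuracy is compared with the OOB
accuracy after permuting one feature at a time; the importance of a
feature is the mean drop over trees.  A constant feature therefore has
importance exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ImportanceResult",
    "ModuleOverlapResult",
    "rank_feature_importance",
    "significant_features",
    "module_overlap",
]

DEFAULT_N_TREES = 500


@dataclass
class ImportanceResult:
    importance: pd.Series  # feature -> mean decrease in accuracy, descending
    oob_accuracy: float
    n_trees: int
    seed: int


@dataclass
class ModuleOverlapResult:
    table: pd.DataFrame  # module_a, module_b, overlap, p_value, adjusted_p
    best_match: dict  # module_a -> module_b (only significant matches)


def _as_xy(features, labels):
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        names = list(features.columns)
        index = features.index
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
        index = pd.RangeIndex(len(X))
    y = np.asarray(labels.loc[index] if isinstance(labels, pd.Series) else labels)
    return X, y, names


def rank_feature_importance(
    features,
    labels,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_features: str | int = "sqrt",
) -> ImportanceResult:
    """Mean-decrease-in-accuracy ranking of features for class labels.

    ``features`` is sample x feature (DataFrame or array), ``labels``
    the per-sample class.  Each of ``n_trees`` trees is fit on a
    bootstrap sample; importance per feature is the mean over trees of
    (OOB accuracy - OOB accuracy after permuting that feature among the
    OOB samples).  Deterministic for a fixed seed.
    """
    X, y, names = _as_xy(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    n = len(y)
    rng = np.random.default_rng(seed)
    drops = np.zeros((n_trees, X.shape[1]))
    used = np.zeros(n_trees, dtype=bool)
    votes = {c: np.zeros(n) for c in classes}
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(X[boot], y[boot])
        if len(oob) == 0:
            continue
        used[t] = True
        pred = tree.predict(X[oob])
        for c in classes:
            votes[c][oob[pred == c]] += 1
        acc = float(np.mean(pred == y[oob]))
        for f in range(X.shape[1]):
            col = X[oob, f]
            if np.all(col == col[0]):
                continue  # permuting a constant changes nothing
            Xp = X[oob].copy()
            Xp[:, f] = rng.permutation(col)
            acc_p = float(np.mean(tree.predict(Xp) == y[oob]))
            drops[t, f] = acc - acc_p
    mda = drops[used].mean(axis=0)
    vote_mat = np.column_stack([votes[c] for c in classes])
    voted = vote_mat.sum(axis=1) > 0
    oob_pred = classes[np.argmax(vote_mat[voted], axis=1)]
    oob_accuracy = float(np.mean(oob_pred == y[voted])) if voted.any() else float("nan")
    imp = pd.Series(mda, index=names).sort_values(
        ascending=False, kind="stable"
    )
    return ImportanceResult(
        importance=imp, oob_accuracy=oob_accuracy, n_trees=n_trees, seed=seed
    )


def significant_features(
    features,
    labels,
    n_trees: int = 100,
    n_permutations: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> pd.Series:
    """Features whose MDA exceeds a label-permutation null.

    Uses the maxT (Westfall-Young) correction: the null distribution is
    the per-permutation *maximum* importance over all features, so the
    cutoff controls the family-wise error rate at ``1 - quantile``
    across features rather than per feature.
    """
    X, y, names = _as_xy(features, labels)
    rng = np.random.default_rng(seed)
    observed = rank_feature_importance(
        features, labels, n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1))
    ).importance
    null_max = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        res = rank_feature_importance(
            X, yp, n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1))
        )
        null_max[b] = res.importance.max()
    cutoff = float(np.quantile(null_max, quantile))
    return observed[observed > cutoff]


def module_overlap(
    modules_a: dict,
    modules_b: dict,
    ortholog_map: dict,
    universe,
    alpha: float = 0.05,
) -> ModuleOverlapResult:
    """Hypergeometric overlap of two module collections across species.

    ``modules_a`` genes are mapped through ``ortholog_map`` (must be
    injective on the genes used) into the shared ``universe``; per
    module pair the one-sided hypergeometric p-value of the overlap is
    computed and BH-adjusted across all pairs.  ``best_match`` keeps,
    per module of A, the module of B with the smallest adjusted p (ties
    by larger overlap), provided adjusted_p < alpha.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe after ortholog mapping")
    mapped_vals = [v for v in ortholog_map.values()]
    if len(mapped_vals) != len(set(mapped_vals)):
        raise ValueError("ortholog_map must be injective")
    M = len(universe)
    rows = []
    for ma, genes_a in modules_a.items():
        mapped = {ortholog_map[g] for g in genes_a if g in ortholog_map} & universe
        for mb, genes_b in modules_b.items():
            gb = set(genes_b) & universe
            k = len(mapped & gb)
            p = float(stats.hypergeom.sf(k - 1, M, len(gb), len(mapped)))
            rows.append((ma, mb, k, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["module_a", "module_b", "overlap", "p_value"])
    table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    best: dict[str, str] = {}
    for ma, sub in table.groupby("module_a"):
        sub = sub.sort_values(
            ["adjusted_p", "overlap", "module_b"],
            ascending=[True, False, True],
            kind="stable",
        )
        top = sub.iloc[0]
        if top["adjusted_p"] < alpha:
            best[ma] = top["module_b"]
    return ModuleOverlapResult(table=table, best_match=best)
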