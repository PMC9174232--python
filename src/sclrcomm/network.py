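"""Signed weighted co-expression networks and gene modules.

The network convention is the signed weighted one: adjacency
``a_ij = ((1 + cor_ij) / 2) ** beta`` so anti-correlated genes get
near-zero weight, with the soft power ``beta`` chosen by a scale-free
topology fit.  Modules are branches of an average-linkage dendrogram on
the topological-overlap dissimilarity ``1 - TOM``; modules smaller than
``min_size`` (default 30 genes) are merged into their closest larger
neighbour, and modules with highly correlated eigengenes are merged.
A module eigengene is the first principal component of the module's
standardized expression, oriented to correlate positively with its
member genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = [
    "SoftThresholdResult",
    "GeneModuleSet",
    "pearson_correlation",
    "pick_soft_threshold",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "module_membership",
    "top_module_genes",
]

UNASSIGNED = "unassigned"
DEFAULT_POWERS = tuple(range(1, 21))
DEFAULT_MIN_SIZE = 30
DEFAULT_MERGE_COR = 0.75
DEFAULT_R2_TARGET = 0.85
#: a leftover gene joins a module only if its mean TOM to it beats this
#: quantile of the gene's TOM to everything outside that module
LEFTOVER_TOM_QUANTILE = 0.95
#: ... and this fraction of the module's internal TOM.  Genes coupled to
#: a module through a shared driver only (e.g. cell-type markers) sit
#: near half the internal cohesion, random genes an order of magnitude
#: lower; one third separates the regimes with margin on both sides.
LEFTOVER_INTERNAL_FRACTION = 1.0 / 3.0
#: when expression is available, a leftover gene joins the module whose
#: eigengene it correlates with most, provided that (positive)
#: correlation is significant at this family-wise level (Bonferroni over
#: all leftover x module tests).  A magnitude cutoff would be wrong
#: here: genes coupled to a module through a thresholded or indicator
#: readout of its driver (e.g. cell-type markers) have attenuated but
#: genuine correlation, while an unrelated gene's correlation is pure
#: sampling noise (|r| ~ 1/sqrt(n_cells)) and never significant after
#: correction.
LEFTOVER_KME_ALPHA = 0.01
#: a dendrogram branch counts as a coherent module only when its mean
#: internal TOM exceeds this multiple of its mean TOM to the rest of the
#: network (separation ratio; ~1 for random gene sets)
COHERENCE_RATIO = 2.0
# Sibling-branch separation threshold for splitting a dendrogram node.
# Weaker than COHERENCE_RATIO on purpose: two real modules that share a
# driver (e.g. active in the same cell type) can have cross-TOM as high
# as half their internal TOM and must still be split apart, while the
# two halves of one module sit at a ratio of ~1.
SPLIT_RATIO = 1.3


@dataclass
class SoftThresholdResult:
    beta: int
    fit_table: pd.DataFrame  # power, r2_signed, slope, mean_connectivity
    target_reached: bool


@dataclass
class GeneModuleSet:
    """Gene -> module assignment plus eigengenes and membership correlations."""

    assignment: pd.Series  # gene -> module id or UNASSIGNED
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x cell
    membership: pd.DataFrame = field(default_factory=pd.DataFrame)  # gene x module
    min_size: int = DEFAULT_MIN_SIZE

    def module_ids(self) -> list[str]:
        mods = sorted(set(self.assignment) - {UNASSIGNED})
        return mods

    def module_genes(self) -> dict:
        out: dict[str, list[str]] = {}
        for gene, mod in self.assignment.items():
            if mod != UNASSIGNED:
                out.setdefault(mod, []).append(gene)
        return out


# --------------------------------------------------------------------------
# correlation / adjacency / TOM
# --------------------------------------------------------------------------


def _constant_rows(vals: np.ndarray) -> np.ndarray:
    """Rows whose variation is indistinguishable from float rounding.

    A relative tolerance is needed: exp/log round-trips leave ~1e-16
    jitter on genes that are constant by construction, and correlations
    of pure rounding noise are meaningless (often exactly +/-1).
    """
    sd = vals.std(axis=1)
    scale = np.abs(vals).max(axis=1)
    return sd <= 1e-10 * np.maximum(scale, 1.0)


def pearson_correlation(X: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation across cells.

    Constant genes get correlation 0 with everything (and 1 with
    themselves) rather than NaN.
    """
    vals = X.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(vals)
    cor = np.atleast_2d(cor)
    constant = _constant_rows(vals)
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=X.gene_ids, columns=X.gene_ids)


def signed_adjacency(cor, beta: int):
    """Signed adjacency ``((1 + cor) / 2) ** beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    arr = np.asarray(cor, dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    adj = ((1.0 + np.clip(arr, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adj


def topological_overlap(adjacency):
    """Topological overlap matrix.

    ``tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j,
    where ``l_ij = sum_u a_iu a_uj`` over u not in {i, j} and ``k_i`` is
    the connectivity of i (sum of off-diagonal adjacency); unit diagonal.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    L = A0 @ A0  # includes no u == i or u == j terms since diag(A0) == 0
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A0) / (kmin + 1.0 - A0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


# --------------------------------------------------------------------------
# soft threshold
# --------------------------------------------------------------------------


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution fit and its slope."""
    k = k[k > 0]
    if len(k) < 3:
        raise ValueError("not enough positive connectivities")
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        kb = k[which == b]
        if len(kb) == 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(len(kb) / len(k)))
    if len(xs) < 2:
        raise ValueError("fewer than 2 non-empty connectivity bins")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(r2 * np.sign(-slope)), float(slope)


def pick_soft_threshold(
    X: ExpressionMatrix,
    powers=DEFAULT_POWERS,
    r2_target: float = DEFAULT_R2_TARGET,
) -> SoftThresholdResult:
    """Smallest power whose scale-free fit index reaches ``r2_target``.

    If no power reaches the target, the power maximizing the signed R^2
    is returned with ``target_reached=False``.
    """
    powers = list(powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("powers must be a non-empty ascending list")
    if X.n_genes < 3:
        raise ValueError("need at least 3 genes")
    cor = pearson_correlation(X).to_numpy()
    rows = []
    for p in powers:
        adj = signed_adjacency(cor, p)
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        r2s, slope = _scale_free_fit(k)
        rows.append((p, r2s, slope, float(k.mean())))
    table = pd.DataFrame(
        rows, columns=["power", "r2_signed", "slope", "mean_connectivity"]
    )
    ok = table[table["r2_signed"] >= r2_target]
    if len(ok):
        return SoftThresholdResult(int(ok["power"].iloc[0]), table, True)
    best = int(table.loc[table["r2_signed"].idxmax(), "power"])
    return SoftThresholdResult(best, table, False)


# --------------------------------------------------------------------------
# module detection
# --------------------------------------------------------------------------


def _merge_correlated_modules(assignment, expression, merge_cor):
    """Iteratively merge module pairs whose eigengenes correlate > merge_cor."""
    while True:
        mods = sorted(set(assignment) - {UNASSIGNED})
        if len(mods) < 2:
            return assignment
        me = module_eigengenes(expression, assignment)
        cor = np.corrcoef(me.to_numpy())
        best, best_cor = None, merge_cor
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if cor[i, j] > best_cor:
                    best, best_cor = (mods[i], mods[j]), cor[i, j]
        if best is None:
            return assignment
        a, b = best
        sizes = assignment.value_counts()
        keep, absorb = (a, b) if sizes[a] >= sizes[b] else (b, a)
        assignment = assignment.replace({absorb: keep})


def detect_modules(
    tom,
    min_size: int = DEFAULT_MIN_SIZE,
    merge_cor: float = DEFAULT_MERGE_COR,
    expression: ExpressionMatrix | None = None,
) -> GeneModuleSet:
    """Cut the TOM dendrogram into modules and apply the merge rules.

    The average-linkage dendrogram of ``1 - TOM`` is explored top-down:
    a branch is accepted as a module as soon as it is coherent (mean
    internal TOM more than ``COHERENCE_RATIO`` times its mean TOM to the
    rest of the network); incoherent branches are split further.  This
    finds tight and loose modules at their own heights instead of
    relying on a single global cut, and dissolves pure-noise branches
    entirely (their internal and external TOM are indistinguishable),
    which keeps random inputs almost entirely unassigned.  Coherent
    branches smaller than ``min_size`` are merged wholesale into the
    module with the closest TOM centroid, mirroring the rule that
    undersized modules join their nearest larger neighbour.  Remaining
    genes join the module whose eigengene they correlate with most,
    provided that positive correlation is significant at the
    Bonferroni-corrected ``LEFTOVER_KME_ALPHA`` level (when expression
    is available); without expression a TOM-based fallback
    requires their mean TOM to the module to beat both the
    ``LEFTOVER_TOM_QUANTILE`` quantile of their TOM to everything
    outside that module and ``LEFTOVER_INTERNAL_FRACTION`` of the
    module's internal TOM.  Otherwise they stay unassigned.
    When ``expression`` is provided, zero-variance genes are excluded up
    front (a constant gene cannot be co-expressed with anything; its
    correlations are undefined) and module pairs with eigengene
    correlation > ``merge_cor`` are additionally merged.  Fully
    deterministic.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    T = tom.to_numpy() if isinstance(tom, pd.DataFrame) else np.asarray(tom, float)
    genes = (
        tom.index
        if isinstance(tom, pd.DataFrame)
        else pd.Index([f"g{i}" for i in range(T.shape[0])])
    )
    if expression is not None:
        vals = expression.values.reindex(genes).to_numpy(float)
        varying = ~_constant_rows(vals)
        if not varying.all():
            keep = genes[varying]
            if len(keep) < 2:
                empty = pd.Series(UNASSIGNED, index=genes, dtype=object)
                return GeneModuleSet(assignment=empty, min_size=min_size)
            sub_tom = pd.DataFrame(
                T[np.ix_(np.flatnonzero(varying), np.flatnonzero(varying))],
                index=keep,
                columns=keep,
            )
            sub = detect_modules(
                sub_tom,
                min_size=min_size,
                merge_cor=merge_cor,
                expression=expression.subset_genes(list(keep)),
            )
            full = sub.assignment.reindex(genes, fill_value=UNASSIGNED)
            return GeneModuleSet(assignment=full, min_size=min_size)
    n = T.shape[0]
    dissim = 1.0 - T
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    Z = average(squareform(dissim, checks=False))

    def coherent(ix: np.ndarray) -> bool:
        if len(ix) < 2:
            return False
        sub = T[np.ix_(ix, ix)]
        internal = sub[~np.eye(len(ix), dtype=bool)].mean()
        rest = np.setdiff1d(np.arange(n), ix, assume_unique=True)
        if len(rest) == 0:
            return False  # the full gene set: no outside to compare to
        external = T[np.ix_(ix, rest)].mean()
        return internal > COHERENCE_RATIO * external

    def internal_mean(ix: np.ndarray) -> float:
        sub = T[np.ix_(ix, ix)]
        return float(sub[~np.eye(len(ix), dtype=bool)].mean())

    # top-down branch descent: a branch becomes a module once it is
    # coherent against the rest of the network AND its own two children
    # are not well-separated from each other (otherwise it is a union of
    # distinct modules and must be split further).  A single global cut
    # height cannot serve tight and loose modules at the same time.
    cores: list[np.ndarray] = []
    smalls: list[np.ndarray] = []
    stack = [to_tree(Z)]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue
        ix = np.array(sorted(node.pre_order()))
        left = np.array(sorted(node.get_left().pre_order()))
        right = np.array(sorted(node.get_right().pre_order()))
        cross = float(T[np.ix_(left, right)].mean())
        if len(left) >= 2 and len(right) >= 2:
            splittable = (
                internal_mean(left) > SPLIT_RATIO * cross
                and internal_mean(right) > SPLIT_RATIO * cross
            )
        elif len(ix) == 2:
            splittable = False
        else:
            # one child is a single leaf: it belongs to the branch only
            # if its TOM to the subtree matches the subtree's internal
            # TOM; a weakly attached straggler means the node is a
            # subtree+noise union and must be split
            sub = left if len(left) >= 2 else right
            splittable = internal_mean(sub) > SPLIT_RATIO * cross
        accept = coherent(ix) and not splittable
        if accept:
            (cores if len(ix) >= min_size else smalls).append(ix)
        else:
            stack.append(node.get_left())
            stack.append(node.get_right())

    # stable ordering: largest module first, ties by smallest member index
    cores.sort(key=lambda ix: (-len(ix), ix[0]))
    assignment = np.full(n, UNASSIGNED, dtype=object)
    module_names = [f"M{i + 1}" for i in range(len(cores))]
    for name, ix in zip(module_names, cores):
        assignment[ix] = name

    assigned = set()
    for ix in cores:
        assigned.update(ix.tolist())
    smalls.sort(key=lambda ix: (-len(ix), ix[0]))
    for ix in smalls:
        if cores:
            # a genuine undersized module: absorb into closest larger one
            centroid_tom = [T[np.ix_(ix, c)].mean() for c in cores]
            assignment[ix] = module_names[int(np.argmax(centroid_tom))]
            assigned.update(ix.tolist())
    leftovers = [g for g in range(n) if g not in assigned]

    if cores:
        internal_tom = []
        for c in cores:
            sub = T[np.ix_(c, c)]
            internal_tom.append(sub[~np.eye(len(c), dtype=bool)].mean())
        kme = None
        if expression is not None and leftovers:
            # membership route: correlation with the module eigengene
            # ("kME") separates true members from sampling noise far
            # more cleanly than TOM, whose min-connectivity
            # normalisation inflates weak genes' overlap with hubs
            current = pd.Series(assignment, index=genes)
            eig = module_eigengenes(expression, current)
            ev = eig.reindex([f"M{i + 1}" for i in range(len(cores))]).to_numpy()
            vals = expression.values.reindex(genes).to_numpy(float)
            lv = vals[leftovers]
            with np.errstate(invalid="ignore", divide="ignore"):
                lz = (lv - lv.mean(axis=1, keepdims=True)) / lv.std(
                    axis=1, keepdims=True
                )
                ez = (ev - ev.mean(axis=1, keepdims=True)) / ev.std(
                    axis=1, keepdims=True
                )
                kme = np.nan_to_num(lz @ ez.T / lv.shape[1], nan=-1.0)
        n_cells = expression.n_cells if expression is not None else 0
        if kme is not None and n_cells > 3:
            # Bonferroni-corrected per-test level over every
            # leftover x module correlation test
            alpha = LEFTOVER_KME_ALPHA / (len(leftovers) * len(cores))
            df = n_cells - 2
        for pos, g in enumerate(leftovers):
            if kme is not None:
                if n_cells <= 3:
                    continue
                best = int(np.argmax(kme[pos]))
                r = float(kme[pos, best])
                if r > 0:
                    with np.errstate(divide="ignore"):
                        t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
                    p = 2.0 * float(stats.t.sf(t, df))
                    if p < alpha:
                        assignment[g] = module_names[best]
                continue
            # TOM-only fallback when no expression is available
            mean_tom = [T[g, c].mean() for c in cores]
            best = int(np.argmax(mean_tom))
            # the floor is the tail of the gene's TOM to everything
            # OUTSIDE the candidate module: a gene whose only strong
            # neighbourhood is the module itself must still qualify
            outside = np.setdiff1d(np.arange(n), np.append(cores[best], g))
            floor = np.quantile(T[g, outside], LEFTOVER_TOM_QUANTILE)
            # must beat both that tail and a fixed fraction of the
            # module's internal coherence; keeps weakly-linked genes out
            threshold = max(floor, LEFTOVER_INTERNAL_FRACTION * internal_tom[best])
            if mean_tom[best] > threshold:
                assignment[g] = module_names[best]

    result = pd.Series(assignment, index=genes)
    # renumber by decreasing size for a stable public labelling
    result = _relabel_by_size(result)
    if expression is not None and len(set(result) - {UNASSIGNED}) >= 2:
        result = _merge_correlated_modules(result, expression, merge_cor)
        result = _relabel_by_size(result)
    return GeneModuleSet(assignment=result, min_size=min_size)


def _relabel_by_size(assignment: pd.Series) -> pd.Series:
    sizes = assignment[assignment != UNASSIGNED].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    mapping = {old: f"M{i + 1}" for i, old in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return assignment.map(mapping)


# --------------------------------------------------------------------------
# eigengenes / membership
# --------------------------------------------------------------------------


def _standardize_rows(vals: np.ndarray) -> np.ndarray:
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    out = np.zeros_like(vals, dtype=float)
    np.divide(vals - mean, sd, out=out, where=sd > 0)
    return out


def module_eigengenes(X: ExpressionMatrix, assignment: pd.Series) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    The eigengene is oriented so that its mean correlation with the
    module's member genes is >= 0; an exact tie is broken toward
    positive correlation with the first member gene.
    """
    mods = sorted(set(assignment) - {UNASSIGNED})
    rows = []
    for mod in mods:
        genes = assignment.index[assignment == mod]
        if len(genes) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        vals = X.values.loc[genes].to_numpy(dtype=float)
        if np.all(vals.std(axis=1) == 0):
            raise ValueError(f"module {mod} contains only constant genes")
        z = _standardize_rows(vals)
        # PC1 of the cell x gene matrix via SVD
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        sd = pc1.std()
        pc1 = pc1 / sd if sd > 0 else pc1
        cors = np.array([_safe_cor(z[i], pc1) for i in range(z.shape[0])])
        mean_cor = cors.mean()
        if mean_cor < 0 or (mean_cor == 0 and len(cors) and cors[0] < 0):
            pc1 = -pc1
        rows.append(pc1)
    return pd.DataFrame(rows, index=mods, columns=X.cell_ids)


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def module_membership(X: ExpressionMatrix, eigengenes: pd.DataFrame):
    """Pearson correlation of every gene with every module eigengene.

    Returns ``(membership, constant_flags)`` where constant genes carry
    correlation 0 and a True flag instead of NaN.
    """
    if not eigengenes.columns.equals(X.cell_ids):
        raise ValueError("eigengenes were not computed on the same cells")
    vals = X.values.to_numpy(dtype=float)
    constant = vals.std(axis=1) == 0
    z = _standardize_rows(vals)
    ez = _standardize_rows(eigengenes.to_numpy(dtype=float))
    n = vals.shape[1]
    mm = (z @ ez.T) / n
    mm[constant, :] = 0.0
    membership = pd.DataFrame(
        np.clip(mm, -1.0, 1.0), index=X.gene_ids, columns=eigengenes.index
    )
    flags = pd.Series(constant, index=X.gene_ids, name="constant")
    return membership, flags


def top_module_genes(membership: pd.DataFrame, module: str, k: int = 10) -> pd.Series:
    """The k genes most correlated with ``module``'s eigengene.

    Descending by correlation, ties broken lexicographically by gene id;
    if k exceeds the gene count all genes are returned.
    """
    if module not in membership.columns:
        raise KeyError(f"unknown module {module!r}")
    col = membership[module]
    order = sorted(col.index, key=lambda g: (-col[g], str(g)))
    return col.loc[order[: min(k, len(order))]]
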