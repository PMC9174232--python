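"""Embedding, graph clustering, lineage inference and pseudotime.

The trajectory model is deliberately simple and deterministic: cells are
embedded in 2D, clustered on a shared-nearest-neighbour graph by greedy
modularity maximization, a minimum spanning tree over cluster centroids
defines lineages as root-to-leaf cluster paths, and pseudotime is arc
length along the piecewise-linear centroid path after orthogonal
projection, rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix

__all__ = [
    "TrajectoryResult",
    "ModuleDynamics",
    "embed_cells",
    "cluster_snn",
    "infer_lineages",
    "compute_pseudotime",
    "module_dynamics",
    "module_exclusivity",
]

DEFAULT_EXCLUSIVITY_COR = -0.3


@dataclass
class TrajectoryResult:
    coords: pd.DataFrame  # cell x (x, y)
    cluster: pd.Series  # cell -> label (ints, 1 = largest)
    lineages: list  # list of ordered cluster-label lists, shared root
    pseudotime: pd.DataFrame  # cell x lineage (NaN off-lineage)


@dataclass
class ModuleDynamics:
    grid: np.ndarray  # pseudotime grid (100 points)
    curve: np.ndarray  # smoothed eigengene on the grid
    direction: str  # "increasing" | "decreasing" | "non-monotone"
    endpoint_diff: float  # range-normalized curve end minus start
    p_value: float  # permutation p for the endpoint difference
    span: float


# --------------------------------------------------------------------------
# embedding
# --------------------------------------------------------------------------


def embed_cells(
    X: ExpressionMatrix,
    n_neighbors: int = 15,
    seed: int = 0,
    method: str = "mds",
) -> pd.DataFrame:
    """2D embedding of cells (cells x genes feature space).

    ``method="mds"`` (default) is classical metric MDS on Euclidean
    distances between standardized expression profiles — deterministic,
    used throughout the test suite.  ``method="umap"`` delegates to
    umap-learn with ``random_state=seed``.
    """
    if X.n_cells < 2:
        raise ValueError("cannot embed fewer than 2 cells")
    if n_neighbors >= X.n_cells:
        raise ValueError("n_neighbors must be smaller than the number of cells")
    feats = X.values.to_numpy(dtype=float).T  # cells x genes
    sd = feats.std(axis=0)
    mask = sd > 0
    feats = (feats[:, mask] - feats[:, mask].mean(axis=0)) / sd[mask]
    if method == "umap":
        import umap

        emb = umap.UMAP(
            n_neighbors=n_neighbors, n_components=2, random_state=seed
        ).fit_transform(feats)
    elif method == "mds":
        from .communication import classical_mds

        emb = classical_mds(cdist(feats, feats), n_components=2)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(np.asarray(emb), index=X.cell_ids, columns=["x", "y"])


# --------------------------------------------------------------------------
# SNN clustering
# --------------------------------------------------------------------------


def cluster_snn(
    data,
    k: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Shared-nearest-neighbour graph clustering.

    Builds a k-nearest-neighbour graph in Euclidean space, weights the
    edge between i and j by ``shared / (2k - shared)`` where shared is
    the number of common neighbours, drops zero-weight edges, and
    maximizes modularity by greedy agglomeration.  Labels are integers
    renumbered by decreasing cluster size (1 = largest).
    """
    if isinstance(data, ExpressionMatrix):
        points = data.values.to_numpy(dtype=float).T
        index = data.cell_ids
    elif isinstance(data, pd.DataFrame):
        points = data.to_numpy(dtype=float)
        index = data.index
    else:
        points = np.asarray(data, dtype=float)
        index = pd.RangeIndex(len(points))
    n = len(points)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    _, idx = nn.kneighbors(points)
    neigh = [set(row[1:]) for row in idx]  # exclude self
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in neigh[i]:
            j = int(j)
            if G.has_edge(i, j):
                continue
            shared = len(neigh[i] & neigh[j])
            if shared == 0:
                continue
            G.add_edge(i, j, weight=shared / (2 * k - shared))
    comms = nx.algorithms.community.greedy_modularity_communities(
        G, weight="weight", resolution=resolution
    )
    labels = np.zeros(n, dtype=int)
    ordered = sorted(
        (sorted(c) for c in comms), key=lambda c: (-len(c), c[0])
    )
    for lab, members in enumerate(ordered, start=1):
        labels[list(members)] = lab
    return pd.Series(labels, index=index, name="cluster")


# --------------------------------------------------------------------------
# lineages and pseudotime
# --------------------------------------------------------------------------


def _centroids(coords: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    return coords.groupby(labels).mean()


def infer_lineages(coords: pd.DataFrame, labels: pd.Series, root) -> list:
    """Root-to-leaf paths of the MST over cluster centroids.

    Deterministic: MST edges are considered in (distance, label pair)
    order and lineages are sorted by their cluster-label sequence.
    """
    if root not in set(labels):
        raise ValueError(f"root cluster {root!r} not among labels")
    cent = _centroids(coords, labels)
    clusters = list(cent.index)
    if len(clusters) == 1:
        return [[root]]
    G = nx.Graph()
    G.add_nodes_from(clusters)
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            d = float(np.linalg.norm(cent.loc[a] - cent.loc[b]))
            G.add_edge(a, b, weight=d)
    mst = nx.minimum_spanning_tree(G, weight="weight", algorithm="kruskal")
    leaves = [c for c in mst.nodes if mst.degree(c) == 1 and c != root]
    if not leaves:  # root is the only leaf (single edge chain from root)
        leaves = [c for c in mst.nodes if c != root]
    lineages = []
    for leaf in leaves:
        path = nx.shortest_path(mst, source=root, target=leaf)
        lineages.append(list(path))
    lineages.sort(key=lambda p: [str(c) for c in p])
    return lineages


def compute_pseudotime(
    coords: pd.DataFrame, lineage: list, labels: pd.Series
) -> pd.Series:
    """Arc-length pseudotime along the piecewise-linear centroid path.

    Cells belonging to the lineage's clusters are projected orthogonally
    onto the path through that lineage's centroids; pseudotime is arc
    length from the root end, rescaled to [0, 1] (projections beyond the
    endpoints clamp to 0/1).
    """
    if not lineage:
        raise ValueError("empty lineage")
    known = set(labels)
    unknown = [c for c in lineage if c not in known]
    if unknown:
        raise ValueError(f"lineage references unknown clusters {unknown}")
    cent = _centroids(coords, labels).loc[lineage].to_numpy(dtype=float)
    cells = labels.index[labels.isin(lineage)]
    pts = coords.loc[cells].to_numpy(dtype=float)
    if len(lineage) == 1:
        return pd.Series(0.0, index=cells)
    seg_vec = np.diff(cent, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    best_d = np.full(len(pts), np.inf)
    best_t = np.zeros(len(pts))
    for s in range(len(seg_vec)):
        v = seg_vec[s]
        L2 = seg_len[s] ** 2
        if L2 == 0:
            proj = np.zeros(len(pts))
        else:
            proj = np.clip((pts - cent[s]) @ v / L2, 0.0, 1.0)
        closest = cent[s] + proj[:, None] * v
        d = np.linalg.norm(pts - closest, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_t[better] = cum[s] + proj[better] * seg_len[s]
    pt = best_t / total if total > 0 else best_t
    return pd.Series(np.clip(pt, 0.0, 1.0), index=cells)


# --------------------------------------------------------------------------
# module dynamics along pseudotime
# --------------------------------------------------------------------------


def _sliding_mean(t: np.ndarray, y: np.ndarray, grid: np.ndarray, window: int):
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    out = np.empty(len(grid))
    half = window / 2.0
    for i, g in enumerate(grid):
        # the `window` cells nearest in pseudotime
        pos = np.searchsorted(ts, g)
        lo = int(np.clip(pos - np.ceil(half), 0, len(ts) - window))
        out[i] = ys[lo : lo + window].mean()
    return out


def module_dynamics(
    eigengene: pd.Series,
    pseudotime: pd.Series,
    span: float = 0.3,
    n_grid: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ModuleDynamics:
    """Smoothed eigengene curve along pseudotime with a direction call.

    Local-mean smoothing with a sliding window of ``span * n`` cells on
    a ``n_grid``-point pseudotime grid.  The direction is called from
    the range-normalized endpoint difference against a permutation null
    (cells shuffled against pseudotime): "increasing"/"decreasing" when
    the permutation p-value is below ``alpha``, else "non-monotone".
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    cells = pseudotime.index.intersection(eigengene.index)
    if len(cells) < 5:
        raise ValueError("need at least 5 cells on the lineage")
    t = pseudotime.loc[cells].to_numpy(dtype=float)
    y = eigengene.loc[cells].to_numpy(dtype=float)
    window = max(int(np.ceil(span * len(cells))), 2)
    grid = np.linspace(t.min(), t.max(), n_grid)
    curve = _sliding_mean(t, y, grid, window)
    delta = curve[-1] - curve[0]
    crange = curve.max() - curve.min()
    endpoint_diff = float(delta / crange) if crange > 0 else 0.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        c = _sliding_mean(t, yp, grid, window)
        null[b] = c[-1] - c[0]
    p = float((np.sum(np.abs(null) >= abs(delta)) + 1) / (n_permutations + 1))
    if p < alpha and delta > 0:
        direction = "increasing"
    elif p < alpha and delta < 0:
        direction = "decreasing"
    else:
        direction = "non-monotone"
    return ModuleDynamics(
        grid=grid,
        curve=curve,
        direction=direction,
        endpoint_diff=endpoint_diff,
        p_value=p,
        span=span,
    )


def module_exclusivity(
    eigengenes: pd.DataFrame,
    module_a: str,
    module_b: str,
    threshold: float = DEFAULT_EXCLUSIVITY_COR,
) -> tuple[float, bool]:
    """Pearson correlation of two module eigengenes across cells and a
    "mutually exclusive" flag (correlation <= ``threshold``)."""
    for m in (module_a, module_b):
        if m not in eigengenes.index:
            raise KeyError(f"unknown module {m!r}")
    a = eigengenes.loc[module_a].to_numpy(dtype=float)
    b = eigengenes.loc[module_b].to_numpy(dtype=float)
    cor = float(np.corrcoef(a, b)[0, 1])
    return cor, cor <= threshold
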