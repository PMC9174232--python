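"""Ligand-receptor communication mapping between cell types.

Genes are attributed to cell types through co-expression modules: a
module is annotated to the cell type whose marker genes it best
overlaps, and a directed interaction edge s -> t is emitted for every
database ligand-receptor pair whose ligand sits in a module annotated
s and whose receptor sits in a module annotated t.  The cell-type x
cell-type count matrix of those edges is the communication summary, and
hypergeometric enrichment annotates gene sets on any gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .network import UNASSIGNED, GeneModuleSet, pearson_correlation

__all__ = [
    "LRDatabase",
    "CellTypeAnnotation",
    "InteractionMap",
    "annotate_modules",
    "build_lr_map",
    "build_interaction_network",
    "rank_interacting_cell_types",
    "enrichment_test",
    "classical_mds",
]

UNANNOTATED = "unannotated"


@dataclass
class LRDatabase:
    """Directed ligand -> receptor gene pairs, unique rows."""

    pairs: list

    def __post_init__(self) -> None:
        seen = set()
        clean = []
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError("ligand and receptor ids must be non-empty")
            if (lig, rec) in seen:
                continue
            seen.add((lig, rec))
            clean.append((str(lig), str(rec)))
        self.pairs = clean

    def genes(self) -> list:
        out: list[str] = []
        for lig, rec in self.pairs:
            for g in (lig, rec):
                if g not in out:
                    out.append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["ligand", "receptor"])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CellTypeAnnotation:
    """module -> cell-type name (or 'unannotated') with marker evidence."""

    labels: dict
    evidence: dict = field(default_factory=dict)

    def __getitem__(self, module: str) -> str:
        return self.labels.get(module, UNANNOTATED)


@dataclass
class InteractionMap:
    edges: pd.DataFrame  # ligand, receptor, source, target
    counts: pd.DataFrame  # cell-type x cell-type, directed (source rows)


def annotate_modules(modules: GeneModuleSet, markers: dict) -> CellTypeAnnotation:
    """Annotate each module to the cell type with the largest marker overlap.

    ``markers`` maps cell type -> marker gene set; sets must be disjoint.
    A tie or zero overlap leaves the module unannotated.
    """
    all_markers: set[str] = set()
    for ct, genes in markers.items():
        genes = set(genes)
        overlap = all_markers & genes
        if overlap:
            raise ValueError(f"marker sets overlap on {sorted(overlap)[:5]}")
        all_markers |= genes
    labels: dict[str, str] = {}
    evidence: dict[str, list] = {}
    for mod, genes in modules.module_genes().items():
        gset = set(genes)
        hits = {ct: sorted(gset & set(mk)) for ct, mk in markers.items()}
        counts = {ct: len(h) for ct, h in hits.items()}
        best = max(counts.values(), default=0)
        winners = [ct for ct, c in counts.items() if c == best]
        if best == 0 or len(winners) != 1:
            labels[mod] = UNANNOTATED
        else:
            labels[mod] = winners[0]
            evidence[mod] = hits[winners[0]]
    return CellTypeAnnotation(labels=labels, evidence=evidence)


def classical_mds(dissim: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS; deterministic up to axis sign,
    which is fixed by making the largest-magnitude coordinate positive."""
    D = np.asarray(dissim, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    coords = np.zeros((n, n_components))
    for out_i, i in enumerate(order):
        if w[i] > 0:
            axis = v[:, i] * np.sqrt(w[i])
            j = int(np.argmax(np.abs(axis)))
            if axis[j] < 0:
                axis = -axis
            coords[:, out_i] = axis
    return coords


def build_lr_map(
    X: ExpressionMatrix,
    lr_db: LRDatabase,
    edge_cor_min: float = 0.5,
    seed: int = 0,
):
    """2D co-expression map of the ligand/receptor genes.

    Restricts the matrix to database genes, embeds them by classical MDS
    on ``1 - cor`` and emits an edge for every gene pair with Pearson
    correlation >= ``edge_cor_min``.  Returns ``(coords, edges)`` where
    coords is a gene x (x, y) DataFrame.  The seed is accepted for
    interface stability; the default embedding is deterministic.
    """
    present = [g for g in lr_db.genes() if g in X.gene_ids]
    if len(present) < 3:
        raise ValueError(f"only {len(present)} LR genes present; need >= 3")
    sub = X.subset_genes(present)
    cor = pearson_correlation(sub)
    coords = classical_mds(1.0 - cor.to_numpy())
    coords_df = pd.DataFrame(coords, index=present, columns=["x", "y"])
    rows = []
    arr = cor.to_numpy()
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            if arr[i, j] >= edge_cor_min:
                rows.append((present[i], present[j], arr[i, j]))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation"])
    return coords_df, edges


def build_interaction_network(
    modules: GeneModuleSet,
    annotation: CellTypeAnnotation,
    lr_db: LRDatabase,
    cell_types=None,
) -> InteractionMap:
    """Directed cell-type interaction edges from module-annotated LR genes.

    Autocrine (s == t) edges land on the diagonal.  Unassigned genes and
    unannotated modules contribute nothing.  ``cell_types`` fixes the
    count-matrix axes; default is the sorted annotated types.
    """
    assignment = modules.assignment
    if cell_types is None:
        cell_types = sorted(
            {ct for ct in annotation.labels.values() if ct != UNANNOTATED}
        )
    rows = []
    for lig, rec in lr_db.pairs:
        ml = assignment.get(lig, UNASSIGNED)
        mr = assignment.get(rec, UNASSIGNED)
        if ml == UNASSIGNED or mr == UNASSIGNED:
            continue
        s, t = annotation[ml], annotation[mr]
        if s == UNANNOTATED or t == UNANNOTATED:
            continue
        rows.append((lig, rec, s, t))
    edges = pd.DataFrame(rows, columns=["ligand", "receptor", "source", "target"])
    counts = pd.DataFrame(0, index=cell_types, columns=cell_types, dtype=int)
    for _, e in edges.iterrows():
        counts.loc[e["source"], e["target"]] += 1
    return InteractionMap(edges=edges, counts=counts)


def rank_interacting_cell_types(counts: pd.DataFrame) -> pd.Series:
    """Cell types by total degree (in + out), descending, ties by name."""
    if counts.shape[0] != counts.shape[1]:
        raise ValueError("counts matrix must be square")
    degree = counts.sum(axis=1) + counts.sum(axis=0)
    order = sorted(degree.index, key=lambda ct: (-degree[ct], str(ct)))
    return degree.loc[order]


def enrichment_test(
    query,
    annotation_sets: dict,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``query`` in each set.

    Upper-tail p-value P(overlap >= observed) on the 2x2 table of query
    vs set within the universe (equivalent to one-sided Fisher's exact),
    Benjamini-Hochberg adjusted across sets.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    names, overlaps, pvals, set_sizes = [], [], [], []
    for name, genes in annotation_sets.items():
        genes = set(genes) & universe
        k = len(query & genes)
        # P(X >= k), X ~ Hypergeom(M=|universe|, n=|set|, N=|query|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(genes), len(query)))
        names.append(name)
        overlaps.append(k)
        set_sizes.append(len(genes))
        pvals.append(min(p, 1.0))
    adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    out = pd.DataFrame(
        {
            "set": names,
            "set_size": set_sizes,
            "overlap": overlaps,
            "p_value": pvals,
            "adjusted_p": adj,
        }
    )
    out["significant"] = out["adjusted_p"] < alpha
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
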