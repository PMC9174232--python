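"""Readers and writers for the on-disk interchange formats.

TSV is the canonical format (genes as rows everywhere); sparse input is
supported as matrix-market triplets with ``genes.tsv`` / ``barcodes.tsv``
siblings.  All writers use a fixed column order, ``\\n`` line endings and
a fixed float format so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, ProteomeTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_lr_database",
    "write_lr_database",
    "read_proteome",
    "write_proteome",
    "write_table",
    "write_truth",
]

FLOAT_FORMAT = "%.10g"


def _check_nonnegative(values: pd.DataFrame, path) -> None:
    arr = values.to_numpy()
    if arr.size and arr.min() < 0:
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative entry at row {values.index[r]!r}, "
            f"column {values.columns[c]!r}"
        )


def read_expression(path, fmt: str | None = None, meta_path=None) -> ExpressionMatrix:
    """Read a gene x cell matrix from TSV or matrix-market triplets.

    For ``fmt="mtx"`` the matrix file needs ``genes.tsv`` and
    ``barcodes.tsv`` siblings (one id per line).  ``meta_path`` may
    point to a TSV of per-cell metadata indexed by cell id.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        values = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx":
        genes_file = path.parent / "genes.tsv"
        barcodes_file = path.parent / "barcodes.tsv"
        for f in (genes_file, barcodes_file):
            if not f.exists():
                raise FileNotFoundError(f"expected sibling file {f}")
        mat = spio.mmread(path)
        genes = genes_file.read_text().splitlines()
        cells = barcodes_file.read_text().splitlines()
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"{genes_file}: {len(genes)} gene ids for {mat.shape[0]} matrix rows"
            )
        if mat.shape[1] != len(cells):
            raise ValueError(
                f"{barcodes_file}: {len(cells)} cell ids for {mat.shape[1]} matrix columns"
            )
        values = pd.DataFrame(np.asarray(mat.todense()), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _check_nonnegative(values, path)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression(X: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        X.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(X.values.to_numpy()))
        (path.parent / "genes.tsv").write_text("\n".join(X.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(X.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(X.cell_meta.columns):
        X.cell_meta.to_csv(
            path.with_suffix(".meta.tsv"), sep="\t", lineterminator="\n"
        )


def read_lr_database(path):
    from .communication import LRDatabase

    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'ligand' and 'receptor'")
    return LRDatabase(list(zip(df["ligand"].astype(str), df["receptor"].astype(str))))


def write_lr_database(db, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    db.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_proteome(path) -> ProteomeTable:
    """Protein x sample TSV whose first row (index 'group') carries labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.index:
        raise ValueError(f"{path}: expected a 'group' row with sample labels")
    groups = df.loc["group"]
    values = df.drop(index="group").astype(float)
    return ProteomeTable(values, groups)


def write_proteome(table: ProteomeTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = pd.concat([table.groups.rename("group").to_frame().T, table.values])
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write any result table with the package's stable formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def write_truth(truth, path) -> None:
    """Serialize a SyntheticTruth to JSON."""
    payload = {
        "gene_module": {g: m for g, m in truth.gene_module.items()},
        "cell_type": {c: t for c, t in truth.cell_type.items()},
        "marker_genes": truth.marker_genes,
        "lr_pairs": [
            {"ligand": p.ligand, "receptor": p.receptor, "source": p.source, "target": p.target}
            for p in truth.lr_pairs
        ],
        "module_activity": {
            m: [round(float(v), 10) for v in row]
            for m, row in truth.module_activity.iterrows()
        },
        "pseudotime": (
            None
            if truth.pseudotime is None
            else {c: round(float(v), 10) for c, v in truth.pseudotime.items()}
        ),
        "lineage": (
            None
            if truth.lineage is None
            else {c: int(v) for c, v in truth.lineage.items()}
        ),
        "branch_point": truth.branch_point,
        "biomarker_effects": truth.biomarker_effects,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
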