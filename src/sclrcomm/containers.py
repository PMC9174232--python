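"""Core in-memory containers shared across the pipeline.

The canonical orientation everywhere in this package is genes (or
proteins) as rows and cells (or samples) as columns, matching the usual
layout of FPKM/RPKM tables produced by full-length scRNA-seq pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ProteomeTable"]


@dataclass
class ExpressionMatrix:
    """Gene x cell non-negative expression with per-cell metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_cells); index are unique gene ids,
        columns are unique cell ids; entries must be non-negative
        (FPKM/RPKM-like or normalized counts).
    cell_meta
        DataFrame indexed by cell id, aligned with ``values.columns``.
        Conventional columns are ``condition``, ``genotype`` and an
        optional ``cell_type``.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.values.columns)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate cell ids: {list(dupes[:5])}")
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            r, c = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.values.index[r]!r}, "
                f"cell {self.values.columns[c]!r}"
            )
        if not self.cell_meta.index.equals(self.values.columns):
            missing = self.values.columns.difference(self.cell_meta.index)
            if len(missing):
                raise ValueError(f"cell_meta missing cells: {list(missing[:5])}")
            self.cell_meta = self.cell_meta.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, cells], self.cell_meta.loc[cells])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.cell_meta)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.cell_meta.copy())


@dataclass
class ProteomeTable:
    """Protein x sample measurement table with a group label per sample."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(self.groups)
        if not self.groups.index.equals(self.values.columns):
            missing = self.values.columns.difference(self.groups.index)
            if len(missing):
                raise ValueError(f"group labels missing samples: {list(missing[:5])}")
            self.groups = self.groups.loc[self.values.columns]

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group_names) -> pd.Index:
        names = {group_names} if isinstance(group_names, str) else set(group_names)
        mask = self.groups.isin(names)
        return self.samples[mask.to_numpy()]
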