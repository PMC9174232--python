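import numpy as np
import pandas as pd
import pytest

from sclrcomm.containers import ExpressionMatrix


def make_matrix(vals, gene_ids=None, cell_ids=None, meta=None) -> ExpressionMatrix:
    vals = np.asarray(vals, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(vals.shape[0])]
    cells = cell_ids or [f"c{j}" for j in range(vals.shape[1])]
    if meta is None:
        meta = pd.DataFrame(index=cells)
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=cells),
        cell_meta=meta,
    )


@pytest.fixture
def tiny_matrix():
    return make_matrix(
        [[0.0, 1.0, 2.0], [3.0, 0.0, 1.0], [5.0, 5.0, 5.0], [0.0, 0.0, 4.0]]
    )


@pytest.fixture
def blocks_matrix():
    """Two clean 20-gene co-expression blocks plus 20 noise genes."""
    rng = np.random.default_rng(7)
    n_cells = 60
    f1 = rng.normal(0, 1, n_cells)
    f2 = rng.normal(0, 1, n_cells)
    rows = []
    for _ in range(20):
        rows.append(5 + 2 * f1 + rng.normal(0, 0.3, n_cells))
    for _ in range(20):
        rows.append(5 + 2 * f2 + rng.normal(0, 0.3, n_cells))
    for _ in range(20):
        rows.append(5 + rng.normal(0, 1, n_cells))
    vals = np.clip(np.array(rows), 0, None)
    return make_matrix(vals)
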