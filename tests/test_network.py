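import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclrcomm import network as net
from sclrcomm import preprocess as pp
from sclrcomm import synthetic as syn

from conftest import make_matrix


def brute_force_tom(A):
    """Independent oracle: literal triple-sum TOM definition."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A0[i, u] * A0[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + A0[i, j]) / (min(k[i], k[j]) + 1.0 - A0[i, j])
    return tom


def random_adjacency(rng, n):
    c = rng.uniform(-1, 1, size=(n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return net.signed_adjacency(c, beta=int(rng.integers(1, 9)))


# ----------------------------------------------------------------- adjacency


def test_signed_adjacency_closed_forms():
    for beta in (1, 3, 6):
        c = np.array([[1.0, -1.0, 0.0], [-1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        a = net.signed_adjacency(c, beta)
        assert a[0, 1] == pytest.approx(0.0, abs=1e-15)
        assert a[0, 2] == pytest.approx(0.5 ** beta, abs=1e-15)
        assert a[1, 2] == pytest.approx(1.0, abs=1e-15)
        assert np.allclose(np.diag(a), 1.0)


def test_signed_adjacency_rejects_bad_inputs():
    with pytest.raises(ValueError):
        net.signed_adjacency(np.array([[1.0, 0.5], [0.2, 1.0]]), 6)
    with pytest.raises(ValueError):
        net.signed_adjacency(np.array([[1.0, 2.0], [2.0, 1.0]]), 6)
    with pytest.raises(ValueError):
        net.signed_adjacency(np.eye(2), 0)


@given(st.integers(0, 10_000), st.integers(2, 6))
@settings(max_examples=30, deadline=None)
def test_adjacency_range_and_monotonicity(seed, n):
    rng = np.random.default_rng(seed)
    c = rng.uniform(-1, 1, size=(n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    a1 = net.signed_adjacency(c, 2)
    a2 = net.signed_adjacency(c, 6)
    assert np.all((a1 >= 0) & (a1 <= 1))
    # larger beta shrinks every off-diagonal weight
    off = ~np.eye(n, dtype=bool)
    assert np.all(a2[off] <= a1[off] + 1e-15)


# ----------------------------------------------------------------------- TOM


def test_tom_equal_adjacency_three_nodes():
    # 3 nodes, all off-diagonal adjacency 0.5:
    # l = 0.25, k = 1, tom = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
    A = np.full((3, 3), 0.5)
    np.fill_diagonal(A, 1.0)
    tom = net.topological_overlap(A)
    off = ~np.eye(3, dtype=bool)
    assert np.allclose(tom[off], 0.5, atol=1e-15)


def test_tom_matches_brute_force_small():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 7))
        A = random_adjacency(rng, n)
        assert np.max(np.abs(net.topological_overlap(A) - brute_force_tom(A))) < 1e-12


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_tom_symmetric_unit_interval(seed):
    rng = np.random.default_rng(seed)
    A = random_adjacency(rng, int(rng.integers(3, 12)))
    tom = net.topological_overlap(A)
    assert np.allclose(tom, tom.T, atol=1e-12)
    assert np.all((tom >= 0) & (tom <= 1 + 1e-12))
    assert np.allclose(np.diag(tom), 1.0)


def test_tom_keeps_dataframe_labels():
    A = pd.DataFrame(
        np.array([[1.0, 0.5], [0.5, 1.0]]), index=["a", "b"], columns=["a", "b"]
    )
    tom = net.topological_overlap(A)
    assert list(tom.index) == ["a", "b"]


# --------------------------------------------------------------- correlation


def test_pearson_constant_gene_zeroed():
    X = make_matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    cor = net.pearson_correlation(X)
    assert cor.loc["g0", "g1"] == 0.0
    assert cor.loc["g1", "g1"] == 1.0


def test_pearson_rounding_jitter_treated_as_constant():
    base = np.exp(2.0)
    jitter = base * np.array([0.0, 1e-16, -1e-16, 2e-16])
    X = make_matrix([base + jitter, [1.0, 2.0, 3.0, 4.0]])
    cor = net.pearson_correlation(X)
    assert cor.loc["g0", "g1"] == 0.0


# ----------------------------------------------------------- soft threshold


def test_pick_soft_threshold_contract(blocks_matrix):
    res = net.pick_soft_threshold(blocks_matrix)
    assert res.beta in range(1, 21)
    assert set(res.fit_table.columns) >= {
        "power",
        "r2_signed",
        "slope",
        "mean_connectivity",
    }
    assert len(res.fit_table) == 20
    # connectivity shrinks monotonically with the power
    mc = res.fit_table["mean_connectivity"].to_numpy()
    assert np.all(np.diff(mc) <= 1e-12)


def test_pick_soft_threshold_prefers_smallest_reaching_target(blocks_matrix):
    res = net.pick_soft_threshold(blocks_matrix, r2_target=0.0)
    tab = res.fit_table.set_index("power")
    first = next(p for p in tab.index if tab.loc[p, "r2_signed"] >= 0.0)
    assert res.beta == first
    assert res.target_reached


# ----------------------------------------------------------- module detection


def _network_modules(X, beta=6, **kwargs):
    cor = net.pearson_correlation(X)
    tom = net.topological_overlap(net.signed_adjacency(cor, beta))
    return net.detect_modules(tom, expression=X, **kwargs)


def test_detect_modules_two_blocks(blocks_matrix):
    mods = _network_modules(blocks_matrix, min_size=10)
    assign = mods.assignment
    first = assign.iloc[:20]
    second = assign.iloc[20:40]
    noise = assign.iloc[40:]
    assert first.nunique() == 1 and first.iloc[0] != net.UNASSIGNED
    assert second.nunique() == 1 and second.iloc[0] != net.UNASSIGNED
    assert first.iloc[0] != second.iloc[0]
    assert (noise == net.UNASSIGNED).mean() >= 0.9


def test_detect_modules_pure_noise_unassigned():
    rng = np.random.default_rng(3)
    X = make_matrix(np.abs(rng.normal(0, 1, size=(120, 60))))
    mods = _network_modules(X, min_size=10)
    assert (mods.assignment == net.UNASSIGNED).mean() >= 0.9


def test_detect_modules_min_size_validation(blocks_matrix):
    cor = net.pearson_correlation(blocks_matrix)
    tom = net.topological_overlap(net.signed_adjacency(cor, 6))
    with pytest.raises(ValueError):
        net.detect_modules(tom, min_size=1)


def test_detect_modules_constant_genes_unassigned(blocks_matrix):
    vals = blocks_matrix.values.copy()
    vals.iloc[40:45] = 7.0  # make five noise genes exactly constant
    X = make_matrix(vals.to_numpy())
    mods = _network_modules(X, min_size=10)
    assert (mods.assignment.iloc[40:45] == net.UNASSIGNED).all()


def test_small_module_absorbed_into_neighbour():
    cfg = syn.SyntheticConfig(
        n_genes=160,
        n_cells=120,
        modules=[syn.ModuleSpec(50), syn.ModuleSpec(10)],
        cell_types=[
            syn.CellTypeSpec("A", 60, active_modules=("M1", "M2")),
            syn.CellTypeSpec("B", 60, active_modules=("M2",)),
        ],
        noise_sd=0.3,
        seed=0,
    )
    X, truth = syn.generate_expression(cfg)
    X = pp.log_transform(X)
    mods = _network_modules(X)  # min_size 30 default
    small_genes = truth.gene_module[truth.gene_module == "M2"].index
    landed = set(mods.assignment.reindex(small_genes))
    assert net.UNASSIGNED not in landed or len(landed) > 1 or not landed
    sizes = mods.assignment[mods.assignment != net.UNASSIGNED].value_counts()
    assert (sizes >= 30).all()


# ------------------------------------------------------ eigengenes/membership


def test_eigengene_unit_variance_and_orientation(blocks_matrix):
    assign = pd.Series(
        ["M1"] * 20 + ["M2"] * 20 + [net.UNASSIGNED] * 20,
        index=blocks_matrix.gene_ids,
    )
    me = net.module_eigengenes(blocks_matrix, assign)
    assert list(me.index) == ["M1", "M2"]
    assert np.allclose(me.std(axis=1, ddof=0), 1.0)
    # oriented with member genes: mean correlation positive
    for m, genes in (("M1", blocks_matrix.gene_ids[:20]),):
        cors = [
            np.corrcoef(blocks_matrix.values.loc[g], me.loc[m])[0, 1] for g in genes
        ]
        assert np.mean(cors) > 0


def test_eigengene_requires_two_genes(blocks_matrix):
    assign = pd.Series(net.UNASSIGNED, index=blocks_matrix.gene_ids)
    assign.iloc[0] = "M1"
    with pytest.raises(ValueError):
        net.module_eigengenes(blocks_matrix, assign)


def test_membership_is_gene_eigengene_correlation(blocks_matrix):
    assign = pd.Series(
        ["M1"] * 20 + ["M2"] * 20 + [net.UNASSIGNED] * 20,
        index=blocks_matrix.gene_ids,
    )
    me = net.module_eigengenes(blocks_matrix, assign)
    mm, constant = net.module_membership(blocks_matrix, me)
    g = blocks_matrix.gene_ids[0]
    expected = np.corrcoef(blocks_matrix.values.loc[g], me.loc["M1"])[0, 1]
    assert mm.loc[g, "M1"] == pytest.approx(expected, abs=1e-12)
    assert not constant.any()


def test_top_module_genes_order_and_ties(blocks_matrix):
    assign = pd.Series(
        ["M1"] * 20 + ["M2"] * 20 + [net.UNASSIGNED] * 20,
        index=blocks_matrix.gene_ids,
    )
    me = net.module_eigengenes(blocks_matrix, assign)
    mm, _ = net.module_membership(blocks_matrix, me)
    top = net.top_module_genes(mm, "M1", k=5)
    vals = mm.loc[top.index, "M1"].to_numpy()
    assert np.allclose(top.to_numpy(), vals)
    assert np.all(np.diff(vals) <= 1e-12)
    assert set(top.index) <= set(blocks_matrix.gene_ids[:20])
    # k larger than the module is fine
    assert len(net.top_module_genes(mm, "M1", k=100)) == 60
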