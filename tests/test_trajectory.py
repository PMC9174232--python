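import numpy as np
import pandas as pd
import pytest

from sclrcomm import trajectory as traj

from conftest import make_matrix


def blob_coords(centers, n_per, sd=0.15, seed=0):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, sd, size=(n_per, 2)))
        labels += [i] * n_per
    coords = pd.DataFrame(
        np.vstack(pts), columns=["x", "y"],
        index=[f"c{j}" for j in range(n_per * len(centers))],
    )
    return coords, np.array(labels)


# ------------------------------------------------------------------ embedding


def test_embed_cells_deterministic_and_shaped():
    rng = np.random.default_rng(0)
    X = make_matrix(np.abs(rng.normal(5, 1, size=(30, 25))))
    e1 = traj.embed_cells(X, n_neighbors=5)
    e2 = traj.embed_cells(X, n_neighbors=5)
    assert e1.equals(e2)
    assert list(e1.columns) == ["x", "y"]
    assert list(e1.index) == list(X.cell_ids)


def test_embed_cells_separates_groups():
    rng = np.random.default_rng(1)
    a = rng.normal(2, 0.2, size=(20, 15))
    b = rng.normal(8, 0.2, size=(20, 15))
    X = make_matrix(np.hstack([a, b]))
    coords = traj.embed_cells(X, n_neighbors=5)
    da = coords.iloc[:15].mean()
    db = coords.iloc[15:].mean()
    within = coords.iloc[:15].std().max()
    assert np.linalg.norm(da - db) > 3 * within


def test_embed_cells_validation():
    X = make_matrix([[1.0], [2.0]])
    with pytest.raises(ValueError, match="2 cells"):
        traj.embed_cells(X)
    X = make_matrix(np.ones((3, 5)) + np.arange(5))
    with pytest.raises(ValueError, match="n_neighbors"):
        traj.embed_cells(X, n_neighbors=5)
    with pytest.raises(ValueError, match="unknown embedding"):
        traj.embed_cells(X, n_neighbors=2, method="tsne")


# ----------------------------------------------------------------- clustering


def test_cluster_snn_separated_blobs():
    coords, truth = blob_coords([(0, 0), (10, 0), (5, 10)], n_per=20)
    labels = traj.cluster_snn(coords, k=12)
    assert labels.nunique() == 3
    # perfect agreement up to label permutation
    for t in range(3):
        assert labels[truth == t].nunique() == 1
    # labels renumbered by size: all same size here, so {1, 2, 3}
    assert set(labels) == {1, 2, 3}


def test_cluster_snn_label_one_is_largest():
    coords, _ = blob_coords([(0, 0), (10, 0)], n_per=10)
    coords = coords.iloc[:-4]  # shrink the second blob
    labels = traj.cluster_snn(coords, k=4)
    sizes = labels.value_counts()
    assert sizes.idxmax() == 1


def test_cluster_snn_validation():
    coords, _ = blob_coords([(0, 0)], n_per=5)
    with pytest.raises(ValueError):
        traj.cluster_snn(coords, k=0)
    with pytest.raises(ValueError):
        traj.cluster_snn(coords, k=5)


# ------------------------------------------------------------------- lineages


def test_infer_lineages_chain():
    # centroids on a line: single lineage root -> far end
    coords, truth = blob_coords([(0, 0), (5, 0), (10, 0)], n_per=15, sd=0.1)
    labels = pd.Series(truth + 1, index=coords.index)
    lineages = traj.infer_lineages(coords, labels, root=1)
    assert lineages == [[1, 2, 3]]


def test_infer_lineages_star():
    # root centre, two arms -> two lineages sharing the root
    coords, truth = blob_coords(
        [(0, 0), (10, 0), (0, 10)], n_per=15, sd=0.1
    )
    labels = pd.Series(truth + 1, index=coords.index)
    lineages = traj.infer_lineages(coords, labels, root=1)
    assert sorted(map(tuple, lineages)) == [(1, 2), (1, 3)]


def test_infer_lineages_unknown_root():
    coords, truth = blob_coords([(0, 0), (5, 0)], n_per=5)
    labels = pd.Series(truth + 1, index=coords.index)
    with pytest.raises(ValueError, match="root"):
        traj.infer_lineages(coords, labels, root=9)


# ----------------------------------------------------------------- pseudotime


def test_pseudotime_is_arc_length_on_a_line():
    # cells exactly on the segment from (0,0) to (10,0)
    xs = np.array([0.0, 2.5, 5.0, 7.5, 10.0])
    coords = pd.DataFrame(
        {"x": xs, "y": 0.0}, index=[f"c{i}" for i in range(5)]
    )
    labels = pd.Series([1, 1, 1, 2, 2], index=coords.index)
    pt = traj.compute_pseudotime(coords, [1, 2], labels)
    cent1, cent2 = xs[:3].mean(), xs[3:].mean()  # 2.5 and 8.75
    expected = np.clip((xs - cent1) / (cent2 - cent1), 0, 1)
    assert np.allclose(pt.to_numpy(), expected, atol=1e-12)


def test_pseudotime_off_lineage_cells_excluded():
    coords = pd.DataFrame(
        {"x": [0.0, 1.0, 2.0, 50.0], "y": 0.0},
        index=["a", "b", "c", "d"],
    )
    labels = pd.Series([1, 1, 2, 3], index=coords.index)
    pt = traj.compute_pseudotime(coords, [1, 2], labels)
    assert list(pt.index) == ["a", "b", "c"]
    with pytest.raises(ValueError, match="unknown clusters"):
        traj.compute_pseudotime(coords, [1, 9], labels)
    with pytest.raises(ValueError, match="empty"):
        traj.compute_pseudotime(coords, [], labels)


# ------------------------------------------------------------------- dynamics


def _dyn(y_fn, n=200, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, n)
    cells = [f"c{i}" for i in range(n)]
    pt = pd.Series(t, index=cells)
    eg = pd.Series(y_fn(t), index=cells)
    return traj.module_dynamics(eg, pt, seed=1)


def test_module_dynamics_directions():
    up = _dyn(lambda t: 2 * t)
    down = _dyn(lambda t: -2 * t)
    flat = _dyn(lambda t: np.full_like(t, 3.0))  # no trend at all
    assert up.direction == "increasing" and up.endpoint_diff > 0.9
    assert down.direction == "decreasing" and down.endpoint_diff < -0.9
    assert flat.direction == "non-monotone"
    assert up.p_value < 0.05 <= flat.p_value


def test_module_dynamics_validation():
    pt = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
    eg = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="5 cells"):
        traj.module_dynamics(eg, pt)
    pt = pd.Series(np.linspace(0, 1, 10), index=[f"c{i}" for i in range(10)])
    eg = pd.Series(np.arange(10.0), index=pt.index)
    with pytest.raises(ValueError, match="span"):
        traj.module_dynamics(eg, pt, span=0.0)


# ---------------------------------------------------------------- exclusivity


def test_module_exclusivity_closed_cases():
    cells = [f"c{i}" for i in range(50)]
    rng = np.random.default_rng(2)
    a = rng.normal(size=50)
    eg = pd.DataFrame(
        [a, -a, rng.normal(size=50)], index=["M1", "M2", "M3"], columns=cells
    )
    cor, flag = traj.module_exclusivity(eg, "M1", "M2")
    assert cor == pytest.approx(-1.0, abs=1e-12)
    assert flag
    cor_self, flag_self = traj.module_exclusivity(eg, "M1", "M1")
    assert cor_self == pytest.approx(1.0) and not flag_self
    with pytest.raises(KeyError):
        traj.module_exclusivity(eg, "M1", "M9")
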