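import numpy as np
import pandas as pd
import pytest

from sclrcomm import synthetic as syn


def base_config(**kwargs):
    defaults = dict(
        n_genes=120,
        n_cells=80,
        modules=[syn.ModuleSpec(20), syn.ModuleSpec(20)],
        cell_types=[
            syn.CellTypeSpec("A", 40, marker_genes=3, active_modules=("M1",)),
            syn.CellTypeSpec("B", 40, marker_genes=3, active_modules=("M2",)),
        ],
        noise_sd=0.3,
        seed=0,
    )
    defaults.update(kwargs)
    return syn.SyntheticConfig(**defaults)


def test_generation_is_reproducible():
    X1, t1 = syn.generate_expression(base_config())
    X2, t2 = syn.generate_expression(base_config())
    assert X1.values.equals(X2.values)
    assert t1.gene_module.equals(t2.gene_module)
    assert t1.module_activity.equals(t2.module_activity)


def test_seed_changes_values():
    X1, _ = syn.generate_expression(base_config(seed=0))
    X2, _ = syn.generate_expression(base_config(seed=1))
    assert not X1.values.equals(X2.values)


def test_layout_partition():
    X, truth = syn.generate_expression(base_config())
    mods = truth.module_genes()
    assert sorted(mods) == ["M1", "M2"]
    assert len(mods["M1"]) == 20 and len(mods["M2"]) == 20
    # modules, markers disjoint; remainder background
    marker = {g for gs in truth.marker_genes.values() for g in gs}
    module = {g for gs in mods.values() for g in gs}
    assert not marker & module
    assert len(marker) == 6
    assert truth.cell_type.value_counts().to_dict() == {"A": 40, "B": 40}
    assert X.n_genes == 120 and X.n_cells == 80
    assert (X.values.to_numpy() >= 0).all()


def test_marker_genes_elevated_in_their_type():
    X, truth = syn.generate_expression(base_config(noise_sd=0.0))
    in_a = truth.cell_type == "A"
    for g in truth.marker_genes["A"]:
        row = X.values.loc[g]
        assert row[in_a.to_numpy()].mean() > row[~in_a.to_numpy()].mean()


def test_validation_errors():
    with pytest.raises(ValueError, match="n_cells"):
        syn.generate_expression(base_config(n_cells=0))
    with pytest.raises(ValueError, match="noise_sd"):
        syn.generate_expression(base_config(noise_sd=-0.1))
    with pytest.raises(ValueError, match="exceed n_genes"):
        syn.generate_expression(base_config(n_genes=30))
    with pytest.raises(ValueError, match="sum to"):
        cfg = base_config()
        cfg.cell_types[0].n_cells = 10
        syn.generate_expression(cfg)
    with pytest.raises(ValueError, match="unknown active modules"):
        cfg = base_config()
        cfg.cell_types[0].active_modules = ("M9",)
        syn.generate_expression(cfg)


def test_lr_plan_planted_pairs():
    cfg = base_config(
        lr_plan=[syn.LRPlanEntry("A", "B", 3), syn.LRPlanEntry("B", "A", 1)]
    )
    _, truth = syn.generate_expression(cfg)
    counts = truth.lr_count_matrix()
    assert counts.loc["A", "B"] == 3
    assert counts.loc["B", "A"] == 1
    m1 = set(truth.module_genes()["M1"])
    m2 = set(truth.module_genes()["M2"])
    for p in truth.lr_pairs:
        src_pool = m1 if p.source == "A" else m2
        tgt_pool = m1 if p.target == "A" else m2
        assert p.ligand in src_pool and p.receptor in tgt_pool
    # pairs are unique
    assert len({(p.ligand, p.receptor) for p in truth.lr_pairs}) == 4


def test_lr_plan_requires_active_modules():
    cfg = base_config(lr_plan=[syn.LRPlanEntry("A", "B", 1)])
    cfg.cell_types[1].active_modules = ()
    with pytest.raises(ValueError, match="no active modules"):
        syn.generate_expression(cfg)


def test_lr_database_decoys_from_background_only():
    _, truth = syn.generate_expression(
        base_config(lr_plan=[syn.LRPlanEntry("A", "B", 2)])
    )
    db = syn.generate_lr_database(truth, n_decoys=5, seed=3)
    assert len(db) == 7
    planted = {(p.ligand, p.receptor) for p in truth.lr_pairs}
    marker = {g for gs in truth.marker_genes.values() for g in gs}
    decoys = [pair for pair in db.pairs if pair not in planted]
    assert len(decoys) == 5
    for lig, rec in decoys:
        assert truth.gene_module[lig] is None and truth.gene_module[rec] is None
        assert lig not in marker and rec not in marker


def test_lr_database_zero_decoys_is_exactly_planted():
    _, truth = syn.generate_expression(
        base_config(lr_plan=[syn.LRPlanEntry("A", "B", 2)])
    )
    db = syn.generate_lr_database(truth, n_decoys=0, seed=0)
    assert db.pairs == [(p.ligand, p.receptor) for p in truth.lr_pairs]


def test_lr_database_pool_exhaustion_error():
    _, truth = syn.generate_expression(
        base_config(lr_plan=[syn.LRPlanEntry("A", "B", 1)])
    )
    with pytest.raises(ValueError, match="decoy"):
        syn.generate_lr_database(truth, n_decoys=10_000, seed=0)


def test_trajectory_zero_noise_monotone():
    cfg = base_config(
        cell_types=[],
        modules=[syn.ModuleSpec(20), syn.ModuleSpec(20)],
        noise_sd=0.0,
        trajectory=syn.TrajectorySpec(
            n_lineages=1, modules_up=("M1",), modules_down=("M2",)
        ),
    )
    X, truth = syn.generate_trajectory_dataset(cfg)
    t = truth.pseudotime
    order = t.sort_values().index
    up_gene = truth.module_genes()["M1"][0]
    down_gene = truth.module_genes()["M2"][0]
    up = X.values.loc[up_gene, order].to_numpy()
    down = X.values.loc[down_gene, order].to_numpy()
    assert np.all(np.diff(up) >= -1e-9)
    assert np.all(np.diff(down) <= 1e-9)
    assert truth.lineage.nunique() == 1
    assert truth.branch_point is None


def test_trajectory_two_lineages_diverge_after_branch():
    cfg = base_config(
        cell_types=[],
        modules=[syn.ModuleSpec(20), syn.ModuleSpec(20)],
        noise_sd=0.0,
        trajectory=syn.TrajectorySpec(
            n_lineages=2, modules_up=("M1",), modules_down=("M2",), branch_point=0.5
        ),
    )
    X, truth = syn.generate_trajectory_dataset(cfg)
    act = truth.module_activity
    late = truth.pseudotime > 0.8
    l1 = (truth.lineage == 1) & late
    l2 = (truth.lineage == 2) & late
    assert l1.any() and l2.any()
    # lineage 1 carries the up-program past the branch, lineage 2 the down-program
    assert act.loc["M1", l1.to_numpy()].mean() > act.loc["M1", l2.to_numpy()].mean()
    assert act.loc["M2", l2.to_numpy()].mean() < act.loc["M2", l1.to_numpy()].mean()
    assert set(X.cell_meta["condition"].unique()) <= {"control", "case"}


def test_trajectory_validation():
    cfg = base_config(
        cell_types=[], trajectory=syn.TrajectorySpec(n_lineages=3)
    )
    with pytest.raises(ValueError, match="n_lineages"):
        syn.generate_trajectory_dataset(cfg)
    cfg = base_config(
        cell_types=[], trajectory=syn.TrajectorySpec(modules_up=("M7",))
    )
    with pytest.raises(ValueError, match="unknown trajectory modules"):
        syn.generate_trajectory_dataset(cfg)
    with pytest.raises(ValueError, match="config.trajectory"):
        syn.generate_trajectory_dataset(base_config(cell_types=[]))


def test_proteome_closed_form_zero_noise():
    table, truth = syn.generate_proteome(
        groups=[("ctrl", 3), ("case", 2)],
        effects={"P1": {"case": 2.0}, "P2": {}},
        noise_sd=0.0,
        seed=0,
        baseline=10.0,
    )
    assert list(table.values.index) == ["P1", "P2"]
    ctrl = table.samples_in(["ctrl"])
    case = table.samples_in(["case"])
    assert np.allclose(table.values.loc["P1", ctrl], 10.0)
    assert np.allclose(table.values.loc["P1", case], 12.0)
    assert np.allclose(table.values.loc["P2"], 10.0)
    assert truth.biomarker_effects == {"P1": {"case": 2.0}, "P2": {}}


def test_proteome_validation():
    with pytest.raises(ValueError, match="two groups"):
        syn.generate_proteome([("a", 3)], {"P": {}}, 0.1, 0)
    with pytest.raises(ValueError, match="protein"):
        syn.generate_proteome([("a", 3), ("b", 3)], {}, 0.1, 0)
    with pytest.raises(ValueError, match="no samples"):
        syn.generate_proteome([("a", 3), ("b", 0)], {"P": {}}, 0.1, 0)


def test_dropout_zeroes_entries():
    X0, _ = syn.generate_expression(base_config(dropout_rate=0.0))
    X5, _ = syn.generate_expression(base_config(dropout_rate=0.5))
    frac0 = (X0.values.to_numpy() == 0).mean()
    frac5 = (X5.values.to_numpy() == 0).mean()
    assert frac5 > frac0 + 0.3
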