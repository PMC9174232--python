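"""End-to-end pipeline: simulate/QC -> network -> communication ->
trajectory -> classification (-> biomarker), with a manifest.

Every stage writes its tables next to the manifest with stable
formatting, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker as bm
from . import classification as cls
from . import communication as comm
from . import io as sio
from . import network as net
from . import preprocess as pp
from . import synthetic as syn
from . import trajectory as traj

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_KNOWN_SECTIONS = {
    "seed",
    "out_dir",
    "synthetic",
    "qc",
    "network",
    "communication",
    "trajectory",
    "classification",
    "biomarker",
}


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters.

    Stage sections are plain dicts with stage defaults applied; unknown
    keys anywhere are rejected at load time.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    synthetic: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    communication: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    biomarker: dict = field(default_factory=dict)

    _DEFAULTS = {
        "qc": {"min_genes": 300, "min_value": 10.0, "min_cells": 1, "log": True},
        "network": {
            "power": "auto",
            "min_size": 30,
            "merge_cor": 0.75,
            "r2_target": 0.85,
        },
        "communication": {"edge_cor_min": 0.5, "n_decoys": 5},
        "trajectory": {"enabled": True, "k": 10, "root": None, "span": 0.3},
        "classification": {"n_trees": 100, "label": "condition"},
        "biomarker": {"enabled": False},
    }

    def __post_init__(self) -> None:
        for section, defaults in self._DEFAULTS.items():
            given = getattr(self, section)
            unknown = set(given) - set(defaults)
            if section == "biomarker":
                unknown -= {"groups", "effects", "noise_sd", "diagnosis", "severity"}
            if section == "synthetic":
                unknown = set()
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            merged = dict(defaults)
            merged.update(given)
            setattr(self, section, merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _synthetic_config(section: dict, seed: int) -> syn.SyntheticConfig:
    spec = dict(section)
    modules = [syn.ModuleSpec(**m) for m in spec.pop("modules", [])]
    cell_types = [syn.CellTypeSpec(**c) for c in spec.pop("cell_types", [])]
    lr_plan = [syn.LRPlanEntry(**e) for e in spec.pop("lr_plan", [])]
    traj_spec = spec.pop("trajectory", None)
    trajectory = syn.TrajectorySpec(**traj_spec) if traj_spec else None
    for key in ("loading_range",):
        for m in modules:
            if isinstance(m.loading_range, list):
                m.loading_range = tuple(m.loading_range)
    return syn.SyntheticConfig(
        modules=modules,
        cell_types=cell_types,
        lr_plan=lr_plan,
        trajectory=trajectory,
        seed=seed,
        **spec,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_root(labels: pd.Series, meta: pd.DataFrame):
    if "condition" not in meta.columns:
        raise ValueError(
            "no trajectory root configured and cell metadata has no "
            "'condition' column to locate a control-dominated cluster"
        )
    frac = (
        (meta["condition"] == "control").groupby(labels).mean().sort_values(
            ascending=False, kind="stable"
        )
    )
    return frac.index[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed}
    written: list[Path] = []

    def emit(stage: str, params: dict, files: dict) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "parameters": params,
                "outputs": {name: str(p.name) for name, p in files.items()},
            }
        )
        written.extend(files.values())

    def fail(stage: str, err: Exception):
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {err} "
            f"(outputs so far: {[p.name for p in written]})"
        ) from err

    # ---- simulate ---------------------------------------------------------
    try:
        scfg = _synthetic_config(config.synthetic, config.seed)
        if scfg.trajectory is not None:
            X, truth = syn.generate_trajectory_dataset(scfg)
        else:
            X, truth = syn.generate_expression(scfg)
        f_expr = out / "expression.tsv"
        f_truth = out / "truth.json"
        sio.write_expression(X, f_expr)
        sio.write_truth(truth, f_truth)
        emit(
            "simulate",
            {"n_genes": scfg.n_genes, "n_cells": scfg.n_cells, "seed": scfg.seed},
            {"expression": f_expr, "truth": f_truth},
        )
    except Exception as err:  # noqa: BLE001
        fail("simulate", err)

    # ---- qc ---------------------------------------------------------------
    try:
        q = config.qc
        Xq = pp.filter_cells_by_detected_genes(X, q["min_genes"])
        Xq = pp.filter_genes_by_expression(Xq, q["min_value"], q["min_cells"])
        Xl = pp.log_transform(Xq) if q["log"] else Xq
        f_qc = out / "expression.qc.tsv"
        sio.write_expression(Xl, f_qc)
        emit("qc", dict(q), {"expression_qc": f_qc})
    except Exception as err:  # noqa: BLE001
        fail("qc", err)

    # ---- network ----------------------------------------------------------
    try:
        ncfg = config.network
        if ncfg["power"] == "auto":
            st = net.pick_soft_threshold(Xl, r2_target=ncfg["r2_target"])
            beta = st.beta
        else:
            beta = int(ncfg["power"])
        cor = net.pearson_correlation(Xl)
        adj = net.signed_adjacency(cor, beta)
        tom = net.topological_overlap(adj)
        modules = net.detect_modules(
            tom,
            min_size=ncfg["min_size"],
            merge_cor=ncfg["merge_cor"],
            expression=Xl,
        )
        me = net.module_eigengenes(Xl, modules.assignment)
        mm, flags = net.module_membership(Xl, me)
        modules.eigengenes, modules.membership = me, mm
        f_assign = out / "module_assignment.tsv"
        f_me = out / "eigengenes.tsv"
        f_mm = out / "membership.tsv"
        sio.write_table(
            modules.assignment.rename("module").rename_axis("gene").reset_index(),
            f_assign,
        )
        sio.write_table(me.rename_axis("module").reset_index(), f_me)
        sio.write_table(mm.rename_axis("gene").reset_index(), f_mm)
        emit(
            "network",
            {"beta": beta, "min_size": ncfg["min_size"], "merge_cor": ncfg["merge_cor"]},
            {"assignment": f_assign, "eigengenes": f_me, "membership": f_mm},
        )
    except Exception as err:  # noqa: BLE001
        fail("network", err)

    # ---- communication ----------------------------------------------------
    try:
        ccfg = config.communication
        lr_db = syn.generate_lr_database(truth, ccfg["n_decoys"], seed=config.seed)
        annotation = comm.annotate_modules(modules, truth.markers_as_sets())
        imap = comm.build_interaction_network(modules, annotation, lr_db)
        ranking = comm.rank_interacting_cell_types(imap.counts)
        f_db = out / "lr_database.tsv"
        f_edges = out / "interaction_edges.tsv"
        f_counts = out / "interaction_counts.tsv"
        f_rank = out / "celltype_ranking.tsv"
        sio.write_lr_database(lr_db, f_db)
        sio.write_table(imap.edges, f_edges)
        sio.write_table(imap.counts.rename_axis("source").reset_index(), f_counts)
        sio.write_table(
            ranking.rename("degree").rename_axis("cell_type").reset_index(), f_rank
        )
        emit(
            "communication",
            {"edge_cor_min": ccfg["edge_cor_min"], "n_decoys": ccfg["n_decoys"]},
            {
                "lr_database": f_db,
                "edges": f_edges,
                "counts": f_counts,
                "ranking": f_rank,
            },
        )
    except Exception as err:  # noqa: BLE001
        fail("communication", err)

    # ---- trajectory -------------------------------------------------------
    dyn_rows = []
    if config.trajectory["enabled"]:
        try:
            tcfg = config.trajectory
            coords = traj.embed_cells(Xl, seed=config.seed)
            labels = traj.cluster_snn(coords, k=tcfg["k"], seed=config.seed)
            root = tcfg["root"]
            if root is None:
                root = _default_root(labels, Xl.cell_meta)
            lineages = traj.infer_lineages(coords, labels, root)
            pt = pd.DataFrame(index=Xl.cell_ids)
            for i, lin in enumerate(lineages, start=1):
                pt[f"lineage_{i}"] = traj.compute_pseudotime(coords, lin, labels)
            for i, lin in enumerate(lineages, start=1):
                series = pt[f"lineage_{i}"].dropna()
                for mod in me.index:
                    dyn = traj.module_dynamics(
                        me.loc[mod],
                        series,
                        span=tcfg["span"],
                        seed=config.seed,
                        n_permutations=200,
                    )
                    dyn_rows.append(
                        (mod, i, dyn.direction, dyn.endpoint_diff, dyn.p_value)
                    )
            f_coords = out / "coords.tsv"
            f_clusters = out / "clusters.tsv"
            f_lineages = out / "lineages.json"
            f_pt = out / "pseudotime.tsv"
            f_dyn = out / "dynamics.tsv"
            sio.write_table(coords.rename_axis("cell").reset_index(), f_coords)
            sio.write_table(labels.rename_axis("cell").reset_index(), f_clusters)
            f_lineages.write_text(
                json.dumps([[int(c) for c in lin] for lin in lineages]) + "\n"
            )
            sio.write_table(pt.rename_axis("cell").reset_index(), f_pt)
            sio.write_table(
                pd.DataFrame(
                    dyn_rows,
                    columns=["module", "lineage", "direction", "endpoint_diff", "p_value"],
                ),
                f_dyn,
            )
            emit(
                "trajectory",
                {"k": tcfg["k"], "root": int(root), "span": tcfg["span"]},
                {
                    "coords": f_coords,
                    "clusters": f_clusters,
                    "lineages": f_lineages,
                    "pseudotime": f_pt,
                    "dynamics": f_dyn,
                },
            )
        except Exception as err:  # noqa: BLE001
            fail("trajectory", err)

    # ---- classification ---------------------------------------------------
    try:
        kcfg = config.classification
        label_col = kcfg["label"]
        if label_col in Xl.cell_meta.columns:
            y = Xl.cell_meta[label_col]
        else:
            y = truth.cell_type.loc[Xl.cell_ids]
        if y.nunique() >= 2:
            res = cls.rank_feature_importance(
                me.T, y, n_trees=kcfg["n_trees"], seed=config.seed
            )
            f_imp = out / "importance.tsv"
            imp = res.importance.rename("mean_decrease_accuracy")
            table = imp.rename_axis("feature").reset_index()
            table["rank"] = np.arange(1, len(table) + 1)
            sio.write_table(table, f_imp)
            emit(
                "classification",
                {"n_trees": kcfg["n_trees"], "oob_accuracy": res.oob_accuracy},
                {"importance": f_imp},
            )
    except Exception as err:  # noqa: BLE001
        fail("classification", err)

    # ---- biomarker (optional) ---------------------------------------------
    if config.biomarker.get("enabled"):
        try:
            bcfg = config.biomarker
            groups = [tuple(g) for g in bcfg["groups"]]
            table, _ = syn.generate_proteome(
                groups,
                bcfg["effects"],
                noise_sd=bcfg.get("noise_sd", 1.0),
                seed=config.seed,
            )
            screen = bm.severity_vs_diagnosis_screen(
                table,
                tuple(bcfg["diagnosis"]),
                tuple(bcfg["severity"]),
            )
            f_prot = out / "proteome.tsv"
            f_screen = out / "biomarker_screen.tsv"
            sio.write_proteome(table, f_prot)
            sio.write_table(screen, f_screen)
            emit(
                "biomarker",
                {"groups": [list(g) for g in groups]},
                {"proteome": f_prot, "screen": f_screen},
            )
        except Exception as err:  # noqa: BLE001
            fail("biomarker", err)

    # ---- manifest ---------------------------------------------------------
    manifest["checksums"] = {p.name: _sha256(p) for p in sorted(set(written))}
    manifest["config"] = config.to_dict()
    (out / "config.resolved.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
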