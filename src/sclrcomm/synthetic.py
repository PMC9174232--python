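"""Synthetic expression, ligand-receptor, trajectory and proteome generators.

Every generator plants a known ground truth (module membership, cell
types, LR pairs, pseudotime, biomarker effect sizes) and returns it
alongside the data, so that each downstream stage of the pipeline can be
tested as a recovery problem.

The expression model is a log-normal latent-factor model: for gene g and
cell c,

    x_gc = max(exp(b_g + sum_m w_gm a_mc + s_g 1[marker] + e_gc) - 1, 0)

with per-gene baseline b_g, module loadings w_gm (non-zero only for the
module the gene belongs to), per-cell module activities a_mc, a
cell-type marker shift, and i.i.d. Gaussian noise e_gc, followed by
independent Bernoulli dropout.  Continuous FPKM/RPKM-like values are
what the correlation-based network machinery downstream consumes, which
is why a count model is not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProteomeTable

__all__ = [
    "ModuleSpec",
    "CellTypeSpec",
    "TrajectorySpec",
    "LRPlanEntry",
    "SyntheticConfig",
    "LRPairTruth",
    "SyntheticTruth",
    "generate_expression",
    "generate_trajectory_dataset",
    "generate_lr_database",
    "generate_proteome",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``activity_sd`` is the SD of the module activity across cells (the
    latent factor), ``loading_range`` the uniform range gene loadings
    are drawn from.
    """

    size: int
    activity_sd: float = 1.0
    loading_range: tuple[float, float] = (0.8, 1.2)


@dataclass
class CellTypeSpec:
    name: str
    n_cells: int
    marker_genes: int = 0
    active_modules: tuple = ()


@dataclass
class TrajectorySpec:
    """One- or two-branch latent trajectory.

    Modules listed in ``modules_up`` rise (and ``modules_down`` fall)
    with pseudotime.  With two lineages both branches share the program
    up to ``branch_point``; afterwards the up-modules keep rising only
    on lineage 1 and the down-modules keep falling only on lineage 2, so
    the branches diverge in orthogonal directions of module space.
    """

    n_lineages: int = 1
    modules_up: tuple = ()
    modules_down: tuple = ()
    branch_point: float = 0.5
    slope: float = 2.0


@dataclass
class LRPlanEntry:
    """Request ``n_pairs`` ligand->receptor pairs from a module active in
    ``source`` cell type to a module active in ``target`` cell type."""

    source: str
    target: str
    n_pairs: int


@dataclass
class SyntheticConfig:
    n_genes: int
    n_cells: int
    modules: Sequence[ModuleSpec] = ()
    cell_types: Sequence[CellTypeSpec] = ()
    noise_sd: float = 0.5
    trajectory: Optional[TrajectorySpec] = None
    dropout_rate: float = 0.0
    seed: int = 0
    lr_plan: Sequence[LRPlanEntry] = ()
    baseline_mean: float = 2.0
    baseline_sd: float = 0.3
    marker_shift: float = 2.0
    active_shift: float = 2.0

    def module_ids(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.modules))]

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        sizes = sum(m.size for m in self.modules)
        n_markers = sum(ct.marker_genes for ct in self.cell_types)
        if sizes + n_markers > self.n_genes:
            raise ValueError(
                f"module sizes ({sizes}) plus marker genes ({n_markers}) "
                f"exceed n_genes ({self.n_genes})"
            )
        for m in self.modules:
            if m.activity_sd < 0:
                raise ValueError("activity_sd must be non-negative")
            if m.size < 1:
                raise ValueError("module size must be >= 1")
        if self.cell_types:
            total = sum(ct.n_cells for ct in self.cell_types)
            if total != self.n_cells:
                raise ValueError(
                    f"cell-type cell counts sum to {total}, expected {self.n_cells}"
                )
            ids = set(self.module_ids())
            for ct in self.cell_types:
                unknown = set(self._norm_modules(ct.active_modules)) - ids
                if unknown:
                    raise ValueError(f"unknown active modules {sorted(unknown)}")
        if self.trajectory is not None:
            if self.trajectory.n_lineages not in (1, 2):
                raise ValueError("n_lineages must be 1 or 2")
            if not 0.0 < self.trajectory.branch_point < 1.0:
                raise ValueError("branch_point must lie in (0, 1)")
            ids = set(self.module_ids())
            traj_mods = set(self._norm_modules(self.trajectory.modules_up)) | set(
                self._norm_modules(self.trajectory.modules_down)
            )
            if traj_mods - ids:
                raise ValueError(f"unknown trajectory modules {sorted(traj_mods - ids)}")

    @staticmethod
    def _norm_modules(mods) -> list[str]:
        """Accept module references as 'M3' or 1-based integers."""
        out = []
        for m in mods:
            out.append(f"M{m}" if isinstance(m, (int, np.integer)) else str(m))
        return out


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------


@dataclass
class LRPairTruth:
    ligand: str
    receptor: str
    source: str
    target: str


@dataclass
class SyntheticTruth:
    """Everything that was planted, the oracle for recovery tests."""

    gene_module: pd.Series  # gene -> module id or None
    cell_type: pd.Series  # cell -> name
    module_activity: pd.DataFrame  # module x cell
    marker_genes: dict = field(default_factory=dict)  # cell type -> [gene]
    lr_pairs: list = field(default_factory=list)  # [LRPairTruth]
    pseudotime: Optional[pd.Series] = None
    lineage: Optional[pd.Series] = None
    branch_point: Optional[float] = None
    biomarker_effects: dict = field(default_factory=dict)

    def module_genes(self) -> dict:
        """Module id -> list of member genes (planted partition)."""
        out: dict[str, list[str]] = {}
        for gene, mod in self.gene_module.items():
            if mod is not None:
                out.setdefault(mod, []).append(gene)
        return out

    def markers_as_sets(self) -> dict:
        return {ct: set(genes) for ct, genes in self.marker_genes.items()}

    def lr_count_matrix(self) -> pd.DataFrame:
        """Planted directed cell-type x cell-type interaction counts."""
        types = sorted(self.cell_type.unique())
        counts = pd.DataFrame(0, index=types, columns=types, dtype=int)
        for p in self.lr_pairs:
            counts.loc[p.source, p.target] += 1
        return counts


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------


def _gene_cell_ids(n_genes: int, n_cells: int) -> tuple[list[str], list[str]]:
    gw = max(4, len(str(n_genes)))
    cw = max(4, len(str(n_cells)))
    genes = [f"G{i + 1:0{gw}d}" for i in range(n_genes)]
    cells = [f"C{i + 1:0{cw}d}" for i in range(n_cells)]
    return genes, cells


def _layout(config: SyntheticConfig):
    """Deterministic assignment of genes to modules/markers and cells to types."""
    genes, cells = _gene_cell_ids(config.n_genes, config.n_cells)
    gene_module = pd.Series([None] * config.n_genes, index=genes, dtype=object)
    cursor = 0
    module_slices = {}
    for mid, spec in zip(config.module_ids(), config.modules):
        sl = slice(cursor, cursor + spec.size)
        module_slices[mid] = sl
        gene_module.iloc[sl] = mid
        cursor += spec.size
    marker_genes: dict[str, list[str]] = {}
    for ct in config.cell_types:
        marker_genes[ct.name] = genes[cursor : cursor + ct.marker_genes]
        cursor += ct.marker_genes
    if config.cell_types:
        labels = np.concatenate(
            [np.repeat(ct.name, ct.n_cells) for ct in config.cell_types]
        )
    else:
        labels = np.repeat("all", config.n_cells)
    cell_type = pd.Series(labels, index=cells)
    return genes, cells, gene_module, module_slices, marker_genes, cell_type


def _plant_lr_pairs(config, gene_module, module_slices, cell_type, rng):
    """Draw planted LR pairs from modules active in the named cell types."""
    active = {
        ct.name: SyntheticConfig._norm_modules(ct.active_modules)
        for ct in config.cell_types
    }
    genes = gene_module.index
    used: set[tuple[str, str]] = set()
    pairs: list[LRPairTruth] = []
    for entry in config.lr_plan:
        for side, name in (("source", entry.source), ("target", entry.target)):
            if name not in active or not active[name]:
                raise ValueError(
                    f"LR plan {side} cell type {name!r} has no active modules"
                )
        lig_pool = np.concatenate(
            [np.asarray(genes[module_slices[m]]) for m in active[entry.source]]
        )
        rec_pool = np.concatenate(
            [np.asarray(genes[module_slices[m]]) for m in active[entry.target]]
        )
        for _ in range(entry.n_pairs):
            for _attempt in range(1000):
                lig = str(rng.choice(lig_pool))
                rec = str(rng.choice(rec_pool))
                if lig != rec and (lig, rec) not in used:
                    break
            else:  # pragma: no cover - pool exhausted
                raise ValueError("could not draw a unique LR pair; pools too small")
            used.add((lig, rec))
            pairs.append(LRPairTruth(lig, rec, entry.source, entry.target))
    return pairs


def _build_expression(config: SyntheticConfig, activities: pd.DataFrame, rng):
    """Shared core: assemble log-space signal and exponentiate."""
    genes, cells, gene_module, module_slices, marker_genes, cell_type = _layout(config)
    n_g, n_c = config.n_genes, config.n_cells
    log_signal = np.empty((n_g, n_c))
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    log_signal[:] = baseline[:, None]
    for mid, spec in zip(config.module_ids(), config.modules):
        sl = module_slices[mid]
        lo, hi = spec.loading_range
        loadings = rng.uniform(lo, hi, size=spec.size)
        log_signal[sl] += loadings[:, None] * activities.loc[mid].to_numpy()[None, :]
    for ct in config.cell_types:
        if not marker_genes[ct.name]:
            continue
        idx = [genes.index(g) for g in marker_genes[ct.name]]
        in_type = (cell_type == ct.name).to_numpy()
        log_signal[np.ix_(idx, np.arange(n_c))] += config.marker_shift * in_type[None, :]
    if config.noise_sd > 0:
        log_signal += rng.normal(0.0, config.noise_sd, size=(n_g, n_c))
    values = np.maximum(np.exp(log_signal) - 1.0, 0.0)
    if config.dropout_rate > 0:
        keep = rng.random(size=(n_g, n_c)) >= config.dropout_rate
        values = values * keep
    lr_pairs = _plant_lr_pairs(config, gene_module, module_slices, cell_type, rng)
    meta = pd.DataFrame({"cell_type": cell_type})
    X = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), meta)
    truth = SyntheticTruth(
        gene_module=gene_module,
        cell_type=cell_type,
        module_activity=activities,
        marker_genes=marker_genes,
        lr_pairs=lr_pairs,
    )
    return X, truth


def generate_expression(config: SyntheticConfig):
    """Generate a gene x cell matrix with planted modules and cell types.

    Returns ``(ExpressionMatrix, SyntheticTruth)``.  Bit-identical for a
    fixed config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, cells, gene_module, module_slices, marker_genes, cell_type = _layout(config)
    mods = config.module_ids()
    acts = np.zeros((len(mods), config.n_cells))
    for i, (mid, spec) in enumerate(zip(mods, config.modules)):
        acts[i] = rng.normal(0.0, spec.activity_sd, size=config.n_cells)
        for ct in config.cell_types:
            if mid in SyntheticConfig._norm_modules(ct.active_modules):
                acts[i] += config.active_shift * (cell_type == ct.name).to_numpy()
    activities = pd.DataFrame(acts, index=mods, columns=cells)
    return _build_expression(config, activities, rng)


def generate_trajectory_dataset(config: SyntheticConfig):
    """Generate expression whose module activities follow a planted trajectory.

    Trajectory-module activities are deterministic functions of the
    planted pseudotime and lineage; ``noise_sd`` is the only stochastic
    perturbation on them, so at ``noise_sd=0`` their expression is an
    exact monotone function of pseudotime.
    """
    config.validate()
    if config.trajectory is None:
        raise ValueError("config.trajectory must be set")
    traj = config.trajectory
    rng = np.random.default_rng(config.seed)
    genes, cells, gene_module, module_slices, marker_genes, cell_type = _layout(config)
    n_c = config.n_cells
    t = rng.uniform(0.0, 1.0, size=n_c)
    lineage = (
        rng.integers(1, traj.n_lineages + 1, size=n_c)
        if traj.n_lineages > 1
        else np.ones(n_c, dtype=int)
    )
    up = set(SyntheticConfig._norm_modules(traj.modules_up))
    down = set(SyntheticConfig._norm_modules(traj.modules_down))
    bp = traj.branch_point
    # lineage 1 carries the up-program past the branch point, lineage 2 the
    # down-program; before the branch point both programs are shared
    t_up = np.where(lineage == 1, t, np.minimum(t, bp)) if traj.n_lineages > 1 else t
    t_down = np.where(lineage == 2, t, np.minimum(t, bp)) if traj.n_lineages > 1 else t
    mods = config.module_ids()
    acts = np.zeros((len(mods), n_c))
    for i, (mid, spec) in enumerate(zip(mods, config.modules)):
        if mid in up:
            acts[i] = traj.slope * (t_up - 0.5)
        elif mid in down:
            acts[i] = -traj.slope * (t_down - 0.5)
        else:
            acts[i] = rng.normal(0.0, spec.activity_sd, size=n_c)
            for ct in config.cell_types:
                if mid in SyntheticConfig._norm_modules(ct.active_modules):
                    acts[i] += config.active_shift * (cell_type == ct.name).to_numpy()
    activities = pd.DataFrame(acts, index=mods, columns=cells)
    X, truth = _build_expression(config, activities, rng)
    # early cells carry the unstressed condition label, mirroring designs
    # where the control arm dominates the trajectory root
    X.cell_meta["condition"] = np.where(t <= 0.3, "control", "case")
    truth.pseudotime = pd.Series(t, index=cells)
    truth.lineage = pd.Series(lineage, index=cells)
    truth.branch_point = bp if traj.n_lineages > 1 else None
    return X, truth


# --------------------------------------------------------------------------
# LR database / proteome
# --------------------------------------------------------------------------


def generate_lr_database(truth: SyntheticTruth, n_decoys: int, seed: int):
    """Planted LR pairs plus ``n_decoys`` decoy pairs among unassigned genes."""
    from .communication import LRDatabase

    if not truth.lr_pairs and n_decoys <= 0:
        raise ValueError("need at least one planted pair or n_decoys > 0")
    rng = np.random.default_rng(seed)
    pairs = [(p.ligand, p.receptor) for p in truth.lr_pairs]
    in_pairs = {g for pair in pairs for g in pair}
    marker = {g for genes in truth.marker_genes.values() for g in genes}
    pool = [
        g
        for g, m in truth.gene_module.items()
        if m is None and g not in in_pairs and g not in marker
    ]
    if 2 * n_decoys > len(pool):
        raise ValueError(
            f"{n_decoys} decoy pairs need {2 * n_decoys} unassigned genes, "
            f"only {len(pool)} available"
        )
    chosen = rng.choice(pool, size=2 * n_decoys, replace=False)
    pairs.extend((str(chosen[2 * i]), str(chosen[2 * i + 1])) for i in range(n_decoys))
    return LRDatabase(pairs)


def generate_proteome(
    groups: Sequence[tuple[str, int]],
    effects: dict,
    noise_sd: float,
    seed: int,
    baseline: float = 10.0,
):
    """Multi-group protein x sample table with planted group mean shifts.

    ``effects`` maps protein -> {group name -> mean shift}; missing
    groups shift by 0.  Returns ``(ProteomeTable, SyntheticTruth)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if not effects:
        raise ValueError("need at least one protein")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for name, n in groups:
        if n <= 0:
            raise ValueError(f"group {name!r} has no samples")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.repeat(name, n) for name, n in groups])
    n_samples = len(labels)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    proteins = list(effects)
    values = np.empty((len(proteins), n_samples))
    for i, prot in enumerate(proteins):
        shift = np.array([effects[prot].get(g, 0.0) for g in labels])
        noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        values[i] = baseline + shift + noise
    table = ProteomeTable(
        pd.DataFrame(values, index=proteins, columns=samples),
        pd.Series(labels, index=samples, name="group"),
    )
    truth = SyntheticTruth(
        gene_module=pd.Series(dtype=object),
        cell_type=pd.Series(labels, index=samples),
        module_activity=pd.DataFrame(),
        biomarker_effects=dict(effects),
    )
    return table, truth
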