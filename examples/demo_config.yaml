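# Small end-to-end demo: simulated heart-like dataset with four cell
# types, planted co-expression modules, ligand-receptor pairs, a
# two-branch trajectory and a plasma-proteome screen.
seed: 11
out_dir: demo_out
synthetic:
  n_genes: 400
  n_cells: 240
  noise_sd: 0.3
  modules:
    - {size: 35}
    - {size: 35}
    - {size: 35}
    - {size: 35}
    - {size: 30}
    - {size: 30}
  cell_types:
    - {name: CM, n_cells: 60, marker_genes: 4, active_modules: [M1]}
    - {name: EC, n_cells: 60, marker_genes: 4, active_modules: [M2]}
    - {name: FB, n_cells: 60, marker_genes: 4, active_modules: [M3]}
    - {name: MP, n_cells: 60, marker_genes: 4, active_modules: [M4]}
  lr_plan:
    - {source: FB, target: CM, n_pairs: 3}
    - {source: FB, target: EC, n_pairs: 2}
    - {source: EC, target: CM, n_pairs: 1}
  trajectory:
    n_lineages: 2
    modules_up: [M5]
    modules_down: [M6]
qc:
  min_genes: 30
  min_value: 0.5
  min_cells: 3
network:
  power: 6
communication:
  n_decoys: 4
trajectory:
  k: 10
classification:
  n_trees: 60
biomarker:
  enabled: true
  groups: [[control, 40], [nonadv, 20], [advpre, 15], [advpost, 15]]
  effects:
    P_DIAG: {nonadv: 2.0, advpre: 2.0, advpost: 2.0}
    P_SEV: {nonadv: 0.5, advpre: 2.5, advpost: 2.5}
    P_NULL: {}
  noise_sd: 1.0
  diagnosis: [[control], [nonadv, advpre, advpost]]
  severity: [[nonadv], [advpre, advpost]]
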