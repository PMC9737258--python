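# Demo run: two reference lines (U251 internal, U87 external) plus six
# patient-derived lines spanning internal-to-external placements.
seed: 17
geometry:
  diameter_um: 500
  n_zones: 5
  um_per_px: 1.0
image:
  z_slices: 1
  noise_sd: 0.05
  cell_radius_um: 6.0
threshold: otsu
populations:
  - {label: U251, n_cells: 400, zone_probs: [0.57, 0.42, 0.01, 0.0, 0.0]}
  - {label: U87,  n_cells: 400, zone_probs: [0.05, 0.48, 0.45, 0.02, 0.0]}
  - {label: TS-A, n_cells: 400, core_shell: {core_fraction: 0.30, shell_bias: 0.05}}
  - {label: TS-B, n_cells: 400, core_shell: {core_fraction: 0.40, shell_bias: 0.20}}
  - {label: TS-C, n_cells: 400, core_shell: {core_fraction: 0.50, shell_bias: 0.40}}
  - {label: TS-D, n_cells: 400, core_shell: {core_fraction: 0.60, shell_bias: 0.60}}
  - {label: TS-E, n_cells: 400, core_shell: {core_fraction: 0.70, shell_bias: 0.80}}
  - {label: TS-F, n_cells: 400, core_shell: {core_fraction: 0.80, shell_bias: 0.95}}
references:
  inner: U251
  outer: U87
coupling:
  direction: resistant_when_external
  noise_sd: 0.0
survival:
  hazard_ratio: 3.0
  baseline_median: 24
  censor_prob: 0.2
  n_per_group: 25
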