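# Default fit profile for fluid-phase phosphatidylcholine bilayers.
# Copy, point `datasets` at your reduced .dat files, set V_L, and run
#   sdpgap fit --config my_run.yaml
label: pc-default
scheme:
  preset: pc
  n_CH2: 28        # methylenes over both chains (DPPC: 28; POPC: 28 + 2 CH)
  n_CH: 0          # methines, pooled into CH2
  n_CH3: 2
  cholesterol_fraction: 0.0
  volume_tolerance: 0.05
V_L: 1256.0        # lipid molecular volume, A^3 (from densitometry)
q_unit: "1/A"
datasets:
  - path: example_saxs_mlv.dat
    name: saxs_mlv
    radiation: xray      # xray | neutron
    geometry: mlv        # mlv | ulv
    solvent_d2o_fraction: 0.0
    beam_sigma: 0.0      # Gaussian q-resolution width, 1/A
    # deuteration: {CH2: 28, CH3: 3}   # e.g. sn-1 palmitoyl-d31
fit:
  population_size: 2000
  max_generations: 500
  stagnation_generations: 100
  islands: 4
  n_starts: 4
  seed: 1
# bounds:             # optional per-gene overrides
#   "eta@saxs_mlv": [0.0, 0.2]
# fixed:
#   "N_diff@saxs_mlv": 0.0
output_dir: results
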