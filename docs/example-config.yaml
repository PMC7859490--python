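# Example pipeline configuration (synthetic mode).
# Run:  panelgp pipeline --config docs/example-config.yaml --out results/demo
master_seed: 7
traits: [CWT]
regions: [WGS]
k_grid: [500]
n_folds: 5
grm_threshold: 0.30
maf_min: 0.01
call_rate_min: 0.90
hwe_p_min: 1.0e-6
max_missing: 0.10
simulate:
  n_founders: 700
  generation_sizes: [500, 200]
  n_sires: [null, 12]
  n_markers: 6000
  n_chromosomes: 5
  base_panel_size: 800
  n_qtl: 50
  h2: 0.33
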