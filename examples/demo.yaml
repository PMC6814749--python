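# Small demonstration run (~1,200 cells); mirrors retinet.pipeline.demo_config
output_dir: retinet_demo
seed: 0
synth:
  n_genes: 1000
  n_types: 6
  cells_per_type: 200
  markers_per_type: 15
min_genes_per_cell: 100
min_cells_per_gene: 5
reduced_dim: 30
k_max: 8
n_perm: 250
run_gwas: true
gwas_effect: 1.0
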