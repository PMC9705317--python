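# Full pipeline configuration for a small synthetic cohort.
# Run with:  minpop run --config examples/run_config.yaml --out scratch/run
seed: 3
simulate:
  n_contigs: 2
  contig_length_bp: 2100000
  n_sites_per_contig: 6000
  pop_names: [A, B]
  pop_sizes: [12, 14]
  fst_matrix: 0.05
  n_outliers: 1
  n_mislabeled: 1
  mislabel_true_pop: B
  mislabel_recorded_pop: A
structure:
  n_pca_sites: 5000
  cluster_cutoff: 0.3   # small cohorts need a wider single-linkage cut
diversity:
  n_boot: 50
fst_scan:
  window_snps: 500
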