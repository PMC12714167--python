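# Demo pipeline configuration: a cohort with a planted differential circuit,
# a trait-coupled coexpression module, GABA-neuron enrichment and planted
# validation effects. All stages are seeded from the single seed below.
seed: 11
n_per_group:
  HC: 15
  MDDNSI: 15
  MDDSI: 15
  MDDSB: 15
n_regions: 90
planted_edges:
  - [0, 1]
  - [1, 2]
  - [2, 3]
  - [3, 4]
  - [4, 5]
  - [5, 6]
  - [6, 7]
  - [7, 8]
  - [8, 9]
  - [9, 10]
edge_effect: 2.0          # standardized mean difference at planted edges
affected_group: MDDSI
noise_sd: 0.1
n_genes: 700
modules:                   # (size, within-module r, trait r)
  - [150, 0.7, 0.5]
  - [150, 0.7, 0.0]
  - [150, 0.7, 0.0]
enriched_module: 0
enrichment_fold: 5.0
validation_effect: 2.0
n_validation_per_group: 30
nbs:
  primary_p: 0.001
  n_perm: 1000
wgcna:
  min_module_size: 100
  target_r2: 0.85
  mm_threshold: 0.8
  gs_threshold: 0.5
  merge_eigengene_dissim: 0.25
enrichment:
  p_threshold: 0.01
  min_overlap: 3
  min_enrichment: 1.0
  n_boot: 1000
  top_n: 5
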