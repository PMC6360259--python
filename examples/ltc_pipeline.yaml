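# Long-time-course configuration: probe selection at p < 0.01, FC > 1.2,
# variance of per-(condition, timepoint) donor medians > 0.05, then the
# k = 3 network clustered 10,000 times keeping the 100 best partitions.
# Point the paths at your expression/metadata/annotation TSVs (see README).
expression: data/ltc_expr.tsv
metadata: data/ltc_meta.tsv
annotation: data/annot.tsv
gmt: data/signatures.gmt
out_dir: results/ltc
selection:
  de_p_threshold: 0.01
  de_fc_threshold: 1.2
  de_adjust: false
  variance_threshold: 0.05
k: 3
n_runs: 10000
keep: 100
base_seed: 42
strategy: max_modularity
enrich_min_size: 5
enrich_max_size: 1500
enrich_fdr: 0.1
enrich_top: 30
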