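# Short-time-course configuration: identical to the LTC run except the
# looser selection p threshold (p < 0.05), matching the acute-stimulation
# design with fewer samples per contrast.
expression: data/stc_expr.tsv
metadata: data/stc_meta.tsv
annotation: data/annot.tsv
gmt: data/signatures.gmt
out_dir: results/stc
selection:
  de_p_threshold: 0.05
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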