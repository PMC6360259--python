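# Methods

## The method

Parsimonious gene correlation network analysis (PGCNA) maps modular
co-expression structure in expression time courses. Rather than keeping a
dense or soft-thresholded correlation matrix, it keeps for every gene only
its *k* strongest positive Spearman correlations (*k* = 3 by default) and
symmetrizes the result: an edge survives if either endpoint nominated it.
For *n* genes this reduces the n(n−1)/2 candidate pairs (41,064,453 at
n = 9,063) to a sparse graph of order k·n edges on which modularity-based
community detection is fast and well conditioned. Modules are then read
out by an ensemble of Louvain clusterings, characterized by hypergeometric
gene-signature enrichment, and summarized as expression dynamics across
the time course.

The pipeline stages, in order:

1. **Probe selection.** Probes enter the network if they are
   differentially expressed in at least one configured contrast (Welch
   two-sample t-test on log2 values, unadjusted p below a threshold, and
   |Δmean(log2)| strictly above log2 of a fold-change threshold), or if
   the unbiased variance of their per-(condition, timepoint) donor
   medians strictly exceeds a threshold (default 0.05 on the log2 scale).
   Defaults for a long differentiation course are p < 0.01 and FC > 1.2;
   an acute-stimulation course uses p < 0.05. The separate
   differential-expression mode used for condition-convergence analyses
   applies FC > 1.5 with Benjamini–Hochberg-adjusted p < 0.05.
2. **Probe→gene merge.** Unannotated probes are dropped; when several
   selected probes map to one gene, the probe with the largest variance
   across all samples represents it (ties: lexicographically smaller
   probe id).
3. **Network.** All-pairs Spearman ρ (average ranks on ties; constant
   rows are dropped with a warning), then per-gene top-k retention among
   strictly positive ρ with lexicographic tie-breaking, then
   symmetrization. Genes with no positive partner remain as isolated
   nodes and form singleton modules downstream.
4. **Clustering.** Weighted Newman–Girvan modularity
   Q = (1/2W) Σ_ij [w_ij − s_i s_j / 2W] δ(c_i, c_j). The graph is
   clustered 10,000 times (seeds base_seed … base_seed + n_runs − 1) with
   the two-phase Louvain heuristic at resolution 1.0 and the 100 best
   partitions by Q are kept; ties rank by run index, so results are
   reproducible from the base seed alone. The final partition is either
   the modularity maximum (default) or, when a signature database is
   supplied, the kept partition maximizing the summed −log10
   best-signature FDR over its modules. Module labels M1, M2, … order by
   descending size.
5. **Enrichment.** Hypergeometric upper tail with draw = module genes,
   successes = signature ∩ population, population = all annotated genes
   in the input (configurable to an explicit universe). Signature sizes
   are taken after intersection with the population; signatures outside
   [5, 1500] genes are excluded; BH correction runs across the full
   module × signature family of one run; at most the top 30 signatures
   per module at FDR < 0.1 are reported. Depletion, when requested, uses
   the lower tail with the same filters. Significances are stored as
   −log10 with a floor at 1e−300.
6. **Overlaps.** Module overlap between two networks, signature-level
   overlap (signatures prefiltered to raw p < 0.001 and 5–1000 genes;
   universe = signatures surviving the prefilter in either table, or an
   explicit count), and DE-set overlap across conditions/timepoints all
   reduce to the same hypergeometric kernel, reported as −log10 p floored
   at 0 and capped at 300. Three-way Venn partitions report the 7
   exclusive region counts.
7. **Dynamics.** Median across donors per (condition, timepoint) group
   (a single-donor group contributes its lone value), then per-gene
   z-scores across group medians (n−1 denominator; constant rows become
   zeros and are flagged) or log2 fold change against each condition's
   baseline group; module profiles are unweighted means of member rows.
   Row ordering uses agglomerative clustering with 1 − Pearson distance
   and average linkage; a constant row's correlation is taken as 0
   (distance 1).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | edges retained per gene; the sparsification strength |
| `de_p_threshold` | 0.01 (selection) / 0.05 (DE mode) | per-contrast Welch p cut |
| `de_fc_threshold` | 1.2 (selection) / 1.5 (DE mode) | linear fold change, applied as a strict log2 cut |
| `variance_threshold` | 0.05 | σ² of group medians on the log2 scale, strict |
| `n_runs` / `keep` | 10,000 / 100 | Louvain ensemble size and retention |
| `base_seed` | 42 | first Louvain seed; runs use consecutive seeds |
| enrichment filters | FDR < 0.1, 5–1500 genes, top 30 | reporting filters for module signatures |
| overlap prefilter | p < 0.001, 5–1000 genes | signature-level module overlap |

## Design choices where the design was open

- **Per-probe test.** The Welch two-sample t-test on log2 intensities: an
  assumption-light default for small unpaired array groups. Moderated
  (empirical-Bayes) tests are deliberately out of scope; the test sits
  behind one function and the thresholds are configurable.
- **Selection p values are unadjusted; DE-mode p values are
  BH-adjusted.** Probe selection is a screening step feeding an
  unsupervised method, so leniency costs little; DE sets are reported
  objects and get FDR control.
- **Ranking by signed ρ, positive edges only.** Retaining only positive
  correlations keeps modularity well defined on nonnegative weights;
  ranking by |ρ| is available via a flag.
- **Variance-filter grouping** uses condition × timepoint cells (not
  timepoints pooled across conditions), preserving condition structure;
  configurable by supplying contrasts/metadata accordingly.
- **Enrichment-informativeness score** for partition selection: Σ over
  modules of −log10(best signature FDR). Simple, monotone in the
  strength of the best annotation per module, and indifferent to module
  count inflation only insofar as every extra module must earn its own
  signature.
- **Correction family.** BH runs across all module × signature tests of
  one run — the conservative choice relative to per-module correction.

## The synthetic benchmark

`simulate_timecourse` emulates a multi-donor, multi-condition bead-array
time course: 400 genes, 8 planted modules, 10% null (moduleless) genes,
2 conditions × 8 ordered timepoints × 3 donors, Poisson(0.3)+1 probes per
gene (mean 1.3). A gene's latent value is
baseline + loading × trajectory(module, condition, time) + donor effect
+ N(0, noise²), with baseline ~ N(8, 1), loadings U(0.5, 1.5), donor
effect sd 0.2, noise sd 0.5; each probe adds a fixed N(0, 0.3) offset and
N(0, 0.1) jitter. One RNG stream with documented draw order makes
datasets bit-reproducible from the seed.

Module trajectories are cubic polynomials per condition. On the
condition × timepoint grid, the centered span of such functions has
dimension 4·n_conditions − 1 (7 for two conditions); trajectories are
drawn as a random rotation of an orthonormal basis of that span so
modules are exactly uncorrelated. Eight modules cannot all be orthogonal
in a 7-dimensional span, so the default uses the regular-simplex frame —
the maximally separated configuration, constant pairwise correlation
−1/(n_modules − 1) ≈ −0.14. Requesting more than 4·n_conditions modules
is an error.

Ground truth shipped with a dataset: the gene → module map (null genes
labeled M0), per-(condition, timepoint) DE sets derived from the
noiseless profiles (|Δ| vs the condition's first timepoint > 1 log2
unit), one exact signature per module plus random decoy sets, and the
noiseless gene × group matrix.

Recovery is scored by the adjusted Rand index over genes with a planted
module: M0 marks "no module", not a module, and null genes are by
construction unclusterable noise. DE power is scored on the
between-condition contrast at each timepoint with 4 donors per group:
sensitivity over gene instances whose noiseless between-condition
difference is ≥ 2 log2 units, empirical FDR over calls landing on null
(zero-difference) genes. With 90% sharp nulls and a fixed 2-log2 spike,
the plain Welch test at n = 4 (≈6 df) under BH has power well below
these figures — the time-course design, where effect sizes are
continuous and the BH cutoff adapts, is the relevant regime and the one
scored.

What the generator does *not* emulate: Illumina probe-intensity
distributions, batch/chip effects, correlated noise between probes of a
gene beyond the shared gene value, missing values, or unannotated
probes. Passing the benchmark therefore demonstrates correctness of the
pipeline's statistics and determinism, not robustness to array
artifacts.

## Numerical notes

- Spearman is computed as Pearson on average ranks; the all-pairs matrix
  is dense (float64), so memory is 8·n² bytes — about 0.7 GB at
  n ≈ 9,000.
- Welch with both groups constant: equal means → t = 0, p = 1; unequal
  means → ±∞, p = 0. Underflowing Welch df falls back to the pooled df.
- Strict inequalities everywhere a threshold is stated (fold change,
  variance, p) — boundary values are excluded.
- Modularity of a zero-weight graph is undefined and raises.
- Problem sizes in tests and the acceptance script (400-gene benchmark,
  100-run ensembles, 5 replicates; 50-run ensembles for the noise sweep)
  are the package's standard desk-scale configuration; the full 10,000 ×
  100 ensemble is the production default on real data.

## Known limitations

- Exact reproduction of the published probe/gene/edge/module counts on
  the original bead-array time courses depends on unstated details of
  the original processing (the per-probe test, the probe-merge rule, the
  legacy Louvain randomization); the arithmetic invariants (pair counts,
  retention bounds) are exact, while module counts reproduce
  approximately.
- No paired-design or batch-aware testing; no partial correlations or
  soft-threshold networks; layout computation and interactive
  visualization are out of scope (networks export to GEXF/GraphML).
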