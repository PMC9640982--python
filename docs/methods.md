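# Methods

## The analysis model

The package targets perturbation time courses with one RNA-seq library per
(timepoint, dose) condition. With no biological replicates there is no
within-group variance to estimate, so parametric DE tests (and their
shrinkage-based replicate-free fallbacks) are either undefined or severely
underpowered. The pipeline instead treats the fold change itself as the DE
statistic and moves the inference downstream: DE genes are placed on a
merged network of biological pathways, and *network position* — not
per-gene significance — is what gets tested, by permutation.

Stages and their models:

1. **Normalization.** Median-of-ratios size factors: reference genes are
   rows with strictly positive counts in all samples; the factor of sample
   j is the median over reference genes of count_ij / geometric-mean_i.
   All downstream log-scale quantities use log2(count/s_j + pseudocount).
   The pseudocount defaults to 1 (conventional; it bounds the statistic for
   zero counts and attenuates fold changes of low-count genes, which is the
   desired behaviour for a thresholded DE rule). A full variance-stabilizing
   transformation is deliberately not fitted: the transform feeds only
   descriptive summaries (distance heatmap, PCA), for which log2(norm + 1)
   is adequate and parameter-free.
2. **DE calling.** log2FC = mean log2 normalized counts over treated
   samples minus the same over controls; DE iff |log2FC| ≥ threshold
   (default 1.0, inclusive). Default contrasts: (t, dose) vs (t, 0) per
   timepoint; a "spontaneous differentiation" mode contrasts (t, 0) vs the
   first timepoint's control.
3. **Set algebra.** Overlap percent is 100·|A∩B|/|A∪B|. Set operations are
   sign-agnostic by default with sign-aware variants, since published DE
   overlap counts rarely state sign handling. The temporal-shift rule had
   to be operationalized from a narrative description; the default —
   sign-matched, DE at the high dose at a non-final timepoint i, DE at the
   low dose at some strictly later j, *not* DE at the low dose at i, with
   denominator = genes DE at the high dose at any non-final timepoint — is
   recorded verbatim in every result object and each clause is a keyword
   argument.
4. **Network.** Pathways merge by node/edge union into an undirected simple
   graph; interaction-type tokens are kept as metadata and ignored by the
   statistics. Gene identity is exact string match after upper-casing
   (pathway databases mix Vav1/VAV1 capitalizations). DE genes absent from
   the network are reported as unmapped, never added as isolates — isolates
   would dilute every degree statistic with artifacts of annotation
   coverage rather than biology.
5. **Topology tests.** Hubs are nodes with degree ≥ 20; the ECDF contrast
   is evaluated at k = 25. Both thresholds are exposed but default to the
   only values with any precedent in the motivating analyses. Nulls re-draw
   the DE label set uniformly among network nodes (degree-bias and
   mean-degree tests are fully vectorized over permutations). The power-law
   diagnostic is a least-squares slope on a logarithmically binned log-log
   degree histogram — a qualitative scale-free check, not a Clauset-style
   maximum-likelihood fit, which the analysis does not need.
6. **Subnetwork tests.** A "subnetwork" is a connected component of size
   ≥ 2 of the DE-induced subgraph; singleton DE nodes are "scattered".
   Components are ordered (size descending, then lexicographically smallest
   member) so reports are diffable. The size test resamples whole node sets
   of size |DE| (side "less" by default: a low-connectivity-biased DE set
   forms a smaller core than chance). The hub-capture null is genuinely
   underdetermined in the motivating description; the default conditions on
   the observed DE set and giant size and resamples giant membership
   uniformly from the DE set, isolating "do hubs concentrate in the
   connected core" from the DE set's own degree bias. The alternative
   (resample node sets, re-derive the giant) is selectable.
7. **Enrichment.** E = (b/n)/(B/N) with the exact hypergeometric upper
   tail P(X ≥ b) — the documented model of two-unranked-list GO tools —
   and Benjamini–Hochberg q-values over the emitted records. Terms are
   intersected with the background before counting; records need b ≥ 3 by
   default. For subnetwork enrichment the target is the giant-subnetwork
   gene set and the background all network genes (the literal
   "non-subnetwork genes as background" reading is selectable).

## p-values from permutation nulls

Every permutation result reports three p-values, labelled:

- `p_empirical` — add-one estimator (1 + #extreme)/(1 + n_iter). Never
  exactly 0; with 1,000 iterations its floor is 1/1001, so very strong
  contrasts saturate.
- `p_randomized` — the classical randomized tie-broken p, using one uniform
  draw from the test's own seeded generator. Several statistics here
  (ECDF differences, component sizes, hub counts) are integer-valued, and
  counting null ties as extreme makes `p_empirical` conservative — on a
  2,000-node preferential-attachment graph only ~2% of nodes exceed degree
  25, so the ECDF statistic at k = 25 has massive tie groups and the
  add-one rule rejects at well under the nominal rate. The randomized p is
  exactly uniform under the null and is the value to use when nominal
  type-I error matters; it is deterministic given the seed.
- `p_normal` — the normal tail of z = (obs − null mean)/null sd, reported
  because it resolves below the empirical floor; undefined (with the
  z-score) when the null is degenerate.

## The synthetic-data generator

The generator emulates the structure of a replicate-free mESC exposure
study — 6 timepoints (D0–D28) × doses {0, 10, 100 nM}, one sample each,
D0 at dose 0 only (16 samples) — at desk scale: 10,000 genes and a
4,000-node / m = 4 preferential-attachment network by default, within 2× of
the motivating study's DE union and network sizes.

- **Counts.** Baseline means log-normal (median 200, log-sd 1.2, floored at
  a configurable minimum); per-sample size factors log-uniform in
  (0.7, 1.4); counts negative-binomial with variance μ + αμ² (α = 0.05 by
  default; α = 0 is Poisson). Per treated timepoint, a fraction `frac_de`
  (default 0.1) of genes respond at both doses with |log2FC| = 2 and random
  sign — this puts per-condition DE counts near 1,000–1,500 at the default
  scale, matching the motivating study's range. A temporal-shift class
  (effect at the high dose at a non-final timepoint, reproduced at the low
  dose only strictly later) is sized so the planted shift fraction is 5% by
  default. The generator and the detector share one definition of
  "shifted", so noise-free recovery is exact by construction.
- **Network and pathways.** Barabási–Albert graphs (connected, simple,
  exactly m(n−m) edges). The pathway cover grows connected edge subsets
  from random seed edges until every edge is covered; `n_pathways` is a
  target, not a guarantee — a pathway closes early when no uncovered edge
  touches it, and extra overlapping pathways are added if coverage
  finishes early. Merging the cover reproduces the input graph exactly,
  which is the property the tests rely on.
- **DE sets.** Sampled without replacement with P ∝ degree^β; β = 0 is
  uniform, β = −0.75 reproduces the low-connectivity bias reported for DE
  genes in pathway networks.
- **Terms.** Random gene sets plus one planted term covering 30% of a
  target list and 5% of the rest of the universe. Note the emitted fold is
  analytically below the coverage ratio cov_t/cov_b because the target
  itself contributes to B/N; it converges to the ratio as |target|/N → 0.

What the generator does *not* emulate: read-level artifacts (mapping,
duplication), gene-length and GC biases, correlated gene modules,
annotation incompleteness, or KEGG's actual pathway size distribution.
Passing recovery tests therefore demonstrate correctness of the statistical
machinery under the stated model, not performance on any particular real
dataset — the motivating study's headline numbers (network size, hub
counts, specific p-values) depend on a specific GEO accession and KEGG
release and are out of scope.

## Numerical choices and degenerate inputs

- DE threshold comparisons are inclusive (≥), as is the hub rule (k ≥ 20)
  and the ECDF convention (fraction ≤ x).
- Empty Venn unions return overlap 0 with an `empty_union` flag rather
  than NaN.
- Degenerate permutation nulls (sd = 0) flag the z-score as undefined
  (`None`) but still return the empirical p.
- Distance matrices are symmetrized and their diagonal pinned to exactly 0
  after the correlation call, so the contract holds to the bit.
- PCA centers each gene across samples and uses SVD; variance fractions are
  reported for all components (they sum to 1 to 1e−10).
- Sampling k-subsets inside vectorized permutation loops uses the
  random-key argpartition trick; the subnetwork null uses a restricted BFS
  over integer adjacency arrays, which keeps the 500-replicate calibration
  suite within a few minutes on one CPU. Test problem sizes (2,000-node
  calibration graphs, 200 permutations per replicate, 4,500-gene recovery
  matrices) were chosen as the smallest scales at which the targeted
  effects are comfortably identifiable.
- Pipeline run manifests record parameters, seed and output SHA-256 hashes
  and contain no timestamps, so identical config + seed reruns are
  byte-identical.

## Known limitations

- The temporal-shift denominator and rule are one defensible
  operationalization among several; results are only comparable across
  runs using the same recorded definition.
- `read_xgmml` supports the minimal node-label/edge-endpoint subset; rich
  XGMML attributes are ignored.
- The power-law diagnostic is descriptive; do not quote its slope as a
  fitted exponent.
- Enrichment assumes flat term sets; GO graph structure and term ancestry
  propagation are out of scope.
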