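# Methods

This note records the models and procedures bacstab implements, the
defaults it chooses where the field's practice is not unique, and what the
synthetic-data tests do and do not establish about real data.

## Study design and containers

The analysis assumes a paired two-site design: sites **A** and **B**
sampled at 4 growth stages with 9 replicate quadrats each (72 samples).
Abundance tables are taxon-by-sample matrices in counts or relative mode;
the *D-value* of any quantity is its site-A-minus-site-B difference at a
matched (stage, replicate) pair, giving 36 paired differences. Pairing by
replicate index is the only scheme that preserves the per-stage structure
of the design; unmatched combinations are dropped with a warning.

## AVD stability index

For taxon *i* within a replicate group of *k* samples, the variation
degree of sample *s* is `a_i(s) = (x_i(s) − x̄_i)/δ_i`. AVD averages
`|a_i(s)|` over samples and over the *n* taxa with `δ_i > 0`.

Choices:

* `δ` is the sample standard deviation (ddof = 1, configurable). With
  k = 9 replicates the distinction is a ~6 % scale factor and does not
  affect orderings.
* Zero-variance taxa are excluded from both numerator and *n*: the ratio
  is undefined at `δ = 0`, and counting such taxa as "zero variation"
  would reward sparsity artefacts. Excluded taxa are reported.
* AVD is computed per (site, stage) group (k = 9, the collection unit) and
  per site (k = 36); both are emitted.
* Input is relative abundance. Because each taxon is standardised by its
  own `δ`, AVD is invariant to per-taxon rescaling; rarefaction is
  therefore not required, but counts are accepted and normalised.

**Per-sample AVD series.** Correlating taxa or functions with stability
needs a per-sample (or per-pair) stability score. We use the per-sample
slice of the AVD sum itself: `v(s) = mean_i |a_i(s)|`, whose group mean is
exactly the group AVD. The per-pair series `v_A(s) − v_B(s)` over the 36
matched pairs is what keystone D-values and function D-values are
correlated against. (A jackknife pseudovalue construction was considered
and rejected: re-standardising after leave-one-out adds enough noise to
mask genuine per-sample disturbance signal.)

## Co-occurrence networks

* Spearman correlation with average ranks for ties; two-sided p from the
  t-approximation on n−2 df. At n = 36 this is accurate to ~0.002 at the
  p = 0.01 threshold (the measured type-I rate of the edge test is
  ≈ 0.012; see the calibration test). A permutation p-value helper exists
  for very small n.
* Edges require `|ρ| > r_min` **strictly** and `p < p_max` strictly
  (taxa: 0.6/0.01; functions: 0.75/0.01). No multiple-testing correction
  is applied by default — the construction rule is a fixed threshold, not
  an inference — but the machinery accepts any thresholds.
* Topology is computed on the unweighted skeleton: avgK = 2E/N,
  GD = 2E/(N(N−1)), avgCC = mean local clustering (0 for degree < 2),
  APD = mean shortest-path length over *connected* pairs only (flagged
  when the graph is disconnected), negative ratio = share of edges with
  ρ < 0.
* Modules: seeded Louvain at resolution 1.0 on the unweighted graph;
  modularity is the Newman–Girvan Q of that partition. Module labels are
  assigned by decreasing size for deterministic output.
* Isolated nodes are retained by `build_network` by default; the pipeline
  drops them (config `network.keep_isolated`), matching the usual practice
  of reporting only connected taxa.

## Keystone taxa

Hub score = HITS hub, computed by power iteration to 1e−8 and
max-normalised; for an undirected graph this is the principal eigenvector
of the adjacency matrix. Betweenness is unnormalised with each unordered
pair counted once. Keystones = union of the top-5 by hub and top-5 by
betweenness (ties: metric desc, degree desc, id asc); the core taxon is
the keystone of maximal degree (ties: betweenness, then id). Keystone
D-value series are Spearman-correlated with the per-pair AVD series;
entries at p ≥ 0.05 are reported as non-significant rather than dropped.

## Robustness, vulnerability, cohesion

* **Robustness**: remove ⌈fN⌉ nodes (uniformly at random, averaged over
  seeded repetitions, or by descending degree with id tie-break), then
  iteratively remove nodes that have lost all their edges (secondary
  extinction; nodes isolated in the original graph are never counted as
  secondary losses). Default grid f = 0 … 0.95 step 0.05, 100 random
  repetitions — enough to resolve the curves at this network size.
* **Vulnerability**: `V_i = (E(G) − E(G−i))/E(G)` with E the mean inverse
  shortest-path length over all pairs (1/∞ = 0); network vulnerability is
  the maximum `V_i`. Undefined (error) when E(G) = 0.
* **Cohesion**: observed pairwise Spearman ρ across a site's samples minus
  the mean of 500 taxon-shuffle nulls (each taxon's values permuted
  independently, preserving marginals). Taxon connectedness is the mean of
  the positive (resp. negative) corrected correlations over all m−1
  partners, zeros included; per-sample cohesion weights connectedness by
  relative abundance; total = positive + |negative|. Spearman is the
  default correlation (config-switchable to Pearson, the original flavour
  of the method). Note a finite-sample property: with n = 36 samples the
  positive-part mean of a null-corrected correlation is strictly positive
  (≈ 0.06) even for independent taxa, so *absolute* cohesion values carry
  a baseline; comparisons between communities measured at the same n are
  unaffected, and the signed mean corrected ρ is centred at zero (the
  calibration the tests check).

## Functional traits

KO level-2/3 read tables are normalised to relative reads per sample,
converted to D-values, and networked at the stricter 0.75 threshold. The
broad/specialized classification ships as an editable YAML resource
(case-insensitive lookup; unknown names are left unclassified). Core
functions are the maximal-degree nodes (all ties reported). Ordinary least
squares of the AVD series on each function's D-series gives the direction
of the stability effect (positive slope = destabilising). Permutation
importance for a joint linear model is provided as a deterministic,
seeded alternative to random-forest importances: the importance of a
predictor is the mean RSS increase when its column is permuted,
normalised to sum to 100 %; per-predictor RNG streams are keyed by
predictor name so the ranking is invariant to column order.

## Synthetic community generator

The generator plays the role of the study system: everything downstream is
validated against its planted structure.

Per sample *s* and taxon *i*, the expected proportion is a softmax over

```
μ_i(s) = evenness_site · base_i + stage_effect(stage(s), i) + coupling_i · (a_s − 1)
```

multiplied by a bounded linear-scale response

```
1 + 0.98 · tanh( a_s · [ ρ_m · F_m(s) · sign_i + σ_site · r_i(s) ] / 0.98 )
```

with counts drawn multinomially at depth 50 000. The parts:

* `F_m` — per-module latent factors, Gram–Schmidt-orthonormalised across
  modules and across the two site blocks, so planted modules are *exactly*
  uncorrelated and every module's realised edge density sits at its
  nominal level rather than fluctuating with 36 factor draws.
* `sign_i` — negative with probability q solving `2q(1−q) = neg_edge_frac`
  (default 0.17), so the *edge*-level negative fraction of inferred
  networks matches the target.
* `r_i(s) = ±1` — taxon-private two-point noise scaled by `σ_site`
  (site A twice site B by default). Two-point noise on the linear scale
  makes replicate disagreement bimodal, which is exactly the signature the
  AVD statistic detects; Gaussian or log-scale noise of any amplitude
  leaves AVD nearly unchanged because the per-taxon standardisation
  removes scale and the lognormal tail suppresses the mean |z|.
* `a_s` — a lognormal per-sample disturbance amplitude multiplying the
  whole response, so a disturbed replicate is visibly disturbed across
  many taxa at once and the per-sample AVD series tracks it.
* Hubs (5 by default) respond strongly to the largest module's factor with
  weak cross-module response and little private noise: they carry the
  highest degree and hub centrality in inferred networks.
* One stabilizer taxon (`coupling < 0`) and three destabilizers
  (`coupling > 0`) tie abundance to the disturbance amplitude, providing
  ground truth for the stability-correlation analyses; the planted
  specialized functions (nitrogen/sulfur metabolism, atrazine degradation)
  are carried by the destabilizer taxa only.
* `module_rho` defaults to 0.55 on the linear scale, which yields
  within-module Spearman correlations around 0.6 after noise and counting
  error — the regime a 0.6 edge threshold presupposes. Site A is also
  given a wider log-baseline spread (evenness ratio 1.25), making site B
  both the more stable and the more diverse site.

Function tables are `incidenceᵀ · counts` with Poisson perturbation; broad
functions are carried by most taxa with a shared enrichment in the hub
module (they become the network's core functions), other functions are
enriched in one module each.

Measured recovery at the default conditions (30 seeds): AVD site ordering
30/30; all five hubs in the top-5 hub list in 28/30 runs (per-hub rate
95 %); module-partition ARI mean 0.80; negative-edge fraction 0.148
against the 0.17 target.

**What the generator does not emulate.** Real compositional count data
with taxon-specific overdispersion, phylogenetic correlation,
environmental covariates, uneven sequencing depth and rarefaction
artefacts; its modules are cleaner and its noise more symmetric than
nature's. Passing the recovery tests shows the *machinery* extracts
planted structure at realistic effect sizes and sample counts — it does
not certify sensitivity on any particular real dataset.

## Numerical and determinism notes

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the generator derives independent streams
  for structure, community and functions from `SeedSequence` spawns, so
  the truth record is reproducible without regenerating tables.
* Louvain is seeded; module labels, node orders, TSV float formatting and
  JSON key order are all fixed, making full pipeline reruns byte-identical
  under the same config and seed.
* Degenerate inputs are errors, not silent NaNs: all-zero sample columns,
  groups without variable taxa, graphs with zero efficiency, fewer than 5
  observations for correlation p-values.
* Ties: top-N taxon ranking breaks by mean abundance then id; keystone
  lists by metric, degree, id; targeted removal by degree then id.

## Known limitations

* The Spearman edge test's t-approximation is mildly anticonservative at
  n = 36 (type-I ≈ 0.012 at nominal 0.01); exact permutation p-values are
  available but quadratic in cost.
* APD and efficiency use unweighted shortest paths; edge weights are
  carried as attributes only.
* Cohesion's positive/negative split has the finite-sample baseline noted
  above; interpret absolute levels only within a fixed design.
* Chao1/ACE require integer counts and are meaningless after relative
  normalisation; the API refuses rather than guesses.
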