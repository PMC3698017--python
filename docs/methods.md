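# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the choices made where the design was genuinely
open. Everything empirical stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external runs.

## Network model

All networks are undirected simple graphs over string gene identifiers.
Self-loops are dropped at construction (with a logged warning) and
duplicate edges collapse; a transcriptional network's edge directions are
discarded on input. Quantities that are undefined for a node or network
(clustering of a degree-1 node, assortativity of a regular graph) carry
NaN rather than a substitute value and are excluded pairwise from
downstream correlations.

### Structural descriptors

* **Edge density** `2E / (N(N−1))`; accepts explicit `(N, E)` counts so
  printed summary-table rows can be checked without the underlying graphs.
* **Giant component**: largest connected node set; ties broken by the
  lexicographically smallest member, for reproducibility.
* **Assortativity**: Pearson correlation of endpoint degrees over the
  doubled edge list (each edge in both orientations). NaN when either
  marginal is constant — regular graphs and perfect matchings have no
  degree–degree correlation to measure.
* **Degree histogram**: relative frequencies over nodes of degree ≥ 1.
  Degree-0 nodes are excluded because the fit operates in log–log space
  where `log 0` does not exist.
* **Power-law fit**: least squares of `log10 p_k` on `log10 k` over all
  observed points, each point weighted by its relative frequency, with
  `α = −slope`. The weighting is deliberate: at the sparse tail a degree
  is only *observed* when its empirical frequency overshoots the law
  (zero-count degrees are invisible), so an unweighted fit is biased
  shallow by well over half a unit of α even on exact power-law samples;
  frequency weights remove that selection effect and leave collinear
  (exact) histograms fitted exactly. Recovery of α ∈ {2, 3} within ±0.3
  from 10,000-draw samples is asserted in the test suite. No tail
  truncation or k_min is applied.

### Centralities

Degree; unnormalized shortest-path betweenness with even splitting over
equal-length paths; local clustering (transitivity) with NaN for degree
< 2; closeness `1 / Σ_j d(i, j)` where unreachable pairs contribute `d = N`
(so scores remain comparable across components); and hub score. The hub
score is the principal eigenvector of `A·Aᵀ` scaled to maximum 1. For a
symmetric adjacency matrix the top eigenspace of `A·Aᵀ = A²` is spanned by
A's extremal eigenvectors and is *degenerate* whenever the spectrum is
symmetric (any bipartite component: stars, paths, trees), in which case a
raw eigendecomposition returns an arbitrary basis vector. The
implementation therefore computes A's Perron eigenvector directly — the
canonical nonnegative representative of that eigenspace — which is also
what alternating hub/authority power iteration converges to on connected
non-bipartite graphs (asserted to 1e-8 against 10,000 iterations).

## Interface overlap

Networks are first restricted to their common genes. The shared-edge
percentage is `100·|E_a∩E_b| / |E_a∪E_b|` (reported to 1 decimal). The
overlap test is the standard two-set hypergeometric upper tail
`P(X ≥ k)` with population `N = C(p, 2)` over the `p` common genes,
`m = |E_a|`, `n = |E_b|`, `k = |E_a∩E_b|` — network a marks pairs, network
b draws pairs. The test is symmetric in the two networks and exact; no
normal approximation is used. Reported `p = 0` from extreme overlaps is
floating-point underflow of the exact tail, not a literal zero.

## Enrichment

* **GEA**: per term, hypergeometric upper tail with gene population
  `N = |universe|`, `m = |term ∩ universe|`, `n = |interest|`,
  `k = |interest ∩ term|`. The universe is restricted to annotated genes
  by default — genes that cannot be annotated carry no information about
  term membership and only dilute the background.
* **Global GPEA**: the population is gene *pairs* of one network,
  `N = p(p−1)/2`, `m = p_GO(p_GO−1)/2`, `n` = edges, `k` = term-internal
  edges.
* **Interface GPEA**: the same tail over the edge union of two networks:
  `N = |E_a∪E_b|`, draws `n = |E_a∩E_b|`, `m` = term-internal union
  edges, `k` = term-internal shared edges. With no shared edges every term
  reports p = 1 with a warning rather than an error.

Term-size filters apply to annotated genes present in the tested network,
not the raw term size. Default significance regimes, all config-exposed:
global GPEA Bonferroni α = 1e-4, interface GPEA BH fdr = 0.01,
per-chromosome GEA nominal α = 0.01. Adjustment methods are Bonferroni
`min(1, pM)` and Benjamini–Hochberg step-up (via statsmodels), input order
preserved. Only the classic hypergeometric statistic is provided; DAG-aware
variants (elim/weight-style) and ancestor propagation are out of scope —
annotations are assumed already propagated by the provider or generator.

The fraction of common significant terms between two networks is the
Jaccard index of their adjusted-significant term sets (terms significant
in both over terms significant in either), NaN when neither network has a
significant term.

## Co-occurrence

Per edge, `d` counts terms annotating both endpoints; normalization
divides by the maximum over edges (0 if the maximum is 0). The CDF is the
plain empirical CDF including zero-score edges, plotted from the origin;
no recentering or subtraction is applied (the stochastic-dominance
comparisons are unaffected by that choice). Reference ensembles permute
node identities uniformly over the fixed topology — equivalent to
permuting the annotation assignment — preserving the degree sequence and
the annotation multiset exactly; R defaults to 100.

## Pathway-level centrality correlation

Centralities are computed once on the full common-gene networks and then
subset to each term's genes — the measures are meant to describe a gene's
role in the whole network, not in an excised fragment; an
``on_term_subgraph`` flag switches to term-induced subgraphs for the
alternative reading. Per qualifying term
(default 11 ≤ size ≤ 1000 common genes) the two value vectors are compared
by Spearman correlation with average ranks for ties; NaN entries
(undefined transitivity) are dropped pairwise. Terms whose vector is
constant in either network cannot be rank-correlated: they are reported
with NaN and excluded from the BH family rather than assigned a pseudo-p.
FDR defaults to 0.05.

## Chromosomal analysis

Coordinates are 1-based inclusive; BED input is converted at the reader.
Midpoints are real-valued. Relative distance divides the midpoint distance
by the chromosome length; each chromosome carries an explicit
circular/linear topology flag so both prokaryote-style (wrapping,
`δ ≤ 0.5`) and eukaryote-style (linear, `δ ≤ 1`) genomes are handled; the
generator defaults to circular. Genes without loci are excluded per
analysis and counted in the report, never imputed. Gene pairs on different
chromosomes yield a not-co-located signal (`None`), not an exception.
Reference distances: 'adjacent' is the mean δ over consecutive genes
sorted by midpoint per chromosome, 'global' the mean over all
same-chromosome pairs. Distribution comparisons use the two-sample KS test
(asymptotic p) and per-chromosome one-way ANOVA of mean distances across
networks, Bonferroni-corrected over chromosomes; chromosomes without at
least two groups of two values, or with zero within-group variance, are
skipped with a warning.

## GRN inference

* **B-spline MI.** Each profile is min–max scaled onto `[0, M−k+1]` for
  `M` bins and spline order `k`; the knot vector repeats the boundary
  knots `k` times so exactly `M` basis functions partition unity. Each
  observation spreads unit weight over adjacent bins by the basis values;
  joint frequencies are `WᵀW/n` products of the two weight matrices and
  MI is the plug-in value in nats. Order 1 is exact hard binning (verified
  against an independent histogram plug-in oracle). Defaults: order 3,
  `M = round(n^(1/3))` clamped to [4, 10] — the cube-root rule balances
  resolution against per-bin occupancy at the sample sizes the estimator
  sees here. Constant vectors return MI 0 with a warning.
* **C3NET.** Each gene contributes at most one edge, to its maximum-MI
  neighbor (lexicographic tie-break), kept only if that MI is significant
  against a permutation null: pooled across gene pairs, each draw permutes
  one profile's sample order, destroying dependence while preserving
  marginals. Bonferroni over the `C(g, 2)` tested pairs; when the
  corrected level is finer than the null's `1/(n_perm+1)` resolution the
  cutoff saturates at the null maximum (the conservative standard for
  permutation tests). Default n_perm = 1000 (minimum 10). The output is
  the deduplicated union of per-gene selections, hence at most g edges.
* **BC3NET.** B bootstrap resamples of the samples (default 100) each
  yield a C3NET network; per-bootstrap randomness comes from spawned
  substreams of the user seed, so changing B or n_perm cannot silently
  reorder other streams. An edge seen `b` times is kept when the one-sided
  binomial tail `P(X ≥ b | B, p0)` passes Bonferroni-corrected α = 0.05
  over the ensemble's distinct edges. The null rate p0 is the ensemble
  mean edge density, total occurrences `/ (B·C(g, 2))` — the test asks
  whether an edge recurs more often than uniform placement of the
  ensemble's edge mass would produce. p0 is logged with every run; it is a
  package choice, as the aggregation null has no unique canonical
  definition.

## Synthetic data

Every generator is a pure function of (configuration, seed); seeds feed
`numpy` `SeedSequence` substreams.

* **Networks**: configuration model over degrees drawn from a discrete
  power law `p_k ∝ k^−α`, `k = 1..kmax`, with kmax tuned (up to the
  structural cutoff `√(2E)`) so the law's mean approaches `2E/n`; residual
  mass is repaired with unit nudges and edges lost to simplification are
  topped up between deficit-weighted endpoints, so the requested count is
  met exactly. A pure power law with minimum degree 1 *fixes* the mean
  degree, so arbitrary `(n, E)` requests bend the distribution's head;
  `natural_edge_count(n, α)` returns the undistorted operating point,
  which the exponent-recovery tests use. The configuration model was
  chosen over preferential attachment because the exponent is a direct
  input.
* **Network pairs**: a uniform sample of the base's edges is retained at
  the requested fraction, the remainder rewired to uniform non-base pairs
  over the same nodes.
* **Annotations**: background terms are uniform gene samples; planted
  terms grow along network edges (absorbing neighbors of current members),
  so their internal edge count exceeds the hypergeometric expectation for
  their size.
* **Loci**: genes placed uniformly on chromosomes of configurable length
  and topology. Planted cis-structure re-targets a fraction (default 0.6)
  of edges to same-chromosome partners sampled with weight
  `exp(−δ / cis_strength)`; the rewired copy is returned next to the map,
  the input network is never mutated.
* **Expression**: a uniform node permutation orients the truth network
  into a DAG; parentless genes are standard normal, every other gene is a
  signed weighted parent sum (weights ±[0.5, 1.0]) plus Gaussian noise,
  and each gene is rescaled to unit variance as generated, so `noise_sd`
  is relative to unit regulatory input at every cascade depth and the
  noise → ∞ limit genuinely decouples all genes. Default
  `noise_sd = 1.5`: a single regulator then explains ~10–30% of its
  target's variance, emulating noisy expression data in which inference
  quality still improves visibly between 100 and 400 samples rather than
  saturating. This linear-Gaussian scheme creates the mutual-information
  structure the inference stage assumes; it does not model transcription
  kinetics, saturation, or platform-specific noise, so passing recovery
  tests demonstrate correctness of the machinery under the stated
  dependency model, not performance on real microarray data.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: networks of
20–5000 genes, 10-seed replicate sets, 100-replicate null calibrations,
bootstrap ensembles of B = 20 with 1000-draw permutation nulls. These sizes
were chosen so each experiment's verdict (rank-1 recovery, rejection
fractions, median F1) is stable across seeds while the whole suite stays
interactive; the statistics themselves are size-agnostic.

## Known limitations

Directed and weighted analyses are out of scope; all inputs are reduced to
undirected simple graphs. GEA/GPEA assume annotation propagation has
already happened. The KS p-value is asymptotic and approximate below ~20
distances per group. The inference stage estimates an undirected skeleton
only, and its binomial aggregation null (p0) is a package definition, not
a community standard. The synthetic expression generator's independence
and linearity assumptions are idealizations; see above for what recovery
results do and do not show.
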