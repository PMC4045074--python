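# Methods

`aquadyn` analyzes monthly OTU-level monitoring campaigns of a drinking
water treatment plant (DWTP) and its distribution system (DWDS). This
note documents the models, the numerical choices, what the synthetic
generator does and does not emulate, and the problem sizes the test
suite and `scripts/acceptance.py` run at.

## Rarefaction and diversity

Every diversity and association analysis operates on rarefied tables:
each event draws, per sample, a fixed depth of reads without
replacement (multivariate hypergeometric). Event *e* of a plan is
seeded `base_seed + e`, so individual events are reproducible in
isolation and pipelines can stream events twice instead of holding them
in memory. Samples shallower than the depth are dropped once, up
front, with an itemized report. Defaults are 100 events for the
association and occupancy stages and 1,000 for headline diversity
matrices; both are configurable, and the test suite uses 5–20 events
(see "Problem sizes" below).

Alpha metrics: observed richness; Shannon entropy H = −Σ p ln p
(natural log); Shannon evenness H / ln(richness), defined as 0 at
richness 1; and the Chao–Shen coverage-adjusted ("nonparametric")
Shannon estimator, with coverage C = 1 − f₁/n, adjusted proportions
C·pᵢ, and Horvitz–Thompson weights 1 − (1 − C·pᵢ)ⁿ. When every read is
a singleton (C = 0) the coverage is floored at 1 − (f₁ − 1)/n to keep
the estimator finite.

Beta metrics: Bray–Curtis (Σ|x−y| / Σ(x+y)) and Jaccard (1 −
shared/union on presence) via scipy; unweighted and weighted UniFrac
via scikit-bio, with the branch-length normalization that bounds the
weighted variant in [0, 1]. UniFrac metric values are averaged over
rarefaction events (not the underlying abundances), matching how the
per-event protocol composes with every other metric.

PCoA is the classical Gower double-centering eigendecomposition.
Negative eigenvalues — routine for semi-metric dissimilarities — are
reported, and their axes kept as separate "imaginary" coordinates.

## Permutation statistics

PERMANOVA (pseudo-F on squared distances, R² = SS_between/SS_total),
ANOSIM (rank-based R with average ranks for ties, denominator
n(n−1)/4), Mantel (Pearson r of off-diagonal vectors, p by permuting
one matrix's rows and columns), and beta-dispersion are implemented
directly on the distance matrix. Every permutation p-value uses the
(1 + b)/(1 + n) estimator and is reproducible from a seed; each test
also has an exhaustive mode that enumerates all label permutations
(n ≤ 8), which the test suite compares against independent brute-force
oracles. scikit-bio's implementations serve as cross-checks in tests,
never as the implementation.

Beta-dispersion embeds the matrix by PCoA keeping the
negative-eigenvalue axes, computes each sample's distance to its group
centroid with the imaginary-part correction d² = d²_real − d²_imag
(clipped at 0), and runs one-way ANOVA plus Tukey HSD (statsmodels) on
those distances. Singleton groups get distance 0 and a flag; a
grouping with zero within-group spread flags the ANOVA as undefined
rather than reporting an infinite F.

Core-OTU selection filters OTUs by grand-mean relative abundance or by
detection frequency, rebuilds Bray–Curtis on the retained counts
(without renormalizing, as the upstream tooling does), and reports the
Mantel r against the full-table matrix per threshold; thresholds
retaining fewer than 3 OTUs, or emptying a sample, are flagged with r
omitted.

## Spatial analysis

The pipe inventory becomes an undirected graph whose edges carry length
(m), wetted surface π·d·L (m²), age at a configurable reference date,
and material. Between two locations the "water path" minimizes total
length; ties break by smaller total surface, then lexicographic node
sequence, for determinism. Age-weighted metrics are defined as
Σ(metric_e × age_e) — length-years and surface-years — since the field
usage names but does not define them; the per-edge quantities are
exposed so a mean-age alternative is a one-line change.

Distance decay correlates each path metric with community dissimilarity
over all location pairs within a sector. The location-level matrix is
the campaign average of *month-matched* sample pairs: averaging
cross-month pairs would let seasonal turnover swamp the spatial signal
(we measured exactly this on synthetic campaigns: r ≈ 0.5 unmatched
versus r ≈ 0.95 matched on the linear sector).

Site-specific OTUs are those detected (pooled over the campaign) at
exactly one location; fractions are over each location's detected
membership and pooled reads.

## Time-lag analysis

For each location, all within-location sample pairs are binned by
|month_i − month_j| and pooled across locations; the curve reports the
mean, population variance and pair count per lag. The three
consecutive sampling days of a month are treated as one time point.
DWTP divergence is the distance of each DWDS sample to the same-month
plant sample, aggregated per location and sector; months without a
plant sample are skipped with a warning.

## MIC association networks

MIC scans axis-aligned a×b grids with a·b ≤ B(n) = max(n^0.6, 4) and
maximizes I/log min(a, b). The heuristic search equipartitions one
axis, restricts the other axis's cut points to clump boundaries
(maximal single-row runs in sort order, capped at 15·a superclumps) and
optimizes the column partition by dynamic programming; mutual
information decomposes additively over columns, so the DP is exact
given the clump restriction. Both orientations are searched. For
n ≤ 10 an exhaustive enumeration of all admissible grids is used
instead, and doubles as the oracle the heuristic is tested against.
The one-axis equipartition means the heuristic can undershoot the
exhaustive optimum on small noisy inputs; it never overshoots.

The robustness protocol, per rarefaction event: only OTUs with
detection > 30% in *every* event are considered; a pair is tested only
if jointly detected in ≥ 70% of samples, with an absolute floor of 21
points; an edge must be discovered (MIC > 0.4 and Bonferroni-corrected
p < 0.05) in ≥ 10 events with the same OLS slope sign every time (the
slope is fitted on jointly detected samples). Events with fewer samples
than the floor yield no testable pairs and a warning. MIC itself is
computed over all samples of the event; the co-occurrence gate only
selects which pairs are tested.

P-values: because MIC depends only on the joint ranks of its inputs,
its permutation null is (up to count ties) a function of n alone, so a
single null pool per event (default 300 shuffled surrogate pairs) is
shared by all pairs of that event. Bonferroni correction over
thousands of pairs demands p-values far below the pool's 1/(n+1)
resolution, so the pool's tail beyond its 90th percentile is
extrapolated with a generalized Pareto fit (the standard
peaks-over-threshold device for permutation tests), with a hard floor
tied to the pool size and a fallback to the empirical estimator if the
fit degenerates. A per-pair permutation p-value remains available on
`mic()` itself. The pool's seed is derived from the event's *content*
(a CRC of its counts), which makes the network invariant to the order
of events and of OTU columns.

Cluster extraction takes connected components of the positive-edge
subgraph, after setting aside "connector" nodes: articulation points
that participate in no positive triangle and whose removal leaves ≥ 2
components of size ≥ 2. Genuine hubs survive (their satellites fall
apart into singletons) and clique members survive (they sit in
triangles); a long path-shaped cluster could be split by this rule, a
known limitation. Nodes with only negative edges are "unassigned",
degree-0 nodes "isolated", and any within-cluster negative edge is
reported in a validation list. Network statistics (density over
connected nodes, mean local clustering coefficient with degree < 2
contributing 0, per-cluster density) use the unsigned graph.

The phylogenetic contrast between two clusters is unweighted UniFrac of
their membership profiles, with a label-shuffling permutation p.

## Occupancy–abundance models (IOAM)

Per OTU and month: μ = mean relative abundance over the month's samples
and f = detection frequency, each averaged over rarefaction events;
zero-μ points are dropped. Five one-parameter laws (shape β fixed at
1) are fitted by maximum likelihood: Poisson 1 − e^(−μ) (no free
parameter; evaluated, not fitted), Nachman 1 − e^(−αμ),
Hanski–Gyllenberg αμ/(1 + αμ), power min(αμ, 1), and negative binomial
1 − (1 + μ/k)^(−k).

The central modeling decision: because f is an average over events, the
occupancy count o = f·n_sites is fractional, and the likelihood
Σ [o ln P + (n − o) ln(1 − P)] treats the month's sites as binomial
trials with fractional successes. Points with f = 0 are accepted when
supplied (they are informative o = 0 observations for data simulated
directly from a law); pipeline-derived points always have f > 0 since
μ > 0 implies at least one detection. P is clipped to
[1e−12, 1 − 1e−12] with the clip count reported; the power law's clip
at 1 lives inside the likelihood. Optimization is bounded scalar
search over ln α ∈ [ln 1e−6, ln 1e9] with xatol 1e−10; a solution at a
bound is flagged "boundary". Goodness of fit is reported as both the
mean and the sum of |f − P|. An alternative likelihood weighting every
(μ, f) point equally, rather than by n_sites, would change little here
(n_sites is nearly constant across months) and is not implemented.

The monthly envelope fits the Hanski–Gyllenberg α per month, then
repeatedly (default 1,000×) shuffles month labels among samples within
each location, rebuilds the per-pseudo-month points from the
event-averaged profiles, refits, and reports the min/Q1/Q3/max of the
permuted α per month against the observed value.

## The synthetic generator

`generate(SyntheticSpec(...))` emulates the processed artifacts of a
15-month, 10-location (DWTP + 3 sectors × 3) campaign: defaults are
4,369 OTUs, per-sample depths lognormal (median ≈ e^7.8 ≈ 2,440,
clipped to [834, 16,817]), two anti-phase seasonal clusters of 24 and
32 OTUs with a 12-month period (winter peak December, summer peak
June), a Hanski–Gyllenberg occupancy law at α = 896, an 881-section /
46 km pipe inventory over the three-sector layout (sector 1 linear,
sectors 2 and 3 branched), and a 15% slice of the OTU pool reserved as
location-specific taxa.

Planted structure, and how it was calibrated:

* **Abundances** are lognormal (σ_log 2.5). The cluster members are
  the community's *dominant* OTUs and jointly hold a configurable share
  (default 55%) of expected reads, with a σ_log 1 spread — real
  seasonal clusters are led by the most abundant genera, and without
  this concentration the members fail the 70% co-occurrence gate and
  the planted network is undiscoverable at survey depths. The seasonal
  amplitude (±1.2 on the log scale, ≈ 3.3× swing) keeps members
  detectable year-round, which is what allows cross-cluster (negative)
  associations to be tested at all.
* **Spatial drift** is a random walk along the pipe layout: each link
  carries independent per-OTU log-abundance increments with variance
  proportional to its length, so expected divergence between any two
  locations grows with the pipe length of the path between them — a
  genuine planted distance decay on the tree-shaped network. The
  drift is confined to non-member OTUs (the seasonal members'
  co-fluctuation stays intact, and the decay signal averages over
  hundreds of taxa), with the default rate (0.006 per √meter) keeping
  the location PERMANOVA R² near 0.1 — spatial effects weak relative
  to temporal, as real systems show. Because the drift field is a
  *single realization* weighted by a highly skewed abundance
  distribution, a 3-pair within-sector correlation remains seed-noisy
  even though the expectation is strictly monotone; the 36-pair
  all-location correlation is the stable readout and the one the tests
  assert on.
* **Location-specific OTUs** are drawn from a moderately abundant band
  of non-members (below the top decile) so they are detectable at their
  home location.
* **The occupancy law** is imposed by thinning: for each OTU-month the
  retention probability r solves r·P_detect = P_model(α, r·μ), where
  P_detect is the expected detection under multinomial sampling at the
  mean depth — thinning lowers both the realized mean abundance and the
  detection frequency, and the solver accounts for both. Presence is
  then Bernoulli-thinned per sample.

What the generator does **not** emulate, and hence what passing tests
do not show about real data: sequencing error, chimeras and PCR bias
(out of scope upstream); spatially *correlated* absence patterns
(thinning is independent per sample, which slightly weakens MIC signal
relative to real co-fluctuation); the conditioning bias of observed
occupancy points (μ is only observed when detected), which pulls the
refitted α below the planted value by ~20–30% at survey depths — the
law's *form* is still recovered as the top-ranked model; and a
seasonal community whose monthly α stays inside the month-permutation
envelope (the paper-like "stable α despite seasonality" requires
seasonality in composition but not in the abundance-to-detection link,
whereas the generator's thinning tracks the seasonal μ exactly; the
envelope's null behavior is therefore validated on stationary
campaigns). Fidelity of α recovery itself is validated by
`simulate_occupancy_points`, which draws (μ, f) directly from the law
with binomial occupancy and recovers α = 896 to well under 15% median
relative error.

`worked_fixture()` ships a 6-OTU × 8-sample miniature with hand-derived
Bray–Curtis, Jaccard, richness, Shannon and MIC constants.

## Pipeline and reproducibility

`run_all(RunConfig(...))` executes rarefy → diversity → stats / spatial
/ temporal → core-select → associate → ioam, writing CSV tables,
PHYLIP distance matrices and a GraphML network plus a manifest of
SHA-256 hashes and the resolved config. The master seed derives each
stage's seed by hashing the stage name, so toggling one stage never
perturbs another. Two runs with the same config and seed produce
hash-identical outputs.

## Problem sizes used by tests and the acceptance script

Simulations are scaled so the whole suite runs on one CPU in minutes,
as the package's own choice of desk-scale defaults:

* occupancy-law recovery: the full stated size — 4,000 OTUs × 15 months
  × 10 sites, 20 replicates (tests) / 10 replicates (script);
* cluster recovery: 400-OTU campaigns, 20 rarefaction events, with the
  protocol thresholds (detection 30%, co-occurrence 70%, MIC 0.4,
  Bonferroni 0.05, ≥ 10 discoveries) unchanged — note 10 of 20 events
  is *stricter* than 10 of 100;
* diversity / lag / decay summaries: 5-event averages;
* null-behavior envelope: 300-OTU stationary campaigns, 999 (tests) /
  499 (script) permutation replicates.
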