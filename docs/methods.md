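# Methods

This note documents the models and procedures implemented in `myconet`,
the parameter choices that matter, and what the synthetic-data tests do
and do not establish about real data.

## Study design assumed

The pipeline is organized around a grouped field design: categorical land
use (DG desert grassland, SL shrubland, RL cropland converted from
grassland) crossed with season (Apr, Sep), with replicate sites per group
(default 9, so 54 samples). The central object is a samples × OTUs count
table; sample metadata carries the design factors and ten soil variables
(pH, EC, SWC, TC, TN, TP, TOC, AN, AP, AK). All stages operate per group
where the design matters (networks) and pooled where comparability
matters (NCI scaling, PCA).

## Diversity

*Rarefaction* subsamples every sample, without replacement, to the
minimum observed depth, drawing uniformly from the sample's read pool;
given a seed the result is deterministic. Rarefaction is off by default —
networks and profiles run on raw counts, with a config flag to rarefy
first — because compositional steps downstream (CLR) do not require equal
depths, while the alpha indices are depth-sensitive and can be computed
on a rarefied copy.

*Shannon* uses the natural log by default (configurable base); *ACE*
follows the standard Chao & Lee form with the conventional rare cutoff of
10 and the coefficient-of-variation term truncated at zero. When every
rare individual is a singleton the sample coverage is zero and ACE is
undefined; the implementation raises rather than guessing (Chao1 would be
the fallback). *Bray–Curtis* and the *Hellinger* transform are standard.

*NMDS* minimizes Kruskal stress-1 by non-metric SMACOF (scikit-learn),
with one classical-scaling start plus random restarts, keeping the
lowest-stress solution. Exact zero dissimilarities between distinct
samples are nudged to 1e-12 because non-metric SMACOF treats zeros as
missing. Ordination follows Hellinger standardization, then Bray–Curtis,
then NMDS, in that order. Stress below 0.2 is the conventional
acceptability rule and is what the test suite checks on generated data.

*Mantel* correlates the lower triangles of two distance matrices
(Spearman by default), with significance from simultaneous row/column
permutations of the second matrix, one-sided (greater):
`p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`. Environment variables enter
as Euclidean distances on z-scored values — the metric is not dictated by
the design, and z-scored Euclidean is the least-committal default for
variables on incommensurate scales.

## Co-occurrence networks

Per group, in order: (1) prevalence filter — keep OTUs with nonzero
counts in at least `ceil(7/9 × n)` of the group's samples (the "7 of 9
replicates" detection rule); (2) centered log-ratio transform with
pseudocount 1 (counts are compositional; CLR removes the shared-total
constraint that induces spurious negative correlation); (3) all-pairs
Spearman correlation with average-rank ties, p-values from the t
approximation, constant columns flagged and zeroed. Filtering precedes
CLR so the geometric mean is not dominated by structural zeros.

Edges are kept where `|r| ≥ t` (closed rule; the open `>` variant differs
only on exact floating-point ties). Isolated OTUs are not network nodes:
"total nodes" counts only nodes with at least one incident edge, the
convention under which published average degrees equal `2E/N`.

### Threshold selection

Two modes. `fixed` (default 0.9) applies a hard cutoff. `rmt` scans
thresholds (default 0.30–0.99, step 0.01) and, at each, zeroes
sub-threshold entries, drops isolated variables, and tests whether the
nearest-neighbour spacing distribution (NNSD) of the unfolded eigenvalues
matches the Poisson law `e^(−s)`: spacings are histogrammed on [0, 3]
with 30 bins (low-expectation bins merged) and compared by chi-square;
the chosen threshold is the smallest with p > 0.05. The rationale is the
universality result that correlated (GOE-like) spectra show level
repulsion while uncorrelated ones show Poisson spacings; the transition
point separates signal from noise without an arbitrary cutoff.

Unfolding is the numerically delicate step. The implementation fits a
least-squares cubic spline with a small number of interior knots placed
at eigenvalue quantiles (n/8, clamped to 3–10) to the empirical spectral
CDF, and evaluates spacings on *distinct* eigenvalues only. Two failure
modes motivated this: a near-interpolating spline (e.g. smoothing chosen
by GCV against the step CDF) flattens all spacings to ~1 and rejects
genuinely Poisson spectra, and graph-structural eigenvalue multiplicities
(stars and isolated dyads pin eigenvalues at exactly 1) produce zero
spacings that carry no level-statistics information. The per-threshold
test requires at least 10 distinct eigenvalues; the scan itself requires
at least 20 OTUs. Identity-like spectra raise a flagged error.

### Topology record

Modules and modularity come from deterministic greedy (CNM)
agglomeration on the unsigned graph. The power-law R² is ordinary least
squares on log frequency vs log degree over degrees with nonzero
frequency. Average path distance averages shortest-path lengths over
connected ordered pairs; geodesic efficiency averages 1/d over all
ordered distinct pairs with unreachable pairs contributing zero. Both are
verified against a Floyd–Warshall oracle in the tests.

## Network complexity index

Each sample's subnetwork is the group network induced on the OTUs with
nonzero count in that sample. Six features: node count, edge count,
density `2E/(N(N−1))`, transitivity, and the reciprocals of diameter and
average path length, the latter two computed on the largest connected
component. "Inverse form" is read as the reciprocal 1/X — the only
reading that makes the two distance features co-directional with
complexity (tighter graphs → larger values), and it gives a natural zero
for disconnected or sub-2-node cases. Degenerate subnetworks (< 2 nodes
or no edges) contribute zeros for density, transitivity, and the inverse
fields.

Features are pooled over all samples (all groups together, so scores are
comparable across groups), z-scored, and decomposed by SVD-based PCA; the
NCI is the PC1 score with the sign oriented so the loading on edge count
is non-negative. Zero-variance columns are dropped with a record; an
all-constant feature matrix yields all-zero scores and a degenerate flag.
Pooled z-scoring makes the index invariant to affine rescaling of any raw
feature. A config switch builds a single all-sample network instead of
per-group networks for subnetwork extraction.

## Guilds

A FUNGuild-style lookup table (taxon, rank, trophic modes, guild,
confidence in {Possible, Probable, Highly Probable}) is searched for each
OTU from species up to phylum; the most specific record at or above the
confidence filter (default Probable, FUNGuild's recommended practice)
wins. Multi-mode records ("Pathotroph-Saprotroph") contribute the OTU's
full abundance to each listed mode, so per-sample mode shares are
reported per mode and may sum above 1 — they are deliberately not a
partition. Arbuscular-mycorrhizal and ectomycorrhizal shares are
guild-level subsets (both symbiotrophic in the bundled table, so AM ≤
Symbiotroph holds by construction). The bundled table is a small curated
fixture for testing, not a database redistribution; production runs
should pass a real FUNGuild export.

## Group statistics

One-way ANOVA uses the classical F; post-hoc letters come from Tukey HSD
at α = 0.05 via an insert-and-absorb compact letter display. RDA
Hellinger-transforms the community, z-scores the environment matrix,
fits the multivariate least-squares regression of community on
environment, and takes the PCA of the fitted values as the constrained
axes; the constrained proportion is the fitted share of total variance,
and species scores use scaling 2 (eigenvalue-weighted). Collinear
environment columns are rejected by rank check, naming a worst pair.
Random-forest importance for the NCI fits a regression forest (default
1000 trees) on a seeded 70% split and permutes each variable on the
held-out 30% (10 repeats); held-out scoring prevents memorized noise from
inflating irrelevant variables' importance. The Spearman panel reports r,
p, and 0.05/0.01 stars; the Mantel preset reports Benjamini–Hochberg
adjusted p alongside raw p.

## Synthetic communities

The generator produces, per group: a planted co-occurrence graph, latent
log-abundances, and counts. The planted graph is a union of disjoint
mini-cliques (default size 5) meeting the requested edge density, grouped
round-robin into modules. Cliques rather than random edges because a
constant correlation ρ on a graph is positive-definite-feasible only when
ρ ≤ 1/|λ_min(adjacency)| — about 0.25 for sparse random graphs — whereas
disjoint cliques (λ_min = −1) carry any ρ < 1 exactly; cliques are also
the co-occurring-guild motif the analysis is meant to recover. The target
correlation matrix (ρ on planted edges, default 0.8) is repaired to
positive definite by alternating projections (eigenvalue clipping at
1e-6, unit-diagonal restore, up to 50 iterations) — a no-op for feasible
clique targets.

Latent log-abundances are multivariate normal around lognormal
rank-abundance base means (SD 1.2) shared across groups, plus a group
composition offset that lies on a two-axis (land use, season) gradient
(loading SD 0.8 per axis): grouped field communities separate along few
environmental axes, which is what makes their 2-D ordinations
interpretable and keeps NMDS stress well below 0.2. Latents pass through
a softmax to proportions and are sampled multinomially at the target
depth (default 20,000 per sample; real runs of this design sequence
several-fold deeper, but 20,000 preserves every qualitative behaviour the
tests rely on at desk scale). Taxonomy assigns each OTU a phylum from a
mixture dominated by Ascomycota, Basidiomycota, Mortierellomycota,
Glomeromycota, and Chytridiomycota (2% residual across minor phyla), with
60% of OTUs in the major phyla also given a genus from a small pool so
guild lookup can resolve below phylum. Soil variables are group means
plus relative Gaussian noise (SD 5%); the default means encode directions
only — cropland higher in EC, TC, TN, TP, AP, AK; September higher in pH
and SWC — since no quantitative targets exist for them, and their
absolute levels are merely plausible for arid sandy soils.

What the generator does *not* emulate: sequencing error, chimeras,
OTU-clustering artifacts, spatial autocorrelation between sites,
overdispersion beyond multinomial, and realistic phylum–environment
coupling. Passing tests therefore establish that the pipeline recovers
planted structure under the stated noise model, not that it is robust to
every artifact of real amplicon data.

## Numerical and degenerate-input choices

- All randomness flows from one seed through named SHA-256-derived
  substreams per stage, so each stage is independently reproducible and
  full runs are byte-identical under a fixed seed.
- Spearman on a constant column returns r = 0 with a flag instead of NaN.
- Bray–Curtis between two all-zero samples is an error, not 0/0.
- Empty networks yield an all-zero topology record with an `empty` flag.
- Correlation values are clipped to [−1, 1] before thresholding;
  `|r| ≥ t` uses a closed comparison.
- PCA sign ties (zero loading on the orienting feature) fall back to the
  sign of the summed PC1 loadings.

## Problem sizes used in tests and the acceptance script

Planted-edge recovery: 1 group, 50 replicates, 200 OTUs, clique density
0.02, ρ = 0.9, depth 50,000, fixed threshold 0.6. NCI ordering: 3 groups
at planted densities 0.005 / 0.02 / 0.05, 20 replicates, 150 OTUs, depth
20,000, threshold 0.7. Mantel calibration: 20 objects, 199 permutations,
400 replications. RMT block recovery: five 10-variable factor blocks plus
100 independent variables at n = 500. The default design (54 × 600 at
depth 20,000) exercises the full pipeline end to end.

## Known limitations

- The RMT scan's chi-square has low power for small spectra; on heavily
  thresholded matrices it accepts Poisson quickly, so the chosen
  threshold should be read together with the scan table the pipeline
  writes.
- The NCI is a relative index: scores are comparable only within the
  sample set whose pooled z-scoring produced them.
- Tukey letters assume balanced-ish groups and equal variances; no
  Welch or mixed-model alternative is provided.
- Guild profiles depend entirely on the lookup table supplied; the
  bundled fixture covers a handful of arid-soil taxa and is meant for
  tests and demos.
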