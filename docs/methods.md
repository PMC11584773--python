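# Methods

## Scope and model

The package treats a multi-omics experiment as a single layered
feature-by-sample matrix: transcripts, proteins, and three metabolite
classes (primary, secondary, lipophilic) measured over the same samples,
here a 5-group × 3-replicate design (wild type vs mutant across green leaf,
white leaf, stem). The scientific object is the *correlation network* over
all features and the question whether one focal feature occupies a hub
position in it.

### Correlation network

Spearman's ρ is computed exactly as the Pearson correlation of
average-fractional ranks; for tie-free data this equals
1 − 6Σd²/(n(n²−1)). With n = 15 samples, tie-free correlations therefore
live on the grid {1 − k/560 : k ∈ ℤ}; off-grid values can only arise from
ties (the packaged published neighbor table contains exactly one off-grid
value, on a protein node, consistent with tied intensities).

All pairs are evaluated by ranking each feature once, standardizing the
ranks, and forming block inner products, so the result is bit-for-bit the
naive per-pair computation while peak memory stays
O(block_size × (n_samples + block_size)). Pairs with |ρ| below the
streaming prefilter (default 0.75) are dropped as they are produced; the
graph is built at the stricter default threshold 0.95. Both thresholds are
inclusive (≥). Zero-variance features have no defined correlation and are
skipped with a logged count rather than emitted as NaN. Because rank
correlation is invariant to monotone per-feature transforms, the choice of
raw vs wild-type-normalized abundances does not affect the network; only
the imputation convention matters, which is why imputation is part of the
model fit.

### Centralities and the hub test

Degree is the unweighted incident-edge count (the published "degree of 29"
is a neighbor count). Closeness and betweenness are shortest-path metrics;
the edge distance is d = 1/|ρ| by default (stronger correlation = closer),
with d = |ρ| available as `distance_mode="raw_weight"` since the source
analysis states the weights but not the distance convention. Closeness(v)
is (number of vertices reachable from v)/(summed shortest distances), 0 for
isolated vertices; betweenness counts each unordered pair once
(Brandes accumulation via networkx).

Hub status is tested by a two-sided one-sample Wilcoxon signed-rank test of
all *non-focal* nodes' metric values against the focal value as location
(the focal node is excluded from its own comparison distribution — the
source description is ambiguous on this point; exclusion is the
conservative reading). Zero differences are dropped; tied absolute
differences receive average ranks. For ≤ 25 nonzero differences the null
distribution of the positive-rank sum is enumerated exactly by dynamic
programming over doubled ranks (integers even under ties), so the exact
branch is correct in the presence of ties; beyond 25 the normal
approximation with tie and continuity corrections is used. At the branch
point the two agree to within ~0.007 in p. The network location is
summarized by the Hodges–Lehmann pseudo-median (median of all Walsh
averages), computed exactly up to 2000 nodes and from a fixed-seed
two-million-pair subsample beyond.

### Differential features and direction z-score

Benjamini–Hochberg is the classical step-up q_(i) = min_{j≥i} m·p_(j)/j
with stable sorting (tied p-values share adjusted values); it is
implemented directly and cross-checked against statsmodels in the test
suite. A feature is differential when |log2FC| ≥ 1 *and* q ≤ 0.1, both
inclusive, with the fold-change rule read as absolute value since both
regulation directions are reported downstream. The term direction score is
z = (up − down)/√count; the square-root denominator follows the verbal
definition of the statistic (the typeset rendering of the formula in the
source drops the radical).

### Phenotype statistics

Canalization is quantified per observation as |x_i − med(x)|/med(x)
(denominator switchable to the mean); the sample CV is reported alongside
for comparison. The statistic is scale-invariant and zero everywhere iff
all values equal the median.

Pigments: measured absorbances are divided by the plate pathlength
(default 0.51 cm for a filled 96-well) to map onto 1-cm-cuvette equations,
then the standard pure-methanol equations apply —
chl_a = 16.72·A665 − 9.16·A652, chl_b = 34.09·A652 − 15.28·A665,
carotenoids = (1000·A470 − 1.63·chl_a − 104.96·chl_b)/221 — scaled by the
extract dilution (default 10×). The coefficient set is recorded on the
result object for auditability. Negative concentrations (possible near
zero absorbance) are returned as computed with a warning flag rather than
clipped.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the raw instruments. Log-abundance of an ordinary feature is
b_i + e_{i,g(s)} + ε with per-feature baseline b_i ~ N(5, 1), group effect
e ~ N(0, group_effect_sd) drawn independently per feature and
genotype × tissue group, and noise ε ~ N(0, noise_sd); abundance is the
exponential. The planted module consists of `hub_size` transcript features
that carry s_j·(L·z_s + √(1−L²)·u_{j,s}) *instead of* a group effect, where
z is a shared per-sample latent factor, L = `hub_loading`, s_j = −1 for the
negatively loaded fraction; the focal feature (emitted in the transcript
layer, as the corresponding protein went undetected in the motivating
proteome) is b_f + z_s + ε. This makes the expected focal–member
correlation ≈ L and the member–member correlation ≈ L², so the loading is
directly interpretable. Protein-layer values below the per-feature
`protein_missing_quantile` (default 0.2) are censored to missing — the
left-censoring regime half-minimum imputation is designed for. All
randomness flows from a single seed; the same spec and seed give a
byte-identical serialized matrix.

Defaults: 150/80/40/40/40 features per layer (+ the focal feature),
group_effect_sd = 1.0, noise_sd = 0.05, hub_size = 29,
hub_negative_fraction = 6/29, hub_loading = 0.99 — i.e. the configuration
whose ego network mirrors the published 29-neighbor/6-negative structure.
The feature count (351) is deliberately desk-scale: large enough for a
nontrivial background network (~60k candidate pairs per dataset, ~6M over a
100-seed recovery run), small enough that a 100-seed experiment finishes in
seconds. What the generator does **not** emulate: count noise and library
size in RNA-seq, peptide-to-protein rollup, batch effects, within-group
correlation beyond the shared group mean, or any spatial structure of
variegation. Passing recovery tests therefore demonstrate correctness of
the pipeline's inference under its own assumptions, not robustness to
real-data artifacts.

`generate_rank_pair(n, d2)` builds tie-free rank vectors with an exact
squared-difference sum, pinning exact Spearman values for tests. A greedy
composition of disjoint swaps (a swap of elements k apart contributes 2k²)
covers most targets; because products of disjoint transpositions cannot
reach every feasible value (n = 4, d² = 14 needs a 3-cycle), infeasible
greedy outcomes fall through to a deterministic backtracking assignment
search with exact rearrangement-inequality bounds. The search agrees with
exhaustive permutation enumeration on feasibility for all n ≤ 8 and solves
every feasible n = 15 target in milliseconds.

## Numerical and design choices

- "Half minimum per protein" is read per-feature (row-wise observed
  minimum), not as a global minimum. Zeros count as observed by default; a
  `zeros_as_missing` ingest flag covers count matrices that encode
  non-detection as 0. Imputation precedes normalization in the pipeline
  (matching the order in which the source describes them; both orders are
  reachable through the module API).
- Reference normalization divides by the arithmetic mean of raw reference
  values (ratio-to-wild-type on the raw scale); features with zero or
  undefined reference mean are dropped and logged.
- Edge streams are canonical (feature_a < feature_b lexicographically),
  emitted block by block; consumers must not rely on global order.
  Component-size ties in `largest_component` break toward the
  lexicographically smallest member.
- Floats in TSV artifacts are printed with 9 decimals so published
  correlation values round-trip; the typographic minus (U+2212) used in
  published tables is normalized to ASCII on every numeric parse.
- CLI exit codes: 0 success, 2 argument errors, 3 contract violations.

## Problem sizes and runtime

The test suite and the acceptance script use desk-scale sizes chosen so the
whole suite runs in well under a minute: 100-seed planted-hub recovery at
the default 351-feature spec (~10 s), 500-seed BH null calibration on
100-feature tables (~1 s), oracle equivalence on 50 random matrices up to
60 features and 100 random graphs up to 7 vertices, and exact-vs-enumerated
signed-rank checks up to n = 12 (4096 sign patterns).

## Known limitations

- The hub test treats node centralities as exchangeable observations; in a
  correlation network they are dependent, so the p-value is a descriptive
  index of extremity (as in the source analysis), not a calibrated error
  rate over networks.
- The approximate signed-rank branch differs from the exact null by up to
  ~0.007 in p at the branch point (n = 25); callers needing exactness
  beyond n = 25 must enumerate externally.
- Only focal–neighbor edges of the packaged published ego table are known,
  so its reconstructed graph is a star; neighbor–neighbor edges are not
  recoverable from the publication.
- The betweenness of a focal node embedded in a near clique is 0; degree is
  the primary recovery metric for the planted-hub design.
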