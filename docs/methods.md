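# Methods

This note records the scientific conventions, parameter choices and known
limitations of the `cerenet` pipeline, in the order the method runs.

## Connectivity matrices

Edge weights are Pearson correlations between per-ROI average BOLD
time-series. Negative correlations are set to exactly 0 — i.e. treated as
absent edges — rather than to a small positive floor, so the matrix
doubles as an adjacency matrix; for the same reason the diagonal is
stored as 0, never 1. No detrending or filtering is applied: inputs are
assumed to be denoised upstream, and the pipeline works on the columns as
given. A zero-variance column is a hard error naming the ROI.

Score groups default to the printed intervals low = [4, 10],
high = [22, 24], with the floor score 3 removed outright. A
quantile-offset rule (median ± (median − first quartile)) could be
derived from data, but the printed lower quartile (~6) is not consistent
with the 25th percentile of a left-skewed distribution with median 16, so
the printed intervals are treated as authoritative and the quantile mode
is not the default.

## Small-world panel

* **Clustering** uses the geometric-mean triangle intensity on weights
  scaled by the network maximum (Onnela convention), which keeps
  `C_i ∈ [0, 1]` and makes clustering invariant to a global rescaling of
  the weights. Nodes with degree < 2 get `C_i = 0`.
* **Path lengths** use the reciprocal weight-to-length map `len = 1/w`,
  the standard convention for correlation weights: strong correlations
  are short edges. `L_w` is the mean shortest distance over ordered
  pairs. A disconnected graph is a hard error by default; an explicitly
  requested harmonic-mean fallback tolerates infinite distances and is
  labelled as such in output.
* **Null ensembles** are built by Maslov–Sneppen double-edge swaps with
  the weight travelling on its edge, so both the degree sequence and the
  multiset of edge weights are preserved exactly. The default budget is
  10 swap attempts per edge per null, 100 nulls, all seeded. A graph with
  no rewirable pair (most importantly a complete graph, where every swap
  target already exists) yields nulls identical to the input, with a
  warning: for such graphs γ = λ = σ = 1 by construction. Ensemble
  normalisation uses means, not medians.
* `σ = γ/λ` with `γ = C_w/⟨C_w^rand⟩` and `λ = L_w/⟨L_w^rand⟩`; σ > 1 is
  read as small-world organisation. Both the raw values (`c_w`, `l_w`)
  and the ratios are reported side by side, since published tables of
  "clustering" and "path length" sometimes carry the normalised
  quantities (raw max-normalised clustering cannot exceed 1, so values
  near 1.2 must be ratios).

### Benchmark graphs

`modular_small_world_graph` is the package's clustered-modular reference:
27 nodes in 4 contiguous modules, within-module weights ~0.6,
between-module edges present at density 0.3 with weight ~0.2, and three
hub nodes bridging all modules at weight ~0.6 (all entries jittered by
N(0, 0.05²)). Two design constraints shape it. First, a fully dense
block-correlation graph is useless as a rewiring benchmark: with every
edge present there is no topology for an edge- and weight-preserving
null to change, and σ is identically 1. Second, if between-module
weights are near zero, every rewired null plants strong shortcuts
between modules and λ explodes, dragging σ below 1 regardless of
clustering. Moderate sparse between-module edges plus hub shortcuts —
both features of empirical correlation networks — give the weighted
small-world signature: γ ≈ 1.1–1.3 at λ ≈ 1, hence σ ≈ 1.08–1.14 across
seeds. `ring_lattice_graph` is the maximally segregated reference
(γ ≫ 1) used to sanity-check the direction of the γ scale.

## Spanning trees

The backbone of strongest connections is the spanning tree of maximum
total weight, built by Kruskal's algorithm on descending weight
(equivalently ascending reciprocal length) with union–find cycle
rejection. Ties are broken by the lexicographic order (−w, i, j) for
bit-reproducibility; equal-weight edges are logged because tree
uniqueness then fails. A disconnected positive-weight graph is an error
listing the components.

Descriptor conventions, chosen where the field uses several:

* **Betweenness** on a tree is computed as the fraction of the
  (n−1)(n−2)/2 unordered node pairs whose unique path passes through the
  node (endpoints excluded), so `BC ∈ [0, 1]` and a star centre attains
  exactly 1. The tree hierarchy `T_h = N_leaf / (2(n−1)·BC_max)` uses
  this fraction-scale maximum; a star then gives exactly
  `T_h = (n−1)/(2(n−1)·1) = 0.5`, the optimum the descriptor was designed
  around.
* **Eccentricity, diameter, radius** are hop counts divided by n−1 (the
  tree's edge count). This normalisation reproduces the magnitudes
  published for 27-node trees (diameters ≈ 0.34–0.43) and matches the
  hop-based tree distances of the MST literature; it is nonetheless a
  reconstruction, since the normalisation is rarely stated explicitly.
* **Degree and betweenness** are additionally divided by their
  within-tree maximum for cross-subject comparability; degree-based
  rankings are unchanged by this per-subject positive scaling.
* **κ = ⟨k²⟩/⟨k⟩** uses raw degrees (range ≈ 2.2–2.3 for 27-node trees,
  consistent with published values; normalised degrees would change the
  scale).
* **r_deg** is the Pearson correlation of endpoint degrees over both
  orientations of every edge (standard assortativity), which makes the
  star's value −1 rather than undefined; it is reported as missing for
  n < 3 or a degree-regular tree.

## Hubs and response-time correlations

A population hub profile counts, per ROI, the fraction of subjects whose
maximum betweenness (or degree) lands on that ROI. Ties credit every
tied ROI, so fractions can sum above 1; with continuous weights ties
have probability zero and fractions sum to exactly 1. The argmax is
taken on normalised metrics (identical ranking to raw).

The response-time analysis correlates each ROI's metric values across
subjects with their median response times; p-values come from the
two-sided t distribution on n−2 degrees of freedom and are reported
unadjusted, mirroring the per-ROI tables this analysis feeds (an
optional BH adjustment across ROIs exists but is off by default). The
selected region is the one with the largest *positive* correlation — the
quantity of interest is slowing, not any association — with a flag for
largest |r|. Exactly constant metric columns are reported as missing;
the constancy test is an exact range check, because a constant
normalised-degree column can carry ~1e−16 of floating-point dust in its
standard deviation.

## Group statistics

Metric panels are natural-log transformed with a 1e−24 additive constant
guarding exact zeros. The degree correlation is negative (≈ −0.35 on
these trees), so it is shifted by +1 before the transform — mapping
(−1, 1] onto (0, 2] — and the affected rows are flagged in the output.
Each of the five contrasts (low vs high pooled, each gender across
groups, genders within each group) runs a classic pooled-variance
one-way ANOVA per metric — "unbalanced" meaning unequal group sizes, not
Welch's correction — followed by Benjamini–Hochberg step-up FDR at
α = 0.05 across the metric family *within* that contrast. Whether the
FDR family should instead pool all contrasts is a judgement call; the
per-contrast default is recorded in every output, and a global-family
mode is available. Group means ± SD are reported on the original metric
scale while inference runs on the transformed scale.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the physics of the measurement:

* **Correlation targets** are block matrices: `within_module_corr` inside
  communities (default 0.35), `between_module_corr` across (default
  0.10), unit diagonal, an optional hub ROI whose row/column is raised by
  `hub_boost`, and per-group multipliers for planting density/clustering
  differences. Targets that lose positive semi-definiteness (possible
  with a strong hub boost) are repaired by clipping negative eigenvalues
  at zero and re-normalising the diagonal, with a logged warning; a
  target whose smallest eigenvalue is below −0.5 before repair is
  rejected as a configuration error rather than silently reshaped.
* **Time-series** are i.i.d. multivariate Gaussian draws from the target
  (frames × ROIs; defaults 1200 frames at 0.72 s, the standard
  resting-state run length). An optional AR(1) filter adds temporal
  smoothness without changing cross-ROI correlations in expectation; the
  default lag coefficient is 0 because temporal autocorrelation is
  irrelevant to correlation-matrix expectations and the i.i.d. default
  keeps the convergence oracles exact.
* **Cohort sizes** default to the study composition: 69 low-scoring
  subjects (25 male / 44 female) and 67 high-scoring (29 male / 38
  female).
* **Scores** are 27 minus a Poisson(11) miss count, rejection-sampled
  into [3, 27]: median ≈ 16, negative skew, both tails populated. Group
  assignment precedes score generation (the generator is asked for "n
  subjects per group"), so scores are drawn from the same distribution
  truncated to the group's interval.
* **Response times** are log-normal (median ≈ 14.8 s, log-scale SD 0.35),
  positive and right-skewed; per-subject response-time distributions are
  not published for this task, so the marginal is a free, documented
  choice.
* **The planted metric–MRT link** is a Gaussian-copula construction that
  takes the realised metric values as given. Two refinements make the
  planted Pearson correlation exact rather than approximate. First, the
  latent coefficient is not set to ρ itself: the exponential marginal
  attenuates correlation, and — for skewed metrics such as tree degrees —
  also inflates it through the metric–Z² term, so the coefficient is
  found by root-solving the closed-form Pearson correlation implied over
  the empirical metric distribution. Second, the copula noise is
  orthogonalised against the metric in-sample. Together these plant
  r = ρ up to the residual nonlinearity (±0.02 at ρ = 0.5, n = 100), so
  recovery tests measure the pipeline's selection and estimation
  behaviour rather than binomial cohort-sampling noise.

What passing tests on these cohorts does **not** show: robustness to
hemodynamic variability, scanner noise, motion artifacts, registration
error or atlas misassignment — none of which the generator models — nor
anything about the published group effects themselves, which depend on
restricted subject data.

## Problem sizes used in the test suite

The statistical suites run at sizes chosen to make their Monte-Carlo
bounds sharp while keeping the default run quick: calibration of the
comparison design uses 200 null replicates of a 10-metric panel
(BH-corrected rejection rate bounded at 7%) and 100 replicates for the
1-SD connectivity-difference power check at n = 40/40; parameter
recovery uses 20 replicate cohorts of 100 subjects × 1200 frames with a
hub boost of 0.25 (within-module correlation 0.4, the upper end of the
regime the recovery property targets, where the planted ROI's degree
distribution is well-behaved); brute-force equivalence checks enumerate
all spanning trees / simple paths on 200 random graphs of 5–8 nodes.

## Known limitations

* The null-ensemble approach degenerates on complete graphs (σ ≡ 1); at
  1200 frames a cohort with all-positive target correlations yields
  complete subject graphs, so small-world scoring is only informative
  when some correlations are non-positive — as in empirical data, where
  negative correlations are discarded.
* Tree descriptors on 27 nodes are coarse: normalised degree takes few
  distinct values, and descriptor distributions are visibly discrete.
* The ANOVA is the classic pooled-variance test by design; it is not
  robust to strong variance heterogeneity between groups.
* Atlas registration, segmentation and volume normalisation are out of
  scope: the pipeline starts at (already extracted) label volumes or
  time-series tables.
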