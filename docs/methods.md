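# Methods

## The statistical model

The nine subscale variables are modeled as a Gaussian graphical model (GGM)
on rank-transformed data. Let `R` be the correlation matrix of the latent
Gaussian copula; with precision matrix `P = R⁻¹`, the edge between nodes *i*
and *j* is the partial correlation

    ρ̂ᵢⱼ = −Pᵢⱼ / √(Pᵢᵢ Pⱼⱼ),

the dependence between two variables after conditioning on all seven others.
Estimation is non-regularized (invert-and-standardize) because the design has
observations greatly outnumbering variables (n ≈ 10³ vs p = 9), the regime in
which estimate-then-select outperforms penalized estimators.

**Rank-based correlation input.** Spearman's ρ_S is the dependence statistic,
but the matrix that is inverted is the copula-corrected transform
`r = 2 sin(π ρ_S / 6)`, the classical rank-based estimator of the latent
Gaussian correlation. Inverting the raw Spearman matrix entrywise is slightly
inconsistent for latent-Gaussian partials — structural zeros map to
population partials up to ~0.01 under the default generating network — which
would inflate the false-inclusion rate of the edge-selection rule as n grows.
The sine map removes the distortion at negligible cost; `copula=False`
restores raw-Spearman inversion for comparison.

**Edge selection.** Nonparametric bootstrap over participants: each of B
replicates resamples n rows with replacement, recomputes ranks within the
replicate (the resample is of participants, so ranks belong to the resampled
data), and re-estimates all 36 partials. An edge is included iff the
percentile interval at coverage 1 − α excludes zero. Defaults B = 5000,
α = 0.05; the redundant `ci`/`alpha` pair is constrained to `ci = 1 − alpha`
unless explicitly overridden. The selected network carries the *full-sample*
estimates with non-selected edges zeroed; using bootstrap means would bias
the weights. Resampled correlation matrices that are numerically indefinite
are repaired by eigenvalue clipping (floor 1e−8, diagonal renormalized,
iterated to convergence) rather than dropped — dropping would bias the CI —
and repair events are counted in the output metadata. Replicates with a
constant column are redrawn and counted.

## Community detection

Clauset–Newman–Moore agglomeration on the absolute selected weights
(Newman–Girvan modularity is undefined for signed graphs; magnitudes are the
common psychometric convention — the signed matrix is preserved for every
other module). Starting from singletons, the pair of communities with the
largest modularity gain ΔQ = 2(e_ab − a_a a_b) is merged until one community
remains; the dendrogram is cut at the maximum Q, taking the earliest state
attaining it so zero-degree nodes stay singletons. Exact ties in ΔQ are
broken lexicographically by the sorted node labels of the candidate pair,
making the procedure fully deterministic — determinism and the absence of
tuning parameters are why this algorithm was chosen. The implementation is a
direct O(n²)-per-merge scan, ample at n = 9, and is cross-checked in the
tests against igraph's fast-greedy routine and an exhaustive Bell-number
partition search on ≤ 8 nodes.

Detection runs on the selected (sparsified) network by default; the
saturated matrix can be passed instead.

## Bridge centrality

Given a partition, for node *i* with community c(i):

* **Bridge expected influence** — Σ over j ∉ c(i) of the signed weight wᵢⱼ
  (direct connections only; satisfies the handshake identity that its total
  equals twice the signed cross-community weight).
* **Bridge closeness** — 1 / mean shortest-path distance to all
  out-community nodes, with edge length 1/|w| (strong edges are short; the
  standard weighted-network convention, recorded in output metadata since it
  changes absolute values). Unreachable nodes give infinite distance, hence
  BCL = 0.
* **Bridge betweenness** — the number of geodesics between node pairs in
  different communities passing through the node (endpoints excluded), with
  tied geodesics counted fractionally so the result is deterministic.

**Difference tests.** Pairwise differences in a metric are tested by the same
participant bootstrap, holding the community partition *and* the edge
inclusion mask fixed at the full-sample solution while the weights are
re-estimated per replicate. Re-running selection per replicate would mix
model-selection variability into what is meant to be a sampling-variability
test of centrality differences; the fixed-mask choice is a declared
assumption. Significance at each pair is the 95% percentile CI of the
difference excluding zero.

## Controllability

The selected signed network is the coupling matrix A of the discrete-time
linear system x(t+1) = A x(t) + B u(t) (signs matter for dynamics, so
|weights| is *not* taken; configurable). A is stabilized as
A′ = A / (1 + |λ_max(A)|), giving spectral radius < 1.

* **Average controllability** of node *i*: trace of the infinite-horizon
  controllability Gramian W solving W = A′WA′ᵀ + eᵢeᵢᵀ (discrete Lyapunov
  equation, solved exactly rather than by finite-horizon truncation). The
  τ = 0 term contributes 1, so values are ≥ 1; typical partial-correlation
  networks of this density give ~1.0–1.2.
* **Modal controllability**: φᵢ = Σⱼ (1 − λⱼ²) vᵢⱼ² over the orthonormal
  eigendecomposition of A′. Nodes coupling into fast-decaying modes (hard-to-
  reach states) score high; strongly connected hubs score low.

The normalization constant and post-normalization spectral radius are written
to the output metadata because alternative conventions change absolute
values.

## Node predictability

Each node is regressed (OLS with intercept) on its selected neighbors, on
rank-transformed data for consistency with the rank-based network; R² is
reported, 0 by convention for isolated nodes, and constant neighbor columns
are dropped. On ranks, R² is invariant to monotone transforms of any
variable. (Mixed-graphical-model predictability is conventionally defined on
raw data; the rank choice is declared and configurable by transforming the
input table.)

## Synthetic data: what it emulates and what it does not

The generator defines a ground-truth partial-correlation network over the
nine variables: within-instrument partials drawn uniformly from 0.2–0.4
(three blocks: 3 schizotypy, 4 self-report, 2 task nodes) and eight fixed
signed cross-block bridge edges concentrated on the social-production node
(+0.15/+0.12/+0.12 to the task and cognitive-perceptual nodes, and weaker
±0.10 edges elsewhere); all other cross-block partials are exactly zero. The
topology mirrors the qualitative sign pattern the analysis is designed to
detect — no published numeric weights exist for this design, and parameter
recovery needs a *known* truth, so the magnitudes are round values chosen
once. A requested configuration whose implied precision matrix is not
positive definite raises with the offending eigenvalue rather than being
silently repaired (with within-block draws near 0.4 the 4-node block sits
close to the feasibility boundary, so some random draws are rejected; the
default seed is feasible with margin).

The canonical precision matrix has unit diagonal and −ρᵢⱼ off-diagonal; its
inverse, standardized to a correlation matrix, is the sampling covariance.
Subscale tables are n i.i.d. draws from that multivariate Gaussian.

Item-level data use a latent Gaussian copula: each subscale latent is
disaggregated into equicorrelated item latents with loading 0.7 (typical
questionnaire reliability; yields subscale-total/latent correlations ≈ 0.8),
cut at standard-normal quantile thresholds — binary SPQ items at the 70th
percentile (~30% endorsement), 5-point BAG items at (0.10, 0.35, 0.65, 0.90),
7-point video ratings at (0.05, 0.20, 0.40, 0.60, 0.80, 0.95). Reverse-keyed
BAG items and Unrelated video conditions load negatively, so scoring recovers
positively oriented subscales. The attention check is an independent
Bernoulli pass flag (default 4% failure), matching how the pipeline consumes
it (include/exclude only).

Not emulated: response times, demographic covariates, item-specific content
effects, differential missingness, and any non-Gaussian marginal shape beyond
what thresholding induces. Passing tests therefore demonstrate statistical
correctness of the pipeline under a Gaussian-copula world with instrument-
block structure, not robustness to real-data pathologies.

## Scoring conventions

* SPQ-B: 22 binary items mapped 8/8/6 to cognitive-perceptual/interpersonal/
  disorganization (the instrument's standard assignment); total = sum of all.
* BAG: 12 items (1–5), four 3-item subscales; reverse-keyed items recoded
  6 − response before summation. The default reverse-key set contains the
  negatively worded perception item; both the item map and key set are
  configuration data, not hard-coded, because alternative keyings are a
  researcher degree of freedom.
* Task indices: Icon = mean(CR) − mean(CU), Metaph = mean(AR) − mean(AU) on
  the 7-point relatedness ratings — the natural congruence-discrimination
  contrast, bounded in [−6, 6]. "Performance summary measure" admits other
  definitions; this one is declared and swappable.
* Missing items: the affected subscale (only) is set to missing for that
  participant; network estimation uses complete rows.

## Determinism and problem sizes

Every stochastic stage takes an integer seed; the pipeline derives per-stage
seeds from a master seed via `SeedSequence((master, stage_index))`, so any
stage replays in isolation. Identical (parameters, seed) give bit-identical
output, and a full pipeline run reproduces byte-identical artifacts.

The test suite and the acceptance script run the study-scale analyses at
desk-scale bootstrap counts chosen once: the single-dataset community check
uses n = 1000 with 1000 bootstrap replicates, the type-I-rate study uses 200
datasets × 500 replicates, and the recovery study 50 replicates at n = 1094
with 500 bootstraps — sizes at which the Monte-Carlo error of each reported
rate is well below the margins asserted. Production analyses default to
B = 5000.

## Known limitations

* The estimator assumes a continuous latent scale; heavily tied ordinal sums
  are handled by midranks, but extremely coarse items (few categories, skewed
  thresholds) attenuate the copula correction's accuracy.
* Percentile bootstrap CIs are first-order accurate; at small n (< ~10 rows
  per node) edge selection is unstable and the package warns.
* Community detection on |weights| discards sign information by design;
  strongly negative within-community edges would be misread as cohesion.
* Controllability values depend on the normalization convention; only
  comparisons under the same convention are meaningful.
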