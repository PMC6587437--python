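# Methods

## Pipeline overview

The analysis runs in seven stages: (1) obtain per-subject ROI time series
(synthetic, or loaded from TSV); (2) per-subject Pearson connectivity and
per-group element-wise average matrices; (3) binarization at each sparsity
threshold T; (4) spectral community detection per subject and per group
network; (5) the five community-quality metrics per (subject, threshold);
(6) group statistics — KS/FDR on metric distributions, global and nodal
Rand-index permutation tests on partitions; (7) classification of the
diagnostic label from metric features, with RFE feature ranking. Every
stage reads and writes plain-text formats (TSV/CSV/JSON), and all
randomness flows from one root seed through named substreams, so a
(config, seed) pair determines every output byte.

## Synthetic cohort model

Each subject's time series is an i.i.d. sequence of zero-mean, unit-variance
Gaussian vectors with block-constant correlation: `rho_in` within a module,
`rho_out` between modules. Defaults: 90 ROIs in three modules of 30,
150 timepoints, `rho_in = 0.5`, `rho_out = 0.1`, 20 subjects per group.
The correlation levels are fixture choices in the range commonly seen for
within- versus between-network resting-state correlations; the pipeline
consumes only Pearson correlations, which are location/scale invariant, so
the Gaussian location/scale convention is immaterial.

Two group effects can be planted, because the pipeline contains two
distinct detectors: a signed shift `delta_rho_in` of the case group's
within-module correlation (a diffuse connectivity change, aimed at the
metric comparisons and the global Rand test) and reassignment of an
`affected_nodes` set to the next module (a focal community change, aimed
at the nodal test). If a block-constant matrix loses positive
semidefiniteness it is shrunk toward the identity by the minimal factor
restoring eigenvalue ≥ 1e−8, and the repair is logged.

What the generator does *not* emulate: haemodynamics, scanner drift and
motion, non-Gaussian noise, between-subject heterogeneity of the
correlation structure, and multi-site batch effects. The last omission
matters most for interpreting tests: with a shared within-group covariance,
subjects' partitions are far more consistent than real fMRI partitions, so
planted effects saturate the permutation tests at smaller effect sizes
than real data would. Passing power checks therefore demonstrates that the
machinery detects what was planted, not that real cohorts of this size
would yield similar p-values.

## Connectivity and binarization

Pearson correlation per ROI pair; a zero-variance column yields r = 0 with
every other column (logged, not fatal). Group averaging is the plain
arithmetic mean (a Fisher-z option exists, off by default). Binarization
keeps edge (i, j) iff r_ij > T — strict inequality, on the signed value,
so negative correlations never produce edges; an inclusive-threshold flag
is provided. Thresholds outside [0.1, 0.9] are rejected.

## Community detection

Newman's leading-eigenvector method: recursive bisection by the sign of
the leading eigenvector of the generalized modularity matrix
`B(g) = [A − kkᵀ/(2m)]_g − diag(row sums)`, each connected component
processed independently. A split is refused when the leading eigenvalue is
≤ 1e−10 or the refined split does not increase modularity. After each
bisection a Kernighan–Lin pass runs: every node is tentatively moved once
(largest gain first, even if negative), and the best intermediate state is
kept when it genuinely improves the recomputed objective — this tunnels
through local optima that accept-only-improving sweeps cannot leave. A
final whole-partition pass of the same style (targets: any community or a
fresh empty one) recovers optima that cross the first cut; on random
graphs small enough for exhaustive search it reaches ≥ 0.9 of the global
maximum modularity, and equals it on planted two-clique graphs.

Determinism: eigenvectors come from a symmetric eigensolver with the sign
fixed so the lowest-index nonzero entry is nonnegative; all tie-breaks
resolve to the lowest (node, community) index; isolated nodes become
singletons; the edgeless graph maps to all singletons. Partitions are
stored in canonical form (communities numbered 1..K by lowest member).

## The five metrics and their diagonal conventions

The density-family metrics (global density, local density, distance-based,
node membership) treat A_xx as 1; this is the unique convention under
which perfect structures attain the stated boundary values (1 for the
first three-as-quality, 0 for the distance-based metric). Modularity uses
the standard A_xx = 0 and is defined as 0 on an edgeless network (logged).
Empty-complement terms — the external density of a single-community
partition, μ(x, ∅) — are defined as 0. Modularity may be negative (down
to −0.5); the other four metrics stay in [0, 1].

## Permutation tests

The global statistic is the pooled mean Rand index over all within-group
subject pairs (both groups' pairs averaged together; per-group means also
reported). The null is built by relabeling subjects with group sizes
preserved; when the number of distinct arrangements is at most the
requested permutation count the null is enumerated exactly, otherwise
permutations are sampled with replacement. The p-value follows the strict
rule — the fraction of null statistics strictly exceeding the observed —
with a non-strict variant and an add-one smoothing flag available, because
the strict rule degenerates to p = 0 whenever the statistic is constant
across permutations (e.g. all partitions identical). The nodal test
reduces each partition to a two-block labeling of the other N−1 nodes
("same module as X" or not), computes the same pooled statistic per node
from one shared permutation stream (so all nodes see identical
relabelings), and attaches BH-adjusted q-values.

Degenerate-data caveat: with highly consistent partitions the within-group
statistic can exceed every permuted value for *every* node, collapsing all
strict p-values to 0 and destroying any ranking among nodes. Localization
analyses therefore use the non-strict rule, under which no-difference
nodes sit at p ≈ 1 and planted nodes at p ≈ 0.

## Group statistics

Two-sample KS tests use the asymptotic Kolmogorov distribution at the
effective sample size mn/(m+n). BH-FDR is applied across the full family
of (metric, threshold) cells within one run — the most conservative
reading of a family boundary. KDE summaries use a Gaussian kernel whose
bandwidth is the literal kernel standard deviation (default 0.02 on the
metric scale); curves are emitted as data, plotting is left to the caller.

## Classification

LDA estimates class means, empirical priors, and the pooled within-class
covariance (denominator n − 2); a ridge of 1e−6 · trace(Σ)/p is added when
the condition number exceeds 1e12 (recorded on the model — with saturated,
collinear metric features this is routine). Posteriors follow Bayes' rule
with the shared covariance; exact ties resolve to the lower class id. KNN
uses Euclidean distance on z-scored features (standardization fitted on
training folds only; k = 5 by default), vote ties go to the single
nearest neighbour, distance ties
to the lower training index. LDA features are deliberately left unscaled:
the discriminant is affine-invariant.

Cross-validation: leave-one-out, or stratified k-fold built by per-class
shuffling and round-robin dealing (deterministic given the seed).
Performance is pooled over held-out predictions with "case" as the
positive class; zero-denominator precision/recall are defined as 0 and
flagged. Per-fold confusion counts are stored so every reported
percentage can be re-derived.

RFE runs backward elimination inside each outer stratified fold: the
feature whose removal yields the highest inner 3-fold CV accuracy is
dropped (ties resolved by removing the feature with the weakest
standardized mean group difference — a content-based rule, so feature
order never matters) until one survives. A feature eliminated at position
i in a p-feature table has rank p − i + 1, and its score is the fold-mean
of (p − rank)/(p − 1) ∈ [0, 1]. The scoring formula (fold-averaged
normalized elimination rank) is this package's construction.

## Problem sizes and defaults

Full runs default to the method's published scale: thresholds 0.1–0.9 in
steps of 0.1, 50,000 global and 10,000 nodal permutations. The bundled
fixture configuration and the test suite run reduced scales (hundreds of
permutations, 20–90 ROIs, 10–20 subjects per group), which keep the whole
suite under a minute of compute while leaving every code path exercised;
power checks use 20–50 replicates per condition. The acceptance script
uses 2,000 permutations per test on 40-subject cohorts.

## Known limitations

- Unweighted, positively-thresholded graphs only; no signed or weighted
  community detection, no alternative association measures.
- The permutation framework assumes exchangeable subjects under the null;
  site effects or covariates are not modeled.
- Recursive bisection with refinement is a heuristic; optimality is
  verified only against exhaustive search at n ≤ 10.
- The strict permutation p-value is anti-conservative on degenerate
  (constant-statistic) data; see above.
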