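# Methods

`psystrat` stratifies early-psychosis patients from their baseline PANSS
symptom profiles with a Mapper graph, replicates the stratification in a
second cohort by nearest-centroid assignment, and quantifies what the
groups buy you: group-specific symptom items, group-linked metabolite
shifts and correlation structure, and prediction of good vs. poor
functional outcome three years later. Because item-level clinical
cohorts of this kind are not publicly deposited, the package ships a
synthetic-cohort generator with planted structure; every end-to-end
claim the test suite makes is a claim about recovery of that planted
structure.

## The Mapper construction

Each patient is a vector of 30 ordinal PANSS item scores (P1–P7, N1–N7,
G1–G16, each 1–7). Mapper summarizes the point cloud as a graph:

1. **Metric.** Normalized Pearson correlation distance,
   d(x, y) = sqrt(2 (1 − r(x, y))). This equals the Euclidean distance
   between z-scored vectors up to a global scale and is therefore a true
   metric, which keeps single-linkage clustering well behaved; the plain
   1 − r form is available via `MapperConfig.distance="one_minus_r"` for
   comparison, and `"euclidean"` exists for the low-dimensional geometric
   fixtures used in testing. A constant symptom vector has no defined
   correlation and is rejected with the offending row named.
2. **Lens.** The first two principal-component coordinates of the
   column-centered score matrix (all items share the 1–7 scale, so
   columns are not rescaled by default; `scale_items=True` z-scores
   them). Component signs are fixed by making each loading vector's
   largest-magnitude entry positive, so the lens is deterministic.
3. **Cover.** Per lens dimension the range is divided into `resolution`
   strides s = (max − min)/resolution with interval centers at
   min + (i + 0.5) s and interval length s × gain; rectangles are the
   Cartesian products. Adjacent-interval overlap is therefore
   1 − 1/gain: the default gain 7 gives ≈ 85.7 % overlap, and the
   default resolution 60 applies per dimension (60 × 60 rectangles for
   the 2-d lens). Intervals are closed, so range maxima fall in the last
   interval; a zero-spread dimension collapses to a single interval with
   a logged warning.
4. **Preimage clustering.** Single linkage on the restricted distance
   matrix, cut by the histogram gap heuristic: build a `bins`-bin
   (default 10) histogram of merge heights over [0, max height] and cut
   at the left edge of the first empty bin that follows a nonempty bin.
   The "follows a nonempty bin" qualifier matters on ordinal data: merge
   heights are bounded away from zero, so the leading bins of the
   histogram are empty and a literal first-empty-bin cut would shatter
   every preimage into singletons. If no gap exists, the preimage is one
   cluster; a singleton preimage is one singleton cluster.
5. **Nerve.** One node per cluster, an edge wherever two clusters share
   at least one patient, weighted by the shared count. Node identity is
   (rectangle id, cluster rank), with all ties broken by patient row
   index, so graphs are exactly reproducible.

`clusterer="none"` skips step 4 and yields the nerve of the cover. This
variant is used to state the gain-monotonicity property exactly: growing
the intervals can only grow preimages and their intersections, so the
cover-nerve edge count is monotone in gain. With gap-heuristic
clustering the full Mapper edge count is *almost always* monotone but
can dip when larger preimages cause clusters to merge; the suite asserts
the theorem form and treats full-graph counts as descriptive.

## From graph to groups A, B, C

Connected components are the coarse structure. Components with fewer
than `min_component_patients` (default 5) distinct patients are
excluded — the analogue of leaving a handful of isolated-node patients
unassigned. If fewer components than `n_groups` (default 3) remain,
the largest component is bisected.

The default bisection is a **normalized-cut spectral split**: the sign
of the Fiedler vector of the symmetric normalized Laplacian of the
shared-member-weighted subgraph (dense solve below 200 nodes,
shift-inverted Lanczos with a fixed starting vector above). This is the
automated stand-in for drawing a boundary across the graph's narrow neck
by eye. Girvan–Newman edge-betweenness removal is provided as an option
(`split_method="edge_betweenness"`, exact on small graphs, igraph-backed
batched removal on large ones) but is not the default: on dense
high-gain Mapper graphs the cheapest betweenness-ordered disconnection
shaves off peripheral nodes instead of cutting the neck, which produces
degenerate "splits". Manual node-set cuts (`split_method="manual"`) are
supported for reproduction studies.

Group names are data-anchored so they are comparable across cohorts:
B is the part with the highest mean positive-factor score; of the
remaining two, C is the one with the higher mean negative-factor score
and A the other. (Naming A vs C by positive score alone would be
decided by noise whenever their positive levels coincide, as they do in
the planted profiles.)

Patients are labeled by majority vote over the nodes containing them;
an exact tie leaves the patient unassigned, as does membership only in
excluded components. The tie rule is a guess — the source analysis
reports a few unclassified patients beyond those in isolated nodes
without stating the rule — and is the simplest one consistent with that
count. `boundary_sensitivity` flips one B/C boundary node at a time and
recomputes profiles and assignments, quantifying how much the exact
boundary position matters.

## Characterization

* **Wallwork five factors** (positive P1 P3 P5 G9; negative N1 N2 N3 N4
  N6 G7; disorganized P2 N5 G11; excited P4 P7 G8 G14; depressed G2 G3
  G6), scored as item sums. The mapping is exposed in reports for audit.
* **Group-specific items**: per item and group, a two-sample
  Kolmogorov–Smirnov test of the group against the pooled rest. D is
  the exact maximum ECDF difference over the pooled support, which is
  the correct statistic in the presence of the massive ties of 1–7
  data. The default p-value follows scipy's two-sided asymptotic
  convention (one-sample KS null at the rounded effective sample size
  n_a n_b/(n_a+n_b)); the limiting-Kolmogorov form and scipy's exact
  small-sample computation are switchable. Bonferroni correction uses
  the full family of 90 comparisons (30 items × 3 groups) by default;
  the family size is configurable because the smaller per-group family
  of 30 is also defensible.
* **Outcomes**: chi-square tests of independence without continuity
  correction for categorical outcomes; one-way ANOVA plus pairwise
  t-tests for GAF, SOFAS and factor scores, with per-group means ± se.

## Replication and prediction

Group centroids are coordinate-wise means of the raw 30-item vectors;
patients of a second cohort get the label of the nearest centroid in raw
Euclidean distance (no scaling — the items share one scale). Exact ties
go to the lexicographically first label and are logged.

Outcome is dichotomized at GAF > 65 (good) vs ≤ 65 (poor), strictly.
Prediction uses L2-penalized logistic regression (inverse penalty =
`regularization_strength`, default 1, the sklearn convention;
unpenalized intercept; lbfgs with tol 1e-8). Feature sets: the 30 raw
items; A/B/C indicators (patients without a group are excluded from
group-feature models, with counts logged); k-means (k = 3, k-means++,
10 restarts, seeded) cluster indicators, raw or on the 2-d PCA lens.
Evaluation reports accuracy/precision/recall at probability 0.5 (an
undefined precision is reported as 0 and flagged), the precision–recall
curve swept over unique predicted scores, PR-AUC as step-interpolated
average precision, and the prevalence baseline — the precision of the
classifier that always predicts a good outcome, whose PR-AUC equals the
prevalence exactly. Schemes: train on cohort 1 / test on cohort 2, and
label-stratified fivefold cross-validation with pooled out-of-fold
scores. Partitions are compared by contingency table, adjusted Rand
index, and maximum-weight bipartite label matching.

Note a subtlety the tests document: with a fixed penalty weight,
duplicating the training data halves the effective regularization, so
fit invariance under duplication holds only in the unpenalized limit.

## Metabolite analysis

Per metabolite, an OLS model `level ~ group + age + sex` (female = 1)
with pairwise group contrasts tested via t-tests on coefficient
differences; complete-case analysis with dropped counts reported, and a
hard error on singular designs. Per group, a correlation network over
all metabolite pairs: product-moment r with the two-sided p from
t = r sqrt((n−2)/(1−r²)); pairs with raw p < 0.05 become edges, with
pairwise-complete n recorded per edge. Edge p-values are deliberately
not corrected for the number of pairs — the threshold is exploratory,
matching the analysis this package reproduces — but Benjamini–Hochberg
flags are emitted alongside. Edges are then classified by the exact set
of groups containing them ({A}, {B}, {C}, {A,B}, {A,C}, {B,C},
{A,B,C}), and annotated against a small static pathway lookup (urea
cycle, transsulfuration, glutamate transamination, …); the annotation is
shipped data, not computed biology.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen once to encode the reported orderings:

* **Groups**: proportions (21, 30, 43)/94 for A/B/C.
* **Symptoms**: per-group means at the Wallwork factor level — A (2.8,
  1.8, 2.0, 2.2, 2.0), B (4.2, 3.5, 3.8, 3.8, 3.0), C (2.8, 4.0, 3.0,
  2.4, 3.2) for (positive, negative, disorganized, excited, depressed);
  items outside the five factors share a 2.5 baseline. An item score is
  clamp(round(factor mean + N(0, sd)), 1, 7) with sd 0.8 — distinct but
  overlapping ordinal profiles, the simplest mechanism with controllable
  separation.
* **Outcomes**: GAF ~ N(mean_g, 10) truncated to [0, 100] with means
  (72, 55, 60) for A/B/C, so good outcome (GAF > 65) is most likely in A
  and least in B; working/living/remission are Bernoulli draws tied to
  the group's good-outcome probability (0.75/0.20/0.35);
  SOFAS ≈ GAF + N(0, 5); diagnosis mixes make B schizophrenia-dominated
  and A enriched for schizophreniform/brief episodes.
  `gaf_means_for_good_prob` converts target good-outcome probabilities
  into GAF means exactly.
* **Metabolites**: 4 redox markers + 28 amino acids, multivariate normal
  within group. GPx means 23.3/25.5/28.1 µmol/min/gHb (sd 8) and
  2-aminobutyrate 21.4/17.9/16.8 µM replicate the reported shifts; the
  published dispersions are standard errors, so the sds are free
  parameters, set to 5 µM generically and scaled down for
  low-concentration species so the nonnegativity floor stays negligible.
  Planted within-group correlations give A a urea-cycle-like block
  (arginine–citrulline–ornithine), C a glutamate hub, and all groups a
  shared glycine–serine edge.
* **Demographics**: age ~ N(25.1, 4), 76.2 % male.
* Geometric fixtures: noisy circle and Gaussian blobs for validating the
  Mapper construction on data of known topology.

What the generator does **not** emulate: real item-level covariance
within factors, skewness of PANSS distributions, informative
missingness (only a missing-at-random outcome rate is provided),
medication effects, or any relation between symptoms and metabolites
beyond group membership. Passing tests therefore demonstrate that the
pipeline recovers planted structure of this idealized form at realistic
sample sizes — not that the clinical stratification itself is
reproduced.

## Numerical and scale choices

All randomness flows from one top-level seed through spawned per-stage
seeds (< 2^31), making pipeline runs byte-reproducible. Problem sizes
in the test and acceptance runs are chosen to finish in minutes on one
core: recovery experiments use n = 300 cohorts over 5–20 seeds,
calibration studies 200 replicates, permutation oracles exact at n ≤ 6
and 10^4 draws at n = 20. Known limitations: the spectral split always
produces exactly `n_groups` parts even when the data do not support
three groups (the group count is fixed by design, not chosen by the
data); the KS asymptotic p-values on heavily tied ordinal data are
conservative; and the Mapper graph's node-for-node shape depends on
proprietary conventions of the platform used in the original analysis,
so only its group structure — not its layout — is comparable.
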