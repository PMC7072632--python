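# Methods

This note records the modeling and numerical choices behind `ecvnet`, the
parameters that matter, what the synthetic benchmark does and does not
emulate, and known limitations.

## Model

Expression profiles (samples × genes, log2 scale) are modeled as a Bayesian
network whose local conditional densities are Gaussian around an additive
B-spline regression: a child gene's expression is the sum of smooth
univariate functions of its parents' expressions plus N(0, σ²) noise. Each
smooth function uses M = 20 cubic B-splines on a clamped knot vector with
uniform interior knots spanning the observed range of the parent. Uniform
knot placement is the simplest reproducible choice; quantile placement was
deliberately not used so that the basis depends only on the observation
range, not the sample distribution.

Evaluation outside the training range **clamps** the input to the nearest
boundary. This is essential for cohort transfer, where a new platform's
values routinely exceed the training range: clamped evaluation returns the
boundary contribution instead of an extrapolated cubic blow-up, at the cost
of flattening genuine out-of-range response.

## Fitting and identifiability

Coefficients are estimated by penalized least squares — the MAP fit under a
Gaussian smoothness prior, not a full posterior integration. The smoothness
penalty takes second-order *divided* differences of the coefficients over
the Greville abscissae rather than raw index differences: with clamped
(hence non-uniform) knots, raw differences penalize straight lines near the
boundary, whereas the divided-difference penalty has all linear functions in
its nullspace. Consequently a linear relationship is reproduced exactly
(machine precision) at any penalty weight — a property the test suite
asserts at < 1e-6.

The penalty weight λ is chosen per local model from the grid
{0.1, 1, 10, 100} by the local score. A ridge term (1e-8) makes the
otherwise rank-deficient additive system strictly positive definite and
pins the arbitrary constant split between additive components.

Because the model has no intercept and components are identified only up to
constants, raw ECv values carry an arbitrary per-component offset. This is
harmless downstream: ΔECv, edge-wise t-tests and clustering of profiles all
difference the offset out, and the shift invariance is tested exactly.
Children without parents are modeled as a Gaussian around the sample mean;
a zero-mean convention would misfit non-centered expression data.

The reported σ² is the raw residual RSS/n; inside the score's logarithms it
is floored at 1e-12 so that noise-free fits stay finite.

## Scoring and structure search

The local score is the closed-form log marginal likelihood of the penalized
Gaussian model (a Laplace-type criterion, exact for Gaussian likelihoods):
the penalized fit term plus ½(log det K − log det A), with K the prior
precision and A the penalized normal-equation matrix, and the residual
variance plugged in. It is decomposable over children, so structure search
sums per-child scores. The criterion follows the usual penalized-spline
network-scoring construction in spirit; equivalence to any particular
published hyperprior is not claimed, and the grid-based λ selection is a
declared stand-in for hyperparameter optimization.

Three searchers share this score:

- **Exhaustive enumeration** (≤ 5 genes) over topological orders with
  best-subset parent selection — exact, used as the oracle the greedy
  search is validated against (≥ 18/20 agreement on seeded instances).
- **Greedy hill climbing** from the empty graph over add/delete/reverse
  moves with acyclicity and a max-parents cap (default 3); moves are
  enumerated in sorted order so results are deterministic.
- **Iterated-subnetwork frequency estimation** for large gene sets: each
  iteration seeds a uniformly drawn gene, grows a subset (default 30 genes
  at scale; 4–6 in the desk-scale tests) by absolute-Pearson-correlation-
  weighted sampling, learns a subnetwork greedily, and records its edges.
  An edge's frequency is the number of subnetworks containing it divided by
  the number of subsets containing both endpoints — the co-sampling
  denominator avoids penalizing rarely co-sampled pairs. This estimator is
  a faithful-in-spirit variant of published neighbor-sampling schemes, not
  a certified reimplementation; its internals (growth distribution, subset
  size, per-subset learner) are declared here rather than inherited.

Thresholding keeps edges with frequency strictly above the cutoff (default
0.1); if both directions survive, the higher-frequency direction wins
(lexicographic on ties). The thresholded union may contain cycles — by
design, since everything downstream needs only per-child parent sets.
Concordance between two estimated networks is |E₁ ∩ E₂| / |E₁ ∪ E₂|
(direction-sensitive); the union denominator is the stricter of the
plausible readings. All randomness flows from one integer seed through
iteration-indexed substreams, so results are independent of execution
order.

## ECv, ΔECv and extraction

ECv of edge p→c in sample i is the fitted component m(x<sub>ip</sub>);
the ECv matrix stacks all samples × edges. ΔECv is stored as the absolute
difference of group means (groups may be singletons). Extraction keeps
edges exceeding the threshold in *every* comparison group (mode `all`, the
conservative intersection rule; `any` gives the union). The default
threshold 1.0 on log2 data corresponds to a two-fold change of the
contribution. Edge-wise significance uses Welch's unequal-variance t-test
on ECv with Benjamini-Hochberg adjustment across the tested edge set only
(not all basal edges); tests default to pooling conditions across lines.
Zero-variance edges are handled explicitly (p = 1 for equal means, p = 0
otherwise) rather than left to a division error.

Transfer evaluates the original trained models on a new cohort without any
cross-platform renormalization (an optional per-gene z-scaling flag exists
but defaults off); an edge is transferable iff both its parent and child
genes are present, and the report enumerates dropped edges and missing
genes.

## Subnetwork assembly, clustering, survival

The differential subnetwork is the basal network's induced subgraph on the
extracted edges' endpoint genes: extracted edges plus "basal fill" edges
connecting those genes. Hubs are the top ⌈5%⌉ of nodes by total
(in + out) degree, extended through ties; components are weak connectivity
classes, largest first.

Sample stratification clusters ECv profiles with Ward agglomeration under
the ward.D2 convention (Euclidean distances squared inside the
Lance-Williams update, heights on the original scale — verified against R's
`hclust(method="ward.D2")` on a hand-computed example), cut at k = 2 by
default. Group survival is compared with the standard two-group log-rank
test (hypergeometric expected events, χ²₁ reference; censored-at-event-time
subjects counted in the risk set) and Kaplan-Meier product-limit curves;
both are implemented directly and cross-checked against `lifelines` in the
test suite.

## Synthetic benchmark

The generator emulates a small in vitro perturbation experiment: 3 lines ×
2 conditions × 3 replicates (18 samples), ~10–30 genes, additive
nonlinear parent→child functions (linear / sigmoid / sine / quadratic) with
Gaussian noise (σ = 0.3), small per-line intercepts (σ = 0.2), root-gene
variability σ = 0.3 by default (replicates of cell-line experiments are
markedly homogeneous), and values in a positive log2-like range (means
6–10).

A planted perturbation designates dedicated regulator→target edges: the
regulator is a root, the target's only parent is the regulator, and the edge
is linear with slope ≈ 1. In the treated condition the regulator's
expression is shifted by the stated magnitude (default 2), so the shift
propagates through the edge function and moves that edge's contribution by
about the same amount — the signal ΔECv detects. A shift of the *function*
at unchanged parent values would be absorbed into the child's residual and
be invisible to any contribution measure evaluated at observed parent
values, so the regulator-shift formulation is the meaningful one. Background
edges get damped gains (absolute slope ≲ 0.35) so perturbations cascade
downstream well below the extraction threshold, reflecting the empirical
pattern that a condition moves a few regulators strongly and the rest of
the network weakly.

Scenario presets used by the tests and the acceptance script:

- **Differential-edge recovery**: the default 18-sample design above; the
  3 planted edges must rank top-3 by min-over-lines ΔECv in ≥ 90% of 25
  seeded replicates.
- **Structure recovery / stability**: a population-style scenario
  (1 condition, 60–100 samples, root σ = 1.0, gain × 3) where parent
  variation is well above noise; used for the ≥ 70% recall / ≤ 30% false
  positive check and for the concordance-vs-iterations trend
  (T ∈ {50, 200, 1000} on a 20-gene system).
- **Cohort stratification**: models trained on the 18-sample design are
  transferred to a simulated 200-patient cohort (100 control-like, 100
  treated-like); exponential survival with hazard ratio 2 between the true
  groups; clustering the transferred ECv profiles and log-rank testing the
  two clusters must give p < 0.05 in ≥ 80% of 25 seeded replicates.

Problem sizes (10–20 genes, tens to hundreds of iterations, 25 replicates)
are the package's own desk-scale defaults, chosen so the full suite runs in
well under a minute while every statistical claim is still measured, not
assumed. What these tests do **not** show: performance on real microarray or
RNA-seq noise (no probe effects, batch effects, heteroscedasticity, or
count-based noise are simulated), behavior at genome scale (10⁴–10⁵ genes,
10⁵–10⁶ iterations), or robustness of ΔECv means on heterogeneous sample
sets — group-mean ECv is only representative when within-group samples are
homogeneous.

## Numerical details and edge cases

- Degenerate parent ranges (all values identical) are rejected at basis
  construction.
- Score ties in searches are broken deterministically (fewer parents, then
  lexicographic edge lists; tolerance 1e-9).
- Cluster labels are renumbered by first appearance, so labelings are
  stable across runs.
- Missing expression values are rejected on load (no imputation); duplicate
  gene or sample identifiers are rejected with the offenders named.
- The low-expression filter drops genes whose mean is strictly below the
  given percentile of gene means (ties kept); follow-up filtering drops
  subjects observed beyond a cutoff (default 2000 days). Both are opt-in
  preprocessing for real cohort data.
- Model sets serialize to JSON with exact float round-trip, so ECv matrices
  recomputed from a reloaded model set are bit-identical.

## Limitations

Estimation is MAP under a fixed λ grid, not a full posterior; no
interaction terms between parents; no heteroscedastic noise; no paired or
moderated-variance tests; k > 2 survival comparison and Cox regression are
out of scope. The iterated-frequency estimator's published reference
implementation was not reproduced verbatim (see above), so frequency values
are comparable within this package, not across implementations.
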