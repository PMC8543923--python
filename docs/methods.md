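# Methods

## Model and estimation

netdbt implements contrast-based network meta-analysis of dichotomous
outcomes on the log odds-ratio scale.  Arm-level data are reduced per
study to baseline contrasts: with baseline arm `b` and comparator `k`,
`y_k = logit(e_k/n_k) − logit(e_b/n_b)`, `Var(y_k) = 1/e_k + 1/(n_k−e_k) +
1/e_b + 1/(n_b−e_b)`, and `Cov(y_k, y_j) = 1/e_b + 1/(n_b−e_b)` for the
shared baseline arm of a multi-arm study.  The baseline arm is the
lexicographically smallest treatment label in the study; this is purely a
parameterisation choice and all reported quantities are invariant to it
(checked by tests against the alternative "largest label" rule and
against relabelling the reference treatment).

Two nested generalized-least-squares models are fitted with weights
`(S + τ²P)⁻¹`, block-diagonal by study:

* the consistency model `y = Xβ`, with `T−1` basic parameters versus a
  reference treatment;
* the design-by-treatment interaction (DBT) model `y = X_dbt θ`, with a
  separate parameter set per design (the set of treatments a study
  compares), parameterised against each design's own baseline.  In this
  parameterisation `X_dbt` always has full column rank, so the number of
  inconsistency parameters is `Σ_d (t_d − 1) − (T − 1)` for a connected
  network — the closed form used by the structural metrics — and equals
  `rank(X_dbt) − rank(X)` computed from the matrices (asserted as a
  cross-module identity in the tests).

A single between-study variance `τ²` is shared by every comparison in a
network.  That forces the compound-symmetry structure `P` (1 diagonal,
0.5 off-diagonal within a study block): it is the unique exchangeable
structure under which every pairwise contrast inside a multi-arm study
has heterogeneity variance exactly `τ²`.  Comparison-specific
heterogeneity models are out of scope.

`τ²` is estimated either by a matrix generalisation of the
DerSimonian–Laird moment method, `τ̂² = max(0, (Q − df) / tr[(W₀ − W₀M(M'W₀M)⁺M'W₀)P])`
with `W₀ = S⁻¹`, or by REML, maximising
`−½[log|Σ| + log|M'Σ⁻¹M|₊ + rss(τ²)]` over `τ² ∈ [0, 10·τ̂²_DL + 1]` by
bounded derivative-free scalar search (`xatol = 1e−8`; the boundary value
0 is compared explicitly against the interior optimum).  `|·|₊` is the
pseudo-determinant on the estimable subspace, so rank-deficient design
matrices are handled; both estimators reduce exactly to their classical
pairwise forms in a two-treatment network (verified against independent
oracles and against a multivariate REML reference fit).

## The global Wald test

The inconsistency parameters are `ω = Cθ`, with the rows of `C` an
orthonormal basis of the left null space of the embedding matrix `A`
(`X_dbt A = X`), obtained by singular value decomposition.  The statistic
`Q_inc = ω̂'(CV_θC')⁺ω̂` is referred to χ² with `df = rank(X_dbt) − rank(X)`
degrees of freedom, treating the plugged-in within-design `τ̂²` (estimated
on the DBT model with the same estimator chosen for the consistency
model) as known.  The statistic is invariant to the choice of basis `C`
and equals the drop in generalized residual sum of squares between the
consistency and DBT fits at the same `τ²`; the implementation computes
both routes and raises if they disagree beyond 1e−8 relative.  Networks
with a single effective design (`df = 0`) are reported as "not
applicable", never as `p = 1`.

When the DBT model is saturated (one study per design) the within-design
variance has no information; it is set to 0 with an explanatory note so
that batch runs never abort on such networks, while the low-level
estimators still raise on zero residual degrees of freedom.

At `τ² = 0` Cochran's Q decomposes exactly into a within-design part (the
DBT-model residual) and a between-design part (the Wald statistic); this
identity is one of the acceptance checks (residual below 1e−10 relative
across 100 random networks).

## Numerical choices

* Matrix ranks and pseudo-inverses use a tolerance of 1e−8 relative to
  the largest singular (eigen) value.
* All cross-products are inverted with Moore–Penrose pseudo-inverses via
  symmetric eigendecomposition; block solves use Cholesky factors and
  report the offending study if a block is not positive definite.
* Continuity correction: if any cell (events or non-events) of any arm of
  a study is zero, 0.5 is added to every cell of every arm of that study
  (events + 0.5 out of n + 1).  The correction is study-level so the
  corrected covariance block stays positive definite; all-zero-event
  studies are retained after correction.  Zero-cell handling is a known
  source of small discrepancies between NMA implementations.
* Two-arm-only networks take a vectorised scalar-block fast path in the
  GLS core; results are identical to the general block path.

## The synthetic-data generator

`synthetic_data` draws networks of randomised trials with known truth:
per study, a baseline log-odds (fixed, or logit-normal across studies —
default mean `logit(0.2)`, SD 0.5, so baseline risks vary realistically
around 20%), study random effects that are multivariate normal with
variance `τ²` and compound-symmetry 0.5 correlation across the study's
contrasts, and binomial event counts per arm.  Inconsistency is planted
as fixed design-specific shifts `ω` on a design's contrasts — exactly the
DBT model's alternative hypothesis, rather than loop-specific shifts,
because that is the hypothesis the test targets.  Seeding is
stream-based: one root seed spawns an independent substream per
replicate, so runs are order-independent and exactly reproducible.

What the generator does **not** emulate about published networks:
selective reporting and risk-of-bias structure, dose/formulation lumping
decisions, non-exchangeable heterogeneity across comparisons, correlation
between arm sizes and effects, and the empirical distribution of network
geometries.  Passing Monte-Carlo checks therefore validate the
statistical machinery under the stated generating model, not the
behaviour of the test on any particular published corpus.

## Study conditions used by the harnesses and acceptance checks

Chosen once, as the package's own defaults, to resemble a median-sized
published network (a triangle is the smallest geometry with a loop; 18
studies is close to the typical study count of published networks):

* **Type-I error**: triangle ABC (designs AB/AC/BC), 6 studies per
  design, 1000 patients per arm, `τ = 0`, true effects (0.3, 0.5); 4000
  replicates, so the Monte-Carlo SE (~0.003) is well below the width of
  the acceptance band.  Plugging in an *estimated* within-design `τ̂²`
  makes the test mildly conservative relative to the exactly calibrated
  known-`τ²` statistic; the acceptance band accommodates this.
* **Power**: the same triangle with `ω = 1.5` on the B:C design, 10
  studies per design, 2000 per arm, 500 replicates.
* **τ recovery**: `τ = 0.5`, 50 studies per design, 1000 per arm, 200
  replicates (REML, consistency model).
* **Heterogeneity absorption**: `ω = 0.5`, `τ = 0`, 6 studies per design,
  200 replicates; the consistency-model `τ̂` absorbs the between-design
  disagreement while the DBT `τ̂` stays near zero.
* **Null-distribution checks** (Q_inc ~ χ²_df, uniform p-values) plug in
  the true `τ² = 0` as known, since that is the regime in which the χ²
  null law is exact; the estimated-`τ̂²` pipeline is covered by the
  type-I-error band instead.
* The synthetic survey in `scripts/acceptance.py` generates 40 random
  eligible networks (4–6 treatments, a closed loop, 1–5 studies per
  design, `τ ~ U(0, 0.3)`), plants a design shift of 1.0 in about 15% of
  them, and runs the full batch pipeline.

## Survey-pipeline analysis choices

Where several reasonable analysis conventions exist, the pipeline fixes:
raw (untransformed) DBT p-values correlated against the natural log of
each structural characteristic, with zero-multi-arm networks counted as
one multi-arm study before the log so they are not dropped; an ordinary
least-squares (gaussian identity) regression of the raw p-value on the
numbers of studies, treatments, direct comparisons and loops, with a
generalized-inverse fallback and a rank-deficiency flag under
collinearity; Kruskal–Wallis for subgroup comparisons of p-value
distributions (rank-based, matching a box-plot presentation); and a
Cochran–Armitage chi-squared trend test for inconsistency rates over
publication years.  Fourth-root p-value summaries are emitted for
plotting parity only and feed no statistic.  "Loops" are counted as the
dimension of the cycle space of the simple graph of direct comparisons
(edges − nodes + components): multi-edges collapse, and a three-arm
design contributes one triangle.

## Known limitations

* Odds ratios only; no risk ratios, risk differences or continuous
  outcomes, and no arm-based (one-stage binomial) likelihood.
* No local inconsistency methods (loop-specific screening,
  node-splitting); the global Wald test is the only inconsistency
  statistic.
* The plug-in Wald test treats `τ̂²_within` as known; with few
  within-design degrees of freedom the χ² reference is approximate and
  the test is conservative at small `τ`.
* Disconnected networks are a hard error rather than being analysed
  component-wise.
* The multivariable-regression response is a raw p-value in [0, 1]; OLS
  is used as a descriptive convention, not a calibrated model.
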