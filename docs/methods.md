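# Methods

This note documents the models, defaults and numerical choices behind
`copetrend`, and what the synthetic-data generator does and does not
emulate.

## Conventions

Two time scales coexist: **ages** in Ma before present (parents older than
children) and **depths** in Ma forward from the root. All conversions go
through `CalibratedTree` (`age = root_age − depth`); nothing else mixes the
two. Traits are log10 wingspans in log10 metres; rates β are in
log10(m)²/Ma; attractions α in 1/Ma.

## Time calibration

A cladogram plus stratigraphic ranges becomes a set of replicate calibrated
trees. Per replicate: polytomies are resolved by sequential random
attachment (each child subtree inserted on a uniformly chosen edge of the
growing local tree, which samples uniformly among the (2k−3)!! rooted
binary arrangements of a k-way polytomy); each tip age is drawn uniformly
within its [age_min, age_max]; minimum node ages are the oldest descendant
tip age.

Two rules then remove zero-duration branches:

* **mbl** (default, 2 Ma; a 1 Ma variant is a parameter): a tips-to-root
  pass enforces `parent_age ≥ max(child ages) + min_bl`, so every branch is
  at least `min_bl` long and tip ages never move.
* **equal**: each maximal connected run of zero-duration branches borrows
  the duration of the first positive branch above it (the donor); along
  every path through the run, branch durations become equal shares of the
  donor. When zero branches reach the root (which happens whenever the
  oldest tip pins the root's minimum age), the root age is first raised by
  `root_buffer` (default 2 Ma) to create the donor. For mbl no root buffer
  is applied (the two-pass rule already separates the root from its
  children).

Regimes are painted onto branch *segments*: clade paintings assign whole
branches to the most exclusive containing clade, stem branch included
(crown-only painting is a switch); era paintings split branches exactly at
each boundary age they cross (not by branch midpoints). Either way the
segments tile the tree exactly, which the `RegimeMap` validator enforces.

## Trait assembly

Wingspan is the summed length of one wing's skeletal elements — humerus,
ulna, metacarpal IV, wing-finger phalanges IV-1..IV-4 — times the adult
rescale factor, in log10 metres. The radius is excluded from the default
sum as anatomically parallel to the ulna; the element list is a parameter.
Juvenile/subadult-only taxa are dropped before analysis.

Missing data are estimated in two stages, both by generalized least squares
under Pagel's λ:

1. records missing only phalanx IV-4 are filled from phalanx IV-3 (λ = 1,
   log10 scale); filled values carry the regression's residual standard
   deviation, which propagates into the wingspan error by the delta method
   (elasticity ph4/wingspan);
2. records without a computable sum get an estimate from the first
   available predictor in a configurable preference order (default phalanx
   IV-2, IV-1, humerus, mandible), with that predictor's **mean standard
   estimate error** (the SD of predicted-minus-known wingspans on training
   taxa) as their standard error. Directly summed wingspans have se 0.

λ acts on the phylogenetic **correlation** matrix (off-diagonals scaled,
unit diagonal). This is the convention under which λ = 0 is *exactly*
ordinary least squares on any tree — on non-ultrametric trees the
covariance-scaled variant would instead be a weighted regression — and
λ = 1 on an ultrametric tree reproduces the independent-contrasts slope.
ML λ is found on [−0.2, 1.3] (estimates slightly outside [0, 1] occur in
practice) by a 31-point grid plus bounded local refinement, rejecting any λ
where the matrix loses positive-definiteness. Per predictor, the λ = 0 and
λ = 1 fits are compared by AICc (k = 3: two coefficients and the residual
variance; k = 4 when λ is estimated) and predictors are ranked by the
retained model's R² (a GLS R², guaranteed in [0, 1] for nested fits).

An outlier exclusion list (taxa with atypical proportions) applies to
regression *fitting* only; excluded taxa still receive trait values.

## OU likelihoods

All families share one forward recursion over branch segments. Crossing a
segment of duration dt in regime r multiplies the state's deviation by
f = exp(−α_r dt), adds (1 − f) of θ_r to the expectation, and adds
−(β_r/2α_r)·expm1(−2α_r dt) to the variance. Accumulating (A, Vs, W) per
node gives the tip covariance V_ij = exp(2A_u − A_i − A_j)·Vs_u (u = MRCA)
and the mean-weight matrix in one pass. Every exponent is non-positive, so
strong attraction cannot overflow, and `expm1` keeps the α → 0 limit
accurate to ~1e−9 relative at α = 1e−10. Brownian motion is its own family
(V = β·S with S the shared path-time matrix); inside OU families α is
bounded below at 1e−6/Ma rather than 0 for the stability of 1/α terms.

Measurement error adds se² to the covariance diagonal (`mserr`); directly
measured wingspans contribute se = 0.

**Fitting.** Conditional on the variance parameters, optima and root value
are linear: they are solved by GLS, and −lnL is minimized over log α and
log β by L-BFGS-B from 8 seeded starts whose α values span half-lives from
1 Ma to 10× tree depth (β starts scale the trait variance by tree depth,
jittered). Infeasible points (covariance not positive-definite, or a mean
design made singular by the α → 0 collapse of a separate-root model) return
a large finite penalty. Convergence tolerance is 1e−12 relative on the
objective. A fit where no start yields a feasible optimum is flagged
unconverged and the pipeline drops that replicate tree from aggregation
(with a reported success count) rather than imputing values.

**Root modes.** `root_equals_basal_theta` aliases Z₀ to the basal regime's
optimum (the Z₀ mean-weight column is folded into that regime's column);
`separate_Z0` estimates it. Parameter counts follow directly from the free
parameters: k = (free α) + (free β) + (mean-design columns), e.g. BM1 = 2,
OU1 = 3, two-regime OUM = 4 (root aliased) or 5 (separate root). Because
published analyses rarely state their k conventions, both root modes are
available and AICc is always reported next to k and lnL so rankings can be
re-derived under a different convention.

**Standard errors.** Two are reported per optimum. `theta_se` is the
conditional GLS standard error — the quantity comparative-methods tables
conventionally print, well-defined even at the α boundary. It treats (α, β)
as known, and simulation shows it understates uncertainty when α is weakly
identified: θ and α trade off along a likelihood ridge (an overestimated α
pulls the optimum toward the tip mean). `theta_se_full` therefore inverts
the joint observed information over (log α, log β, optima) — central
differences, steps 0.05 on log-variance parameters and 0.01 on optima —
and is floored at the GLS value (conditioning can only remove
uncertainty). Coverage statements should use `theta_se_full`; in recovery
simulations its ±2 se interval covers the true optima ~91–97% of the time
versus ~86% for the conditional se. When the information matrix is not
positive-definite at the optimum, the GLS value is reported for both.

**Derived quantities.** Phylogenetic half-life ln(2)/α (infinite at α = 0);
equivalent trend coefficient μ = α·θ with bounds α(θ ± 2 se) — the α → 0
limit of an OU model with a distant optimum is Brownian motion with drift
μ; optima back-transformed to metres as 10^θ. Aggregation across replicate
trees reports *both* the half-life of the median α and the median of
per-tree half-lives: the two differ noticeably for skewed α distributions,
and published tables do not always say which was used.

## Model comparison and trends

AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); Akaike weights are normalized relative
likelihoods within each replicate's candidate set (they sum to 1 per tree).
Across replicates the summary reports medians and absolute ranges of the
parameters and median/IQR of the weights, and flags models whose median
weight is at least half the best model's.

The era-split trend regressions are deliberately non-phylogenetic: they
describe the realized size-age distribution (lineage evolution plus species
sorting), complementary to the model fits. OLS slopes carry t-based 95%
CIs; major-axis slopes (the leading principal axis of the age-size
covariance, appropriate when neither axis is error-free) carry seeded
2000-resample bootstrap CIs. Taxon ages default to stratigraphic midpoints,
with an option to reuse the sampled tip ages; a taxon exactly on the
boundary goes to the older interval. Since age is measured before present,
a size increase toward the present is a negative slope; reversing the age
axis flips the sign exactly.

## Synthetic data

The generator emulates the study conditions the pipeline was built for:

* **tree**: forward birth–death with extinct lineages kept as fossil tips,
  90 tips spanning 160 Ma, root at 228 Ma before present. Birth/death
  defaults (0.09/0.07, high turnover) were set so that ~25% of tips predate
  the 150 Ma regime boundary, matching the emulated record's pre/post
  split, rather than the ~10% a strongly growing process leaves.
* **regimes**: default two-era shift at 150 Ma — a constrained basal regime
  (α = 0.03/Ma, half-life 23 Ma, θ = 0 log10 m ≈ 1 m) and a
  trending/attracted derived regime (α = 0.015/Ma, θ = 0.9 log10 m ≈ 8 m,
  an optimum above the realized sizes, so lineages climb throughout);
  β = 0.0008 log10(m)²/Ma in both; clade-shift and single-regime scenarios
  are alternatives (the clade scenario's derived fraction, 0.74 of tips,
  matches the emulated study's basal/derived taxon split of 19 vs 53).
* **traits**: exact OU transition sampling per branch segment (the
  Euler–Maruyama discretization exists only as a test oracle), observation
  noise 0.05 log10 m (the scale of the wingspan-regression estimate
  errors).
* **measurements**: wing elements are fixed anatomical fractions of the
  summed wing skeleton, so recomputing the sum recovers the trait exactly;
  cranial elements scale allometrically with lognormal noise. Stratigraphic
  windows are U(2, 10) Ma wide around the true tip age.
* **missingness**: block-structured — a 25% complete-specimen fraction plus
  independent per-element deletion among the rest, scaled so marginal
  missingness matches the per-element targets (distal wing elements
  missing most often). The `apply_missingness` operation itself is pure
  independent Bernoulli; the block structure lives in `generate_dataset`.

What the generator does **not** emulate: correlated stratigraphic errors
between related taxa, non-uniform preservation through time,
ontogenetic-stage misassignment, allometric deviations of element
proportions across the tree (elements are a fixed fraction of wing length,
so single-predictor regressions are better behaved on synthetic data than
on real skeletons), and topological error in the cladogram. Passing tests
therefore demonstrate the correctness of the estimators under the model's
own assumptions, not robustness to those violations.

## Known limitations

* ML (not REML) variance parameters: α is noticeably variable at n ≈ 100
  (recovery simulations show median α̂ within a factor ~1.2 of truth but
  replicate scatter of a factor ~2), which is why the full-information se
  matters for the optima.
* The 'equal' calibration generalizes the equal-share rule to *branching*
  runs of zero branches by equalizing along every path through the run;
  chains reduce to the classic behaviour.
* Era paintings on trees whose root is younger than every boundary collapse
  to a single era; the pipeline then skips that scheme for that replicate
  with a warning.
* Major-axis bootstrap CIs are percentile intervals; no BCa correction.
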