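# Methods

This note records the statistical model, the concrete algorithmic choices,
the default parameters and the simulation conditions used throughout `mrnet`,
including every place where the design was genuinely open.

## Data model

All estimators and learners assume a linear-Gaussian structural equation
model (SEM). Entities `M_1 … M_p` follow

    M_j = Σ_i w_ij M_i + Σ_h α_h IV_h + Σ_u λ_uj U_u + ε_j,
    ε_j ~ N(0, σ_j²),  U_u ~ N(0, 1) latent,

with the weighted adjacency `W = (w_ij)` acyclic. Instruments are genotype
dosages (raw 0/1/2 values; Hardy-Weinberg, variance `2·maf·(1−maf)`).
The implied covariance is `(I − W)⁻ᵀ S (I − W)⁻¹` with
`S = Aᵀ diag(v) A + Λᵀ Λ + diag(σ²)` collecting instrument loadings `A`
(including pleiotropy edges), confounder loadings `Λ` and noise; the
simulator exposes this closed form (`sem_covariance`, `joint_covariance`) so
empirical moments and learner behavior can be checked against an exact
oracle. Gaussian noise is an implementation choice — the estimators are
method-of-moments/least-squares and only rely on second moments, but the
Fisher-z conditional-independence tests are exact only under Gaussianity.

## Simulator defaults (the reference study conditions)

* Minor-allele frequency 0.3 for study genotypes (uniform 0.05–0.5 when a
  range is requested). Dosages are two Bernoulli(maf) draws summed.
* Random DAGs: a uniform permutation fixes a causal order; each of the
  C(n,2) ordered slots receives an edge independently with
  `p = min(1, d/(n−1))` where `d` is the expected out-degree, so the expected
  edge count is `p·n(n−1)/2` (= `d·n/2` for `p < 1`). Nonzero weights are
  uniform in magnitude on [0.3, 0.9] (recovery studies use [0.4, 0.8]) with
  random sign.
* Sparsity `d = 1.0` for recovery studies — metabolite-scale omics networks
  are sparse, with typical degree near 1–2.
* One instrument per entity with first-stage effect α = 0.5–0.6 and unit
  noise: first-stage F at n = 5000 is then in the hundreds, comfortably
  "strong" without being degenerate.
* Confounders are latent standard-Normal factors with an explicit loading
  matrix (zero in the recovery studies, which probe learning under valid
  instruments; nonzero in the confounding demonstrations).
* Two-sample cohorts are regenerated from the same MAF vector with different
  seeds — never row-resampled — so they are fully independent.
* Deliberate violations are injected as explicit instrument → off-target
  edges (`inject_pleiotropy`) of size 0.3.

What the simulator does **not** emulate: linkage disequilibrium, population
structure, non-linear or binary traits, case-control sampling, measurement
error. Passing tests therefore show correctness of the estimators and
learners under their stated assumptions, not robustness to those real-data
complications.

## Classical estimators

* First stage: ordinary least squares of the (covariate-residualized)
  exposure on all its instruments jointly; `predicted` are fitted values from
  instruments only; F is the standard joint-significance statistic.
* Multivariable MR / 2SLS standard errors: the two-stage sandwich
  `σ̂²(X̂ᵀX̂)⁻¹` with residuals evaluated at the observed exposures (the
  proper 2SLS estimator); a seeded nonparametric bootstrap is available. The
  source text for the design gives point estimators only, so the se choice is
  ours; the sandwich is the community default.
* Wald ratio: first-order delta method,
  `se² = se_gy²/β_gx² + β_gy²·se_gx²/β_gx⁴`. Denominators must clear a
  weak-instrument floor `|β_gx|/se_gx ≥ 2` (configurable); first stages in
  mediation must clear F ≥ 10. Both thresholds are conventions, not derived.
* Mediation: `φ = β − τγ` holds exactly by construction;
  `Var(φ) ≈ Var(β) + γ²Var(τ) + τ²Var(γ)` treats the three stage estimates
  as independent, which is first-order correct when the two instruments are
  independent.
* Covariates are residualized out of exposure, instruments and response
  before any IV fitting (the adjust-first ordering of the pipeline).

## Instruments

* Polygenic factors: PCA of the centered dosage matrix, or correspondence
  analysis of the one-hot genotype-class expansion (per-variant classes that
  never occur are dropped). Scores are orthogonal in-sample; a deterministic
  sign convention (largest-|loading| entry positive) makes runs reproducible.
* Assignment is exclusive: each candidate instrument goes to the entity where
  its univariate first-stage F is largest (ties broken lexicographically),
  provided F clears the threshold (default 10). Exclusivity prevents one
  factor from instrumenting both sides of an edge. Entities with no
  instrument are *kept* — they surface later as bidirected edges.
* The pleiotropy screen for `M_i → M_j` is the t-test of the IV coefficient
  in `M_j ~ M_i + IV` (equivalently the partial correlation of `M_j` and IV
  given `M_i`), at level 0.05 by default. The underlying property specifies
  conditional independence but not a test statistic; the two-regressor t-test
  is the exact finite-sample test under the linear-Gaussian model. A failing
  instrument is excluded *for that pair only*.

## Network identification

* Skeleton: PC-stable with Fisher-z partial-correlation tests. Neighborhoods
  are frozen at the start of each conditioning level, pairs and conditioning
  subsets are enumerated lexicographically, and separating sets are recorded
  — the learner is deterministic given the data and configuration. With a
  population covariance (`n = None`) a partial correlation below 1e-8 counts
  as an exact zero, which turns the learner into its own asymptotic oracle;
  on exact input the skeleton equals the true DAG adjacency.
* Orientation: for edge `M_i – M_j`, direction `M_i → M_j` is supported when
  `M_i`'s strongest valid instrument is marginally associated with `M_j`
  *and* passes the pleiotropy screen given `M_i`. Support on both sides is a
  conflict → bidirected (logged); no instrument on either side → bidirected
  (the direction is unidentifiable without genetics — in real metabolomic
  data this is the signature of diet-driven entities); an instrumented but
  inconclusive edge
  stays undirected, reserving "bidirected" for genuinely instrument-less
  pairs. Screening in both directions before declaring a conflict is our
  interpretation; the alternative (first-found wins) is order-dependent.
* Conditioning on the exposure alone identifies the direction exactly in
  polytrees; when two adjacent entities share a parent the screen's
  conditional independence fails structurally and the edge remains
  unoriented rather than mis-oriented. The shipped oracle specs are
  polytrees for this reason.
* Acyclicity: directed proposals are applied in decreasing confidence
  (confidence = min(pleiotropy p-value, 1 − marginal p-value); subsample
  edge frequency where available); any proposal that would close a directed
  cycle is reverted to undirected and logged.
* Hamming distance: each unordered pair has a status in
  {absent, i→j, j→i, unoriented} (undirected and bidirected pool as
  unoriented); any status mismatch costs 1. This makes presence/absence and
  orientation errors equally expensive, which is the convention used for both
  tuning and recovery scoring.
* Tuning: for each candidate level, skeletons are learned on 10 seeded
  subsamples (70% without replacement) and the mean pairwise Hamming distance
  recorded; the minimizing level wins, ties toward the smaller level.
  Skeletons (not oriented networks) are compared because orientation is
  instrument-driven and does not depend on the level. Default grid
  {0.05, 0.01, 0.001}.
* Edge effects: each directed edge `M_i → M_j` carries the coefficient of
  `M_i` in the regression of `M_j` on all of `M_j`'s directed parents.
* Instruments enter only the orientation stage, never the skeleton stage.

## Stability diagnostics

* Backdoor sets are enumerated exhaustively (all subsets up to `max_size`,
  all simple paths; intended for small graphs). Any undirected/bidirected
  edge on a simple path between the query nodes raises an ambiguity error
  rather than silently picking a resolution.
* The confounding-equivalence display over discrete strata reduces, under the
  linear-Gaussian model, to the X coefficient in `Y ~ X + S`; the test is a
  Z-test on the difference of the two X coefficients. Because both estimates
  share one sample, the variance of the difference comes from a seeded paired
  bootstrap (500 resamples by default) or an influence-function closed form.
  The variable-increment test uses the same machinery for nested models.
* ROC tests score candidate edges by their frequency across learner
  subsamples (the score axis is otherwise unspecified in the literature this
  follows); labels are the original network's edges. Receptor removal sizes
  run k = 1…3 and results pool over k. Permutation groups are drawn without
  replacement within *exact* (in-degree, out-degree) classes of pure
  receptors or broadcasters; if no class is large enough the test reports
  not-applicable instead of relaxing the match. Identity permutations are
  rejected and redrawn. Besides the remainder AUC, the permutation test
  reports the AUC over edges incident to the permuted nodes, which is the
  readout that collapses when broadcasters are permuted.
* Default pass floors: AUC ≥ 0.8, test level 0.05 — configurable defaults,
  not derived quantities.

## Network analysis

* Broadcaster: no arrows in, arrows out. Receptor: arrows in, none out.
  Undirected/bidirected edges count toward hubness (total degree) but toward
  neither role. Hub threshold defaults to the 95th percentile of total
  degree ("highly connected" made concrete).
* Modules: greedy modularity maximization on the |effect|-weighted undirected
  projection (deterministic); the per-module summary reports size, internal
  weight mass, and boundary nodes with their in/out-degrees — the border
  criterion is reported, not enforced.
* Outcome integration appends the trait after the network is fitted,
  mirroring the network-first-then-outcome sequence. The trait is constrained
  to be a pure receptor, so its skeleton neighbors are exactly its direct
  parents and no trait → entity orientation can occur by construction; only
  the trait's incident independencies are tested. Parent effects come from
  the joint regression of the trait on all parents; non-parents are annotated
  with their directed mediating paths.

## Reference study sizes

The reproducibility studies (`mrnet.evaluation`, run by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: pleiotropy
calibration n = 2000 × 1000 reps; single-IV equivalence 100 datasets of
n = 500; two-sample agreement 100 rep pairs of n = 10,000; finite-sample
recovery 20 seeds of 20 entities at n = 5000 with tuning selection over
{0.05, 0.01, 0.001}; Z-test calibration 500 size reps and 200 violation reps
at n = 5000 with 500 bootstrap resamples; reduction/permutation studies on a
fixed 20-node design with degree-matched broadcasters and receptors;
outcome integration 20 seeds of 30 entities, 9 trait parents, n = 5000;
backdoor validation over every DAG with ≤ 5 nodes (all canonical
upper-triangular patterns × all ordered query pairs, which covers all labeled
DAGs because both the enumeration and the d-separation oracle are
label-equivariant).

## Known limitations

* The pleiotropy screen conditions on the exposure only; edges whose
  endpoints share a parent stay unoriented (see above). Conditioning on
  discovered parent sets would extend identification but is deliberately out
  of scope here.
* Constraint tests are Gaussian; heavy-tailed omics should be transformed
  first.
* Backdoor enumeration and the stability ROC tests re-learn networks and are
  meant for tens, not thousands, of entities per call.
* Summary-statistic-only network identification, pleiotropy-robust
  summary-data estimators (Egger/median/mixture-type), latent-variable
  discovery and non-linear models are out of scope.
* PC-stable's sequential edge removal does not *guarantee* that skeleton edge
  count is monotone in the test level on every dataset, although it holds in
  all shipped studies; the monotonicity check is part of the acceptance
  suite.
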