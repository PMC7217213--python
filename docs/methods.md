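# Methods

## Model and estimation

All estimation is contrast-based weighted least squares. The data are
`m` pairwise comparisons `d_j` (effect of `treat1` minus `treat2` on an
additive scale such as the log odds ratio) with standard errors treated
as known. The standard NMA model is `d = Bθ + ε` with `B` the m×n
edge–vertex incidence matrix; the additive CNMA model is `d = BCβ + ε`
with `C` the n×c treatment-by-component combination matrix. Because `B`
annihilates constants, only contrasts of `θ` are identified; we solve
through the Moore–Penrose pseudoinverse of the information matrix
(`BᵀWB` is the weighted graph Laplacian) and report `θ̂` against a
chosen reference. In the CNMA model the inactive treatment (placebo by
default) is the all-zero row of `C`: this is a modelling assumption
(adding placebo to a treatment changes nothing), distinct from merely
choosing a reference for reporting, and `β̂` is interpreted against it.

Interaction models append columns to `C` — entry 1 for every treatment
containing all members of the interacting set, labelled `A*B` with the
member names sorted. The same mechanism accepts three-way and higher
sets, and `build_combination`'s dose mapping allows entries above 1
(a doubled dose coded as 2 contributes twice the component effect).
Interaction sets that co-occur in no treatment are rejected: their
column would be identically zero and the coefficient pure noise.

### Identification policy

`fit_cnma` requires `rank(X_a) = c` by default and otherwise raises an
error naming the components whose unit vectors fall outside the row
space. Pseudoinverse output on a rank-deficient design is well defined
but easy to misread as full identification, so working in the estimable
subspace is opt-in (`allow_rank_deficient=True`), and is the default
route only in `fit_disconnected`, whose purpose is exactly that
setting. A contrast `v` is declared estimable iff the residual of `v`
after projection onto the row space of `X_a` has norm below 1e-10
(relative); estimable contrasts are invariant to the choice of
generalized inverse, and their Wald variances come from the
pseudoinverse covariance `(X_aᵀWX_a)⁺`. For disconnected fits a
reference component may instead be named, in which case its column is
dropped from `C` and `X_a` before solving; the reduced coefficients are
then read as contrasts against the reference *under the additivity
assumption*. For partially identified disconnected fits the reported
covariance is the WLS covariance of the chosen (restricted or
pseudoinverse) parameterization.

No additivity test is offered on disconnected networks: the comparator
(the standard NMA model) does not exist there, and `additivity_test`
refuses such fits with an explicit message rather than returning a
p-value.

## Heterogeneity, Q statistics, and the additivity test

`Q = (d − δ̂)ᵀW(d − δ̂)` is always computed at the common-effect
weights; its degrees of freedom are `n_a − k − rank(design)` where
`n_a` is the total number of arms and `k` the number of studies
(`k − rank` for two-arm-only networks). `I² = max(0, (Q−df)/Q)`,
reported as NaN for saturated fits (df = 0).

The between-study variance uses the multivariate method of moments
`τ̂² = max((Q − df) / tr((I−H)UW), 0)`, where `U` is block diagonal:
starting from `0.5·BBᵀ` (diagonal 1, entries ±0.5 for contrasts sharing
an arm), the `p(p−1)/2`-square block of each study's contrasts is kept
and everything off-block zeroed. For two-arm-only networks `U = I` and
the denominator is the familiar generalized DerSimonian–Laird quantity
`Σ w_j (1 − h_jj)`. τ² is re-estimated separately under each design
(standard, additive, interaction) since the models absorb different
amounts of between-study variation. A random-effects fit adds `τ̂²` to
every **raw** sampling variance, re-runs the multi-arm adjustment, and
refits; the reported `Q`, `df`, `I²` remain the common-effect
quantities.

The additivity test exploits that `H` and `H_a` are commuting
projections, so `Q_a − Q = (δ̂_a − δ̂)ᵀW(δ̂_a − δ̂)` ~ χ² on `n − 1 − r`
df. The default (`weights="common"`) uses the common-effect Q values
and is the statistic usually quoted alongside NMA results; note that
under genuine between-study heterogeneity it conflates heterogeneity
with non-additivity and rejects too often. `weights="random"`
recomputes both projections on shared random-effects weights (τ̂² from
the standard fit), which restores approximately nominal size — in our
Monte-Carlo check at τ² = 0.04 the empirical size is ≈ 6% at the 5%
level over 10⁴ replicates (the small residual inflation comes from
plugging in an estimated τ̂²), versus ≈ 13% for the common-weights
variant under the same conditions. Nested CNMA models are compared by
the analogous Q difference with df equal to the rank difference;
nesting is verified by projecting the sparser design's columns onto the
richer column space.

## Multi-arm adjustment

A p-arm study's `p(p−1)/2` contrasts are correlated. We recover arm
variances `s_i²` by least squares from the contrast variances
(`v_jk = s_j² + s_k²`; exactly determined for p = 3, overdetermined
above), then set the adjusted weight of contrast (j,k) to
`w_jk = (1/s_j²)(1/s_k²) / Σ_i 1/s_i²`. This makes the study's
edge-weight Laplacian equal the arm-level GLS information matrix
`diag(w) − wwᵀ/Σw` exactly, which is the contract the tests verify for
p = 2…5. Consequences: equal contrast variances `v` yield adjusted
variance `v·p/2`; two-arm studies are unchanged; the operation is
idempotent. If the observed variances are inconsistent with any
arm-based decomposition beyond a relative 1e-8, the least-squares
reconciliation is used with a warning; an implied non-positive arm
variance is an error, since no arm-level model could have produced the
data.

## Arm-level input

Binary arm-level tables are converted to log odds ratio contrasts per
within-study pair, `se = √(1/a + 1/(n₁−a) + 1/b + 1/(n₂−b))`, with 0.5
added to all four cells of any 2×2 table containing a zero
(per-comparison continuity correction). Within a study the constructed
log ORs are exactly consistent (`d_xy + d_yz = d_xz`). Mean-difference
pooling from raw means/SDs and risk-ratio construction are out of
scope; such effects can be supplied pre-computed as contrasts.

## Synthetic data generator

`simulate(SimSpec(...))` emulates the structure of combination-treatment
networks like the antidepressant example: an inactive placebo, single-
and multi-component treatments, mostly two-arm studies with occasional
three-arm ones. Defaults: three components with true log ORs 0.55, 0.35,
0.15 (ORs ≈ 1.7/1.4/1.2), seven treatments, 30 studies with a 4:1
two-to-three-arm mix, contrast standard errors drawn in [0.2, 0.5] —
the magnitudes typical of response outcomes in moderately sized trials —
and τ² = 0 unless specified. `depression_like_spec()` scales this up to
the 22-treatment / 18-component / three-combination structure with two
placebo-controlled studies per treatment plus head-to-head and
three-arm studies.

Randomness enters at the **arm** level, which is what makes the draws
compatible with the fitted model: each arm receives a random effect
`u_i ~ N(0, τ²/2)` — so every contrast has marginal heterogeneity
variance τ², contrasts sharing an arm have covariance τ²/2 (exactly the
`0.5·BBᵀ` structure the moment estimator assumes), and within-study
consistency of the contrast means is preserved — plus a sampling error
`e_i ~ N(0, σ_i²)` with the recorded contrast standard error
`√(σ_i² + σ_j²)`, so multi-arm contrasts are correlated exactly as the
weight adjustment assumes. A single scalar per study would instead
force pairwise correlation 1 among a study's contrasts and is not the
τ² model being fitted. What the generator does **not** emulate: real
arm sizes and event counts (it draws Gaussian contrasts directly),
non-normal small-sample behaviour of log ORs, selective reporting, and
design-by-treatment inconsistency; passing calibration tests therefore
demonstrates correctness of the estimation machinery under the model,
not robustness to violations of it.

## Numerical choices

- Singular values below 1e-10 × the largest are treated as zero
  everywhere a rank or pseudoinverse is computed (the Laplacian of a
  connected network has exact rank n−1; the cutoff guards float noise).
  The dense least-squares oracle used in tests applies the same cutoff —
  LAPACK's default machine-precision cutoff can keep the Laplacian's
  null direction and amplify rounding noise through a ~1e-15 singular
  value.
- Q values and Q differences are clamped at 0 against −1e-16-scale
  round-off; the Pythagorean identity is verified to 1e-8 inside
  `additivity_test` and treated as a usage error (mismatched weights)
  when violated.
- Wald confidence intervals use normal quantiles on the additive scale
  with no multiplicity adjustment; chi-square p-values with df = 0 are
  reported as NaN.
- Ordering is deterministic: treatments, components and studies sort
  lexicographically unless an explicit order is supplied; contrasts sort
  by (study, treat1, treat2) in those orders. All matrices follow this
  ordering, which is what makes printed designs reproducible.
- Duplicate comparisons within a study are rejected, and a study
  touching p treatments must contribute exactly p(p−1)/2 contrasts.

## Problem sizes

The test suite and acceptance script use networks of up to 8 treatments
and 20 studies for the oracle-equivalence sweep (100 networks), the
51-study depression-like structure for the pipeline checks, 500
replicates for bias/coverage and 1000 for test size — sizes at which
the Monte-Carlo error of a coverage estimate is about ±1 percentage
point, adequate for the 93–97% acceptance band.

## Known limitations

- The Q decomposition into within-design heterogeneity and
  between-design inconsistency is not implemented, nor are node-splitting
  inconsistency models or net-heat diagnostics.
- No automated interaction selection: the primitives (`add_interactions`,
  `compare_nested`) support forward selection, but the search and its
  multiplicity consequences are left to the analyst.
- Standard errors are treated as known constants, as is conventional;
  very small studies violate this.
- Graphical output is limited to plain-text forest tables.
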