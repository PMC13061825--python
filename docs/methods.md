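# Methods

## The testing problem

A confirmatory factor model for a p-vector x posits x = Λf + ε with
uncorrelated residuals, so that Σ(θ) = ΛΦΛ′ + Ψ.  After fitting θ by
normal-theory maximum likelihood (minimizing F(S, Σ(θ)) = ln|Σ(θ)| +
tr(SΣ(θ)⁻¹) − ln|S| − p against the biased sample covariance S), the fit
is tested with either

* T_ML = (N−1) F(S, Σ(θ̂)), or
* T_RLS = (N/2) tr[(I − Σ(θ̂)⁻¹S)²],

which share one asymptotic law.  Under multivariate normality that law is
χ²_d with d = p(p+1)/2 − q.  Under general distributions it is a weighted
sum Σ_j λ_j Z_j², where the λ_j are the d positive eigenvalues of U Γ: Γ
is the asymptotic covariance of vech(S) (a fourth-moment functional of
the data distribution) and U = V − VΔ(Δ′VΔ)⁻¹Δ′V projects the
normal-theory weight matrix V = ½D_p′(Σ⁻¹⊗Σ⁻¹)D_p off the model tangent
space spanned by Δ = ∂vech Σ(θ)/∂θ′.

The estimated eigenvalues λ̂ of ÛΓ̂ are unstable even at large n, which
translates into poor type I error control when they are plugged straight
into the tail probability H(t; λ) = P(Σ λ_j Z_j² > t).  Every procedure
in this package is one choice of stabilizer λ̂ → λ̃:

| label  | λ̃ |
|--------|----|
| ALL    | λ̂ unchanged |
| SB     | grand mean in every entry (the Satorra–Bentler correction) |
| EBAx   | means of x equal blocks of consecutive sorted eigenvalues |
| pEBAx  | (EBAx + grand mean)/2 |
| pEBAdf | (λ̂_i + grand mean)/2 (singleton blocks) |
| pOLS2  | (OLS line of λ̂ on index + grand mean)/2, floored at 1e-8 |
| SS     | scale-and-shift of T matching the χ²_d mean and variance |
| SF     | scaled F approximation from Σλ̂, Σλ̂², Σλ̂³ |

Each is crossed with the base statistic (T_ML or T_RLS) and the Γ
estimator (plug-in or exactly unbiased, suffix UG), giving the 36
robustified tests plus the two normal-theory tests.

## Nested comparisons (measurement invariance)

For nested models M0 ⊂ M1 the difference T_D = T_0 − T_1 has the same
kind of mixture limit with d0 − d1 weights, the eigenvalues of U_D Γ.
U_D is estimated two ways:

* **2000 method** — a single restricted-projection formula evaluated at
  the M1 estimates, U_D = VΔ₁(Δ₁′VΔ₁)⁻¹A′[A(Δ₁′VΔ₁)⁻¹A′]⁻¹A(Δ₁′VΔ₁)⁻¹Δ₁′V,
  with A the Jacobian of the constraints carrying M1 onto M0.
* **2001 method** — U_0 − U_1 with each U at its own model's estimates.

The two coincide at the population parameter (asserted in the tests) but
differ in finite samples; under the 2001 method the trace of Û_DΓ̂ and
the sum of its d0−d1 leading eigenvalues can differ, which is why the SB
difference test comes in an eigenvalue-sum version and the classical
trace version (SB_2001, reported with a warning flag when the scaled
statistic goes negative — that artifact is deliberately not masked).

**Identification choice.**  Weak (metric) invariance is tested with
marker-variable identification: in every group the first loading is
fixed at 1 and the factor variance is free.  Under this parameterization
the constrained model is *exactly* the configural model plus linear
equality constraints ("non-marker loadings equal across groups"), which
is what the 2000 method's constraint Jacobian requires; under
unit-factor-variance identification the same hypothesis is a nonlinear
proportionality constraint.  Both parameterizations describe the same
covariance manifolds, so the fitted Σ̂, the T statistics and all degrees
of freedom (df0 − df1 = (G−1)(p−1)) are unchanged.

## Numerical choices

* **Optimizer**: L-BFGS-B on the N_g/N-weighted discrepancy with the
  analytic gradient tr[Σ⁻¹(Σ−S)Σ⁻¹ ∂Σ/∂θ_k]; gradient tolerance 1e-7,
  max 500 iterations; non-PD trial points get a large penalty value.
  Starting values: loadings 0.7, residual variances half the sample
  variances, factor variances 1, covariances 0.  M1 fits in nested runs
  warm-start from the expanded M0 solution.
* **Multi-group assembly**: V is block-diagonal with blocks (N_g/N)V_g
  and Γ block-diagonal with blocks Γ_g/(N_g/N); only the product UΓ is
  identified, and this split makes its eigenvalues exactly 1 under
  normality with a correct model (asserted at the population in tests).
* **Eigenvalues**: extracted from the symmetric form Γ^{1/2}UΓ^{1/2}
  (with Γ projected onto the PSD cone first); the d largest are kept,
  the remainder checked to be numerically zero in the goodness-of-fit
  case, and negative dust is clipped at 0.
* **Tail probability H**: equal weights reduce to an exact scaled
  chi-square; otherwise Ruben's mixture-of-chi-squares expansion (whose
  truncation error is bounded by the missing mixture mass, target 1e-9)
  for d ≤ 60, an Imhof-type quadrature for larger d, and a 10⁷-draw
  Monte Carlo fallback.  The three routes agree to ~1e-6 on cross-checks.
* **Unbiased Γ (UG)**: αm̂4 + β s s′-terms with α = n(n²−n+2)/((n−1)(n−2)(n−3)),
  β = −(n−1)(n+1)/(n(n−3)), γ = −2(n−1)²/(n(n−2)(n−3)), derived exactly
  from the finite-sample expectations of the ingredient statistics and
  verified unbiased by simulation (a test asserts the mean over 20000
  n=20 replications equals the population Γ of a centered exponential).
* **Unequal blocks** in EBAx/pEBAx: sizes as equal as possible with the
  remainder given to the leading blocks, so larger blocks absorb the
  smallest eigenvalues.
* **SF parameters**: the mixture's mean, squared coefficient of
  variation, and skewness are matched to cF(df1, df2); the latter two
  depend only on (df1, df2), so df2 is a 1-D root find and df1, c follow
  in closed form.  If the skewness equation has no admissible root (the
  equal-weight limit df2 → ∞) a two-moment scaled chi-square is used.

## Synthetic data

Four generator families share an exact target covariance and common
marginal skewness/excess-kurtosis targets — (2, 7) "moderate", (3, 21)
"severe":

* **N** — multivariate normal.
* **VM** — Vale–Maurelli: Fleishman cubic marginal transforms of a
  latent normal whose pairwise intermediate correlations solve the cubic
  moment relation.
* **IG** — independent generator: x = Lu + ε with independent
  standardized non-normal components; the factors carry a boosted share
  of the non-normality (smallest boost making every residual's implied
  cumulants Fleishman-feasible), and each residual's third/fourth
  cumulants are then solved from cumulant additivity so every observed
  marginal hits the targets exactly.
* **PL** — each marginal is a continuous increasing 3-piece linear
  transform of a standard normal (free knots and slopes, least-squares
  calibrated on the first four moments, which are evaluated in closed
  form from truncated-normal partial moments); underlying pairwise
  correlations are root-found so the covariance converges to the target.

The study populations: a five-factor model with p/5 indicators per
factor, loadings drawn once per scenario seed from U[0.5, 1.5], unit
factor/residual variances, and the six interfactor correlations (−.3,
−.2, 0, .1, .2, .3) assigned cyclically to the ten factor pairs; a
one-factor multi-group model with invariant loadings for invariance
testing; a method-factor misspecification (orthogonal unit-variance
factor, alternating-sign loadings, default magnitudes 0.78/0.43/0.32 at
p = 15/30/60 on the odd indicators of the first factor) for
goodness-of-fit power; and group-wise loading perturbations of size h
(default 0.3, applied to two non-marker loadings of the last group) for
invariance power.  Because the default method-factor magnitudes were
originally calibrated against a particular set of drawn loadings, the
power they induce depends on the loading draw;
`calibrate_method_loading` re-solves the defining calibration (50%
asymptotic normal-theory power at n = 800 under normality) for the
population actually drawn, and the power checks in the test suite use
that calibrated magnitude.

**What the generators do and do not emulate.**  They reproduce the
covariance structure and the marginal third/fourth moments exactly in
population.  They do not reproduce any particular real dataset's
higher-order dependence: the three non-normal families deliberately
differ beyond the matched moments (a test separates PL from VM by a
two-sample KS on a marginal).  Passing the Monte Carlo checks therefore
says the procedures control type I error under these calibrated
departures from normality, not under arbitrary real-data non-normality.
Two components are this package's own constructions rather than
transcriptions: the 3-piece PL family and the IG boost allocation; both
are documented above, and rejection rates at small n under severe
kurtosis are somewhat sensitive to such construction details and to the
particular drawn loadings.

## Monte Carlo harness

A condition is (study, p, n, G, distribution, reps, seed).  Seeding is
hierarchical (SeedSequence spawn per replication), so results are
independent of execution order and worker count.  Non-converged
replications are discarded and counted; rejection rates use converged
replications as denominator, and a condition with more than 20%
discards is flagged invalid rather than averaged silently.  Aggregation
criteria over condition sets: RMSE and MAD of the rejection rates
around the nominal 5%, and the shares of rates inside/below/above the
Bradley band [2.5, 7.5] (boundaries inclusive).

Problem sizes in the shipped tests and in `scripts/acceptance.py` are
scaled down from the full 525-condition, 2000-replication campaign: the
suite uses 200–500 replications per asserted condition and the
acceptance script 800, with tolerances widened by the corresponding
binomial standard errors (each derivation is stated where it is used).
The full grids remain available through `ebatest study --scale full`.

## Known limitations

* Mean structures, ordinal-categorical indicators and missing data are
  out of scope; estimation is NTML only.
* General nonlinear nesting constraints are not supported; nesting must
  be expressible as label merges/fixings of the larger model's
  parameters (which covers loading-equality invariance).
* The PL and IG constructions are this package's documented stand-ins
  for the cited generator classes, as noted above.
* The SB_2001 trace statistic can be negative; it is reported as-is
  with a flag.
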