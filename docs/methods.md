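# Methods

## Model and assumptions

`singlesem` fits linear covariance-structure models for p observed
indicators y of m latent variables η:

    η = B η + ζ,        y = Λ η + ε,
    ζ ~ (0, Ψ),         ε ~ (0, Θ),    ζ ⟂ ε,

so the implied covariance matrix is Σ(θ) = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ. B may
have nonzero diagonal entries (self-causative loops, as in loop-simplex
models of repeated measurements); (I−B) invertibility is re-checked at
every evaluation via a sign/log-determinant test and violations reject the
step. Ψ and Θ are symmetric by construction: the two off-diagonal positions
of a cell are the *same* parameter object, so symmetry cannot drift.

Estimation is normal-theory maximum likelihood on the sample covariance
matrix S with N cases:

    F_ML(θ) = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p,    χ² = c · F_ML,

with multiplier c = N−1 by default (the convention of the classical SEM
programs this notation follows; c = N is available). Assumptions inherited
from this framework: multivariate normality, independent identically
distributed cases, linear effects, and a correctly specified structure —
the χ² test addresses only the last.

## The single/best-indicator discipline

Each latent is scaled by one indicator whose loading is fixed at 1.0 (the
"scaling" or best indicator). That indicator's measurement error variance
is *fixed* by the analyst, not estimated. The toolkit treats this as the
central specification act, for a reason the chain simulator makes exact:
when a chain of latents η_A → η_B → η_C all cause the indicator y5, any of
them can serve as "the" latent measured by y5. The choice is operationalized
by the amount of error variance accumulated onto y5 — all disturbances
entering the chain downstream of the chosen latent:

    identity C:  Var(err5)
    identity B:  Var(err5) + Var(errC)
    identity A:  Var(err5) + Var(errC) + Var(errB)

A wrong choice need not produce misfit. With a second indicator y6 caused
directly by η_B, the model reproduces Cov(y5,y6) = λ6·Var(η_B) for *any*
identity choice by a compensating loading estimate
Cov(y5,y6)/Var(chosen latent): exact under B, attenuated under C, inflated
under A (`compensating_estimate`, and `run_identity_experiment` verifies
the fitted loading equals this closed form at population moments). The
`assignment_rules` function encodes which indicator-to-latent assignments
are causally coherent at all — e.g. y6 can never indicate η_C, because the
disturbances entering at η_C do not cause y6; using y5 and y6 as two single
indicators permits only (C for y5, B for y6).

Percent-of-variance elicitation (`elicit_error_variance`) converts the
analyst's judgments — each error source's share of the indicator's
variance, in percent — into the fixed value: observed variance × (sum of
percents)/100. Percents are additive because error sources are modeled as
independent; a sum above 100 is rejected. `FIXED_PCT` grammar declarations
store the percent symbolically and resolve it against diag(S) at fit time.

## Numerical choices

- **Parameterization**: one unconstrained vector over the distinct free
  parameters. Equality constraints are implemented by pooling (all cells
  sharing a label are literally one parameter), which is exact and is what
  the method-latent recipe (equal effects of a method latent on all
  affected indicators) requires.
- **Starting values**: explicit `START` values where declared; otherwise
  loadings 1, effects and covariances 0, latent variances half the scaling
  indicator's observed variance, error variances half the indicator's
  observed variance.
- **Optimizer**: BFGS with the analytic gradient
  dF/dθ = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)·∂Σ/∂θ]. Steps where Σ leaves the positive
  definite cone (Cholesky failure) or (I−B) is singular return a large
  barrier value, so the line search backtracks instead of ridging Σ.
  Convergence: gradient max-norm ≤ 1e-6 (and F is reported with the exact
  gradient norm attained); on failure up to 5 jittered restarts with seeds
  derived from a recorded restart seed. Non-convergence is flagged and the
  best point returned, never hidden. The identity experiment tightens the
  gradient tolerance to 1e-9 for its own fits because its results are
  compared against exact closed forms.
- **Variances are not bounded**: a negative variance estimate (Heywood
  case) is a diagnostic signal and is flagged, not clipped.
- **Standard errors**: expected information,
  Var(θ̂) = (2/c)·E⁻¹ with E_ij = tr(Σ⁻¹ ∂Σ_i Σ⁻¹ ∂Σ_j); an observed
  (finite-difference) information option exists. Singular information
  suppresses SEs with a flag.
- **Nesting check** for χ²-difference tests: cell-wise (restricted free ⊆
  unrestricted free, shared fixed values equal) on Λ and Θ, plus a special
  rule for the latent block: a saturated unrestricted block (B ≡ 0, Ψ all
  free) nests any restricted latent structure with no more free
  latent-level parameters, since the saturated block spans every latent
  covariance matrix. This is exactly the structured-vs-saturated comparison
  (df 20 vs 14, Δdf = 6) that motivates the check; a pure cell-wise rule
  would wrongly reject it because the restricted model frees B cells fixed
  at zero in the saturated one.

## Diagnostics

The modification index is the classic score (Lagrange-multiplier)
statistic: with g the gradient of F in the candidate's direction at the
constrained optimum and v the candidate's expected information after
partialling out the free parameters, MI = c·g²/(2v) ~ χ²(1) and
EPC = −g/v. MI approximates the χ² drop from actually freeing the cell
*locally*: the agreement degrades roughly in proportion to the misfit
fraction (verifiable in the scalar case in closed form), so the refit mode
(`refit=True`), which computes the exact Δχ², doubles as the oracle in the
test suite; the fixtures place the misspecification at a moderate size
(χ² ≈ 130 at N = 10,000, MI/Δχ² ≈ 1.07) where the score form is in its
regime of validity. EPC is raw (in the parameter's own units);
standardized EPC is future work.

Underidentified-if-freed detection is a numerical rank test: the candidate
cell's implied-moment derivative is regressed on the span of the free
parameters' derivatives at θ̂; a relative residual below 1e-7 means freeing
the cell adds no new direction to the moment map, so the parameter is
un-estimable, cannot contribute misfit, and its MI is reported as 0 with an
explicit "uninformative" flag — the honest reading is *this assertion is
untestable here*, not *this assertion is right*. Error-covariance
candidates carry a caution note (freed error covariances tend to become
fudge-factors); nothing is ever auto-freed.

## Sensitivity

`half_and_double` refits with each asserted error variance at half and at
double its value, one target at a time, and reports the monitored
estimates (by default those directly connected to the latent the target
scales) plus each variant's χ². No threshold declares a change
"substantial" — the numbers are reported and judgment stays with the
analyst. On the two-indicator chain block the monitored loading follows
Cov(y5,y6)/(Var(y5) − fixed value) exactly, hence is strictly increasing
in the asserted error variance; this closed form anchors the tests.
Halving/doubling a value fixed at zero is refused: a zero error variance
is itself the assertion to reconsider.

## Synthetic data

The generator is the normal generative counterpart of the model
(ζ ~ N(0,Ψ), ε ~ N(0,Θ), independent; PSD enforced by eigendecomposition
so rank-deficient Θ is allowed). Seeds are mandatory; there is no hidden
RNG state. Default study conditions: the chain world uses
Var(η_A) = 1, disturbance variances 0.5 (at B), 0.5 (at C), 0.2 (at y5),
0.5 (at y6), and λ6 = 0.8, giving the worked moments
Var(η_B) = 1.5, Var(η_C) = 2.0, Var(y5) = 2.2, Cov(y5,y6) = 1.2; the
Monte-Carlo calibration study uses 200 replications of n = 500 from the
structured four-latent/eight-indicator model, sizes at which a single
replication fits in tens of milliseconds and the χ² rejection rate at
α = 0.05 can be bracketed meaningfully ([0.02, 0.09] with 200 draws).

What the generator does *not* emulate: non-normal indicators, heterogeneous
cases, nonlinearity, missing data, and mean structure. Passing tests
therefore certify the covariance algebra, the estimator, and the
diagnostics under the model's own assumptions — not robustness of real-data
conclusions to violations of those assumptions.

## Known limitations

- Raw-data (FIML) estimation, robust corrections, multi-group models,
  ordinal indicators, and fit indices other than χ² are out of scope (the
  toolkit's testing philosophy is the χ² test, not indexing).
- The loop-simplex fixture is a structural skeleton (parse, audit,
  identification); no numerical replication of published estimates is
  attempted because the source models' data are not available.
- The symbolic path tracing is specialized to the three-stage chain;
  general models go through the numeric implied-covariance machinery.
- When the latent level demands one identity and an indicator pair demands
  another, the toolkit exposes the conflict as fit degradation and
  diagnostics; no closed form for the resulting compromise estimates is
  provided.
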