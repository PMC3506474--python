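# singlesem

A small maximum-likelihood structural equation modeling (SEM) toolkit built
around the *single/best-indicator* specification discipline used in
path-oriented epidemiological and behavioral modeling: each latent variable
η is given a scale by fixing the loading of its best indicator at 1.0, and
that indicator's measurement error variance is **asserted** (fixed by the
analyst) rather than estimated. The asserted error variance is a theory
claim — it selects *which* variable along a causal chain the latent denotes
— and the toolkit provides the machinery to state, fit, test, diagnose, and
stress that claim.

## What it computes

For a model in LISREL-style matrices (Λ loadings, B latent effects — self
loops allowed, Ψ latent disturbance (co)variances, Θ measurement error
(co)variances), the implied covariance matrix is

    Σ(θ) = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ

and estimation minimizes the normal-theory ML discrepancy

    F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

with χ² = (N−1)·F_ML referred to χ²(df), df = p(p+1)/2 minus the number of
distinct free parameters (equality-constrained cells pool into one).

The toolkit covers:

- **Model grammar** (`parse_model`): plain-text declarations of latents,
  indicators, fixed/free/equality-labeled cells, including `FIXED_PCT`
  error variances resolved against the observed variance at fit time.
- **df auditing** (`count_df`) and **empirical identification screening**
  (zero-variance or redundant indicators, disconnected variables, Jacobian
  rank at starting values).
- **ML fitting** (`fit_ml`) with analytic gradients, expected-information
  standard errors, Heywood-case flags, and **χ²-difference tests** for
  nested models (`chisq_difference`).
- **Diagnostics** (`modification_indices`): score-form modification index
  (MI) and expected parameter change (EPC) for fixed cells, with explicit
  detection of parameters that are *underidentified if freed* — a wrong
  fixed error variance in that situation produces **zero** MI, an honestly
  uninformative diagnostic the report flags.
- **Sensitivity** (`half_and_double`, `elicit_error_variance`,
  `variance_perturbation_demo`): the half-and-double procedure refits with
  each asserted error variance halved and doubled and reports how the
  monitored estimates move.
- **Simulation** (`simulate_data`, `run_identity_experiment`,
  `assignment_rules`): a generative three-stage causal chain
  η_A → η_B → η_C → y5 (with η_B → y6) demonstrating *latent identity
  selection*: fixing y5's error variance at the sum of the disturbance
  variances downstream of a chosen latent selects that latent, and a wrong
  choice is absorbed as a compensating (biased) estimate of the y6 loading,
  Cov(y5,y6)/Var(chosen latent).

## Worked example

```python
import singlesem as ss

world = ss.ChainWorld()          # Var(eta_A)=1, disturbances 0.5/0.5/0.2,
                                 # y6 loading 0.8, y6 error variance 0.5
for identity in "ABC":
    exp = ss.IdentityExperiment(world=world, chosen_identity=identity,
                                design="multiple")
    res = ss.run_identity_experiment(exp, allow_invalid=True)
    print(identity, round(res.lambda6_hat, 4), round(res.bias, 4))
```

prints

```
A 1.2 0.4
B 0.8 0.0
C 0.6 -0.2
```

Choosing the true common cause (identity B, accumulated error
0.2 + 0.5 = 0.7) recovers the generating loading 0.8 exactly. Choosing the
downstream latent C (accumulated error 0.2, latent variance 2.0) attenuates
the estimate to 1.2/2.0 = 0.6; the upstream latent A (accumulated error
1.2, latent variance 1.0) inflates it to 1.2/1.0 = 1.2 — yet all three
models fit the two-indicator covariances perfectly, which is why the
assertion must be defended by theory and probed by sensitivity analysis,
not left to fit statistics.

The same workflow is available from the shell:

```sh
singlesem identity-experiment --identity C --mode population --allow-invalid
# identity=C design=multiple mode=population lambda6_hat=0.6 bias=-0.2 chisq=4.885e-10 df=0
singlesem elicit --variance 4.0 --percents 5,5
# 0.4
```

Other subcommands: `dfcount`, `fit`, `diagnose`, `sensitivity half-double`,
`simulate chain`, `fixtures export`. Exit codes: 0 success, 2 input error,
3 non-convergence, 4 invalid indicator-to-latent assignment.

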