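"""Maximum-likelihood fitting of a covariance-structure model.

The discrepancy is the normal-theory ML fit function

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

minimized over the distinct free parameters (equality groups pooled into one
parameter each).  The model test statistic is ``chisq = (N - 1) * F_ML`` by
default (the LISREL convention; ``multiplier="n"`` selects N), referred to a
chi-square with ``df`` from the moment/parameter audit.  Standard errors come
from the expected information matrix at the optimum.

Free variances are not bounded away from zero: a converged solution with a
negative variance estimate (a Heywood case) is reported with a flag, never
silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .algebra import SingularModelError, implied_covariance_derivs
from .model import DfAudit, ModelError, SemModel, count_df

__all__ = [
    "SampleMoments",
    "FitResult",
    "FitOptions",
    "fit_ml",
    "chisq_difference",
    "ChisqDifference",
    "NestingError",
]

_BIG = 1e12  # barrier value returned when Sigma(theta) leaves the PD cone


# ---------------------------------------------------------------------------
# Sample moments
# ---------------------------------------------------------------------------


@dataclass
class SampleMoments:
    """A sample covariance matrix with its sample size."""

    S: np.ndarray
    N: int
    variable_names: list

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = len(self.variable_names)
        if self.S.shape != (p, p):
            raise ModelError(
                f"covariance matrix is {self.S.shape} but there are {p} variable names"
            )
        if np.abs(self.S - self.S.T).max() > 1e-8:
            raise ModelError("sample covariance matrix is not symmetric (tolerance 1e-8)")
        self.S = (self.S + self.S.T) / 2.0
        if np.any(np.diag(self.S) < 0):
            raise ModelError("negative variance on the covariance matrix diagonal")
        if self.N < 1:
            raise ModelError("sample size must be positive")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    def aligned_to(self, model: SemModel) -> "SampleMoments":
        """Reorder variables to the model's indicator order (names must match)."""
        if self.variable_names == model.indicator_names:
            return self
        if set(self.variable_names) != set(model.indicator_names):
            raise ModelError(
                "covariance variable names do not match the model's indicators: "
                f"{self.variable_names} vs {model.indicator_names}"
            )
        idx = [self.variable_names.index(n) for n in model.indicator_names]
        return SampleMoments(self.S[np.ix_(idx, idx)], self.N, list(model.indicator_names))


# ---------------------------------------------------------------------------
# Fit options and result
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    chisq_multiplier: str = "n-1"  # or "n"
    gtol: float = 1e-6
    ftol: float = 1e-10
    max_iterations: int = 500
    max_restarts: int = 5
    restart_seed: int = 0
    jitter_scale: float = 0.1
    observed_information: bool = False  # SEs from observed instead of expected info
    allow_unidentified: bool = False  # skip the df >= 0 gate


@dataclass
class FitResult:
    theta_hat: np.ndarray
    param_names: list
    F_ML: float
    chisq: float
    df: int
    p_value: float
    se: Optional[np.ndarray]
    converged: bool
    n_iterations: int
    audit: DfAudit
    model: SemModel  # with FIXED_PCT cells resolved
    moments: SampleMoments
    multiplier: float
    gradient_norm: float
    restarts_used: int = 0
    restart_seeds: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def estimate(self, name: str) -> float:
        return float(self.theta_hat[self.param_names.index(name)])

    def estimates(self) -> dict:
        return {n: float(v) for n, v in zip(self.param_names, self.theta_hat)}

    @property
    def heywood(self) -> bool:
        return any(f.startswith("heywood") for f in self.flags)


# ---------------------------------------------------------------------------
# Fit function and gradient
# ---------------------------------------------------------------------------


def _ml_pieces(S: np.ndarray, logdet_S: float, Sigma: np.ndarray):
    """(F, Sigma^-1, W) with W = Sigma^-1 - Sigma^-1 S Sigma^-1, or None if non-PD."""
    p = S.shape[0]
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Sigma_inv = np.linalg.inv(Sigma)
    F = logdet + np.trace(S @ Sigma_inv) - logdet_S - p
    W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    return F, Sigma_inv, W


def _objective_factory(model: SemModel, S: np.ndarray):
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ModelError("sample covariance matrix is not positive definite")

    def fun_and_grad(theta):
        try:
            Sigma, derivs, _ = implied_covariance_derivs(model, theta)
        except SingularModelError:
            return _BIG, np.zeros_like(theta)
        pieces = _ml_pieces(S, logdet_S, Sigma)
        if pieces is None:
            return _BIG, np.zeros_like(theta)
        F, _, W = pieces
        grad = np.array([np.sum(W * d) for d in derivs])
        return F, grad

    return fun_and_grad, logdet_S


def _default_starts(model: SemModel, S: np.ndarray) -> np.ndarray:
    """Starting values: explicit starts where given, otherwise the policy
    (loadings 1, effects/covariances 0, variances half the relevant observed
    variance)."""
    mean_var = float(np.mean(np.diag(S))) if S.size else 1.0
    # scaling indicator of each latent: first fixed nonzero loading
    scaling = {}
    for j in range(model.m):
        for i in range(model.p):
            c = model.Lambda[i, j]
            if c.status == "fixed" and c.value not in (None, 0.0):
                scaling[j] = i
                break
    starts = []
    for fp in model.free_parameters():
        if fp.start is not None:
            starts.append(fp.start)
            continue
        matrix, i, j = fp.cells[0]
        if matrix == "Lambda":
            starts.append(1.0)
        elif matrix == "B":
            starts.append(0.0)
        elif matrix == "Psi":
            if i == j:
                k = scaling.get(i)
                starts.append(0.5 * float(S[k, k]) if k is not None else 0.5 * mean_var)
            else:
                starts.append(0.0)
        elif matrix == "Theta":
            starts.append(0.5 * float(S[i, i]) if i == j else 0.0)
    return np.array(starts, dtype=float)


def fit_ml(model: SemModel, moments: SampleMoments, options: Optional[FitOptions] = None) -> FitResult:
    """Fit a model to sample moments by minimizing the ML discrepancy.

    FIXED_PCT error variances are resolved against ``diag(S)`` before
    fitting.  The optimizer is quasi-Newton (BFGS) on the unconstrained free
    vector with an analytic gradient; steps producing a non-positive-definite
    implied covariance are rejected by a barrier value.  Non-convergence
    triggers up to ``max_restarts`` jittered restarts with recorded seeds,
    and is reported in ``converged`` / ``flags`` — the best point found is
    always returned.
    """
    opts = options or FitOptions()
    moments = moments.aligned_to(model)
    S = moments.S
    resolved = model.resolve_fixed_pct(S)
    resolved.validate(strict=False)
    audit = count_df(resolved)
    if audit.df < 0 and not opts.allow_unidentified:
        raise ModelError(
            f"model is under-determined (df={audit.df}); "
            "set allow_unidentified to fit anyway"
        )
    params = resolved.free_parameters()
    names = [fp.name for fp in params]
    fun_and_grad, _ = _objective_factory(resolved, S)

    theta0 = _default_starts(resolved, S)
    rng = np.random.default_rng(opts.restart_seed)
    flags: list[str] = []
    best = None
    restart_seeds: list[int] = []
    n_attempts = 0
    converged = False
    total_iters = 0

    for attempt in range(opts.max_restarts + 1):
        if attempt == 0:
            start = theta0
        else:
            seed = int(rng.integers(2**31 - 1))
            restart_seeds.append(seed)
            jrng = np.random.default_rng(seed)
            scale = opts.jitter_scale * np.maximum(np.abs(theta0), 1.0)
            start = theta0 + jrng.normal(0.0, scale)
        n_attempts = attempt + 1
        if len(params) == 0:
            best = (0.0, np.zeros(0), 0, True)
            converged = True
            break
        res = optimize.minimize(
            fun_and_grad,
            start,
            jac=True,
            method="BFGS",
            options={"gtol": opts.gtol, "maxiter": opts.max_iterations},
        )
        total_iters += int(res.nit)
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        ok = bool(res.success) or gnorm <= opts.gtol
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x, dtype=float), gnorm, ok)
        if ok and res.fun < _BIG / 2:
            converged = True
            best = (float(res.fun), np.asarray(res.x, dtype=float), gnorm, True)
            break

    F, theta_hat, gnorm, _ = best
    if not converged:
        flags.append("non-convergence: best point returned; try other starting values")
    F = max(F, 0.0) if F > -1e-10 else F
    if F < 0:
        flags.append(f"negative discrepancy {F:.3e} (numerical)")
        F = 0.0

    # Heywood screening: negative free variance estimates
    for fp, val in zip(params, theta_hat):
        matrix, i, j = fp.cells[0]
        if matrix in ("Psi", "Theta") and i == j and val < 0:
            flags.append(f"heywood: {fp.name} = {val:.6g} < 0")

    mult = float(moments.N - 1) if opts.chisq_multiplier == "n-1" else float(moments.N)
    chisq = mult * F
    if audit.df > 0:
        p_value = float(stats.chi2.sf(chisq, audit.df))
    else:
        p_value = 1.0  # saturated model: exact fit, no test

    # standard errors
    se = None
    if len(params) > 0:
        try:
            Sigma, derivs, _ = implied_covariance_derivs(resolved, theta_hat)
            Sigma_inv = np.linalg.inv(Sigma)
            if opts.observed_information:
                # H is the observed Hessian of F; Var(theta) = (2/mult) H^-1
                H = _observed_hessian(fun_and_grad, theta_hat)
                acov = (2.0 / mult) * np.linalg.inv(H)
            else:
                k = len(params)
                E = np.empty((k, k))
                SiD = [Sigma_inv @ d for d in derivs]
                for a in range(k):
                    for b in range(a + 1):
                        E[a, b] = E[b, a] = np.sum(SiD[a] * SiD[b].T)
                acov = (2.0 / mult) * np.linalg.inv(E)
            dvar = np.diag(acov)
            if np.any(dvar <= 0):
                raise np.linalg.LinAlgError
            se = np.sqrt(dvar)
        except (np.linalg.LinAlgError, SingularModelError):
            flags.append("standard errors suppressed: information matrix singular")
            se = None

    return FitResult(
        theta_hat=theta_hat,
        param_names=names,
        F_ML=float(F),
        chisq=float(chisq),
        df=int(audit.df),
        p_value=p_value,
        se=se,
        converged=converged,
        n_iterations=total_iters,
        audit=audit,
        model=resolved,
        moments=moments,
        multiplier=mult,
        gradient_norm=float(gnorm),
        restarts_used=n_attempts - 1,
        restart_seeds=restart_seeds,
        flags=flags,
    )


def _observed_hessian(fun_and_grad, theta, eps: float = 1e-5):
    """Central-difference Hessian of F from the analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for a in range(k):
        step = eps * max(1.0, abs(theta[a]))
        tp = theta.copy()
        tp[a] += step
        tm = theta.copy()
        tm[a] -= step
        _, gp = fun_and_grad(tp)
        _, gm = fun_and_grad(tm)
        H[a] = (gp - gm) / (2.0 * step)
    return (H + H.T) / 2.0


# ---------------------------------------------------------------------------
# Chi-square difference test
# ---------------------------------------------------------------------------


class NestingError(ModelError):
    """The two models are not nested, so the difference test is invalid."""


@dataclass
class ChisqDifference:
    delta_chisq: float
    delta_df: int
    p_value: float


def _latent_block_saturated(model: SemModel) -> bool:
    for i in range(model.m):
        for j in range(model.m):
            c = model.B[i, j]
            if c.is_free or c.value not in (None, 0.0):
                return False
    for i in range(model.m):
        for j in range(i + 1):
            if not model.Psi[i, j].is_free:
                return False
    return True


def _cellwise_nested(restricted, unrestricted, matrices, tol=1e-10):
    for name in matrices:
        Mr = getattr(restricted, name)
        Mu = getattr(unrestricted, name)
        for idx in np.ndindex(Mr.shape):
            cr, cu = Mr[idx], Mu[idx]
            if cr.is_free and not cu.is_free:
                return False, (
                    f"{restricted.cell_name(name, *idx)} is free in the restricted "
                    "model but fixed in the unrestricted model"
                )
            if not cr.is_free and not cu.is_free:
                vr = cr.value if cr.value is not None else None
                vu = cu.value if cu.value is not None else None
                if vr is None or vu is None:
                    continue  # unresolved FIXED_PCT cells compare after resolution
                if abs(vr - vu) > tol:
                    return False, (
                        f"{restricted.cell_name(name, *idx)} fixed at different values "
                        f"({vr} vs {vu})"
                    )
    return True, ""


def check_nested(restricted: SemModel, unrestricted: SemModel):
    """Structural nesting check.

    Cell-wise rule: every free cell of the restricted model is free in the
    unrestricted model and shared fixed cells carry the same values.  For the
    latent-level block a saturated unrestricted block (B all fixed zero, Psi
    all free) nests *any* restricted latent structure with no more free
    latent-level parameters, since a saturated block spans every latent
    covariance matrix.
    """
    if restricted.indicator_names != unrestricted.indicator_names:
        return False, "different indicator sets"
    ok, reason = _cellwise_nested(restricted, unrestricted, ("Lambda", "Theta"))
    if not ok:
        return False, reason
    if restricted.latent_names == unrestricted.latent_names and _latent_block_saturated(
        unrestricted
    ):
        n_lat_r = sum(
            1 for fp in restricted.free_parameters() if fp.matrix in ("B", "Psi")
        )
        n_lat_u = sum(
            1 for fp in unrestricted.free_parameters() if fp.matrix in ("B", "Psi")
        )
        if n_lat_r <= n_lat_u:
            return True, ""
        return False, "restricted model has more free latent-level parameters"
    ok, reason = _cellwise_nested(restricted, unrestricted, ("B", "Psi"))
    if not ok:
        return False, reason
    return True, ""


def chisq_difference(fit_restricted: FitResult, fit_unrestricted: FitResult,
                     tol: float = 1e-6) -> ChisqDifference:
    """Chi-square difference test between two nested fits on the same moments."""
    mr, mu = fit_restricted.moments, fit_unrestricted.moments
    if mr.N != mu.N or mr.variable_names != mu.variable_names or not np.allclose(
        mr.S, mu.S, atol=1e-12, rtol=0.0
    ):
        raise NestingError("the two fits use different sample moments")
    ok, reason = check_nested(fit_restricted.model, fit_unrestricted.model)
    if not ok:
        raise NestingError(f"models are not nested: {reason}")
    delta_df = fit_restricted.df - fit_unrestricted.df
    if delta_df < 1:
        raise NestingError(
            "no degrees of freedom separate the models (identical free structure?)"
        )
    delta = fit_restricted.chisq - fit_unrestricted.chisq
    if delta < -tol * max(1.0, fit_unrestricted.chisq):
        raise NestingError(
            f"restricted chi-square is smaller than unrestricted ({delta:.3g}); "
            "this signals an optimizer failure in one of the fits"
        )
    delta = max(delta, 0.0)
    return ChisqDifference(float(delta), int(delta_df), float(stats.chi2.sf(delta, delta_df)))
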