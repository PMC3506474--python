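"""Closed-form covariance machinery.

Two layers live here.  The general layer computes the model-implied
covariance matrix

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta

and its derivatives with respect to the free parameters.  The special-purpose
layer is exact path-tracing algebra for a three-stage causal chain

    eta_A -> eta_B -> eta_C -> y5,   eta_B -> y6

with independent disturbances entering at every stage.  The chain is the
canonical setting for *latent identity selection*: a single indicator y5 can
stand for any of the three latents along the chain, and the choice is made
operationally by fixing y5's measurement error variance at the sum of the
disturbance variances entering downstream of the chosen latent.  Choosing the
wrong latent does not necessarily produce misfit — the loading of a second
indicator y6 can absorb the mistake as a compensating (biased) estimate,
which these closed forms quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ModelError, SemModel

__all__ = [
    "ImpliedCov",
    "ChainWorld",
    "implied_covariance",
    "implied_covariance_derivs",
    "implied_covariance_jacobian",
    "common_cause_cov",
    "chain_moments",
    "accumulated_error_variance",
    "compensating_estimate",
]


class SingularModelError(ModelError):
    """(I - B) is numerically singular at the requested parameter values."""


# ---------------------------------------------------------------------------
# Model-implied covariance matrix
# ---------------------------------------------------------------------------


@dataclass
class ImpliedCov:
    Sigma: np.ndarray
    theta_vector: np.ndarray


def _structural_pieces(model: SemModel, theta):
    Lam, B, Psi, Theta = model.materialize(theta)
    m = model.m
    IB = np.eye(m) - B
    # reject near-singular (I - B); loop models make this a live concern
    sign, logdet = np.linalg.slogdet(IB)
    if sign == 0 or logdet < -30:
        raise SingularModelError("(I - B) is singular at these parameter values")
    A = np.linalg.solve(IB, np.eye(m))
    return Lam, B, Psi, Theta, A


def implied_covariance(model: SemModel, theta=None) -> ImpliedCov:
    """Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta."""
    Lam, _, Psi, Theta, A = _structural_pieces(model, theta)
    G = Lam @ A
    Sigma = G @ Psi @ G.T + Theta
    Sigma = (Sigma + Sigma.T) / 2.0
    if theta is None:
        tv = np.array([fp.start for fp in model.free_parameters()], dtype=float)
    elif isinstance(theta, dict):
        tv = np.array([theta[fp.name] for fp in model.free_parameters()], dtype=float)
    else:
        tv = np.asarray(theta, dtype=float)
    return ImpliedCov(Sigma, tv)


def _cell_deriv(model, matrix, i, j, Lam, Psi, A, G, APGt):
    """dSigma for a unit change in one cell; symmetric cells move both entries."""
    p = model.p
    d = np.zeros((p, p))
    if matrix == "Lambda":
        # dSigma = sym(dLam . A Psi G^T); dLam = e_i e_j^T
        row = APGt[j, :]  # (A Psi G^T)[j, :]
        d[i, :] += row
        d[:, i] += row
    elif matrix == "B":
        # dA = A dB A;  dSigma = sym(G dB A Psi G^T) with dB = e_i e_j^T
        d = np.outer(G[:, i], APGt[j, :])
        d = d + d.T
    elif matrix == "Psi":
        if i == j:
            d = np.outer(G[:, i], G[:, i])
        else:
            d = np.outer(G[:, i], G[:, j])
            d = d + d.T
    elif matrix == "Theta":
        d[i, j] = 1.0
        d[j, i] = 1.0
    else:  # pragma: no cover
        raise ModelError(f"unknown matrix {matrix!r}")
    return d


def implied_covariance_derivs(model: SemModel, theta=None, extra_cells=None):
    """Sigma and the list of dSigma/dtheta_k matrices (pooled cells summed).

    ``extra_cells`` may list additional ``(matrix, i, j)`` cells (normally
    fixed ones); their derivative matrices are appended after the free ones.
    Used by the score-test diagnostics.
    """
    Lam, _, Psi, Theta, A = _structural_pieces(model, theta)
    G = Lam @ A
    APGt = A @ Psi @ G.T  # m x p
    Sigma = G @ Psi @ G.T + Theta
    Sigma = (Sigma + Sigma.T) / 2.0
    derivs = []
    for fp in model.free_parameters():
        d = np.zeros((model.p, model.p))
        for matrix, i, j in fp.cells:
            d = d + _cell_deriv(model, matrix, i, j, Lam, Psi, A, G, APGt)
        derivs.append(d)
    extra = []
    if extra_cells:
        for matrix, i, j in extra_cells:
            extra.append(_cell_deriv(model, matrix, i, j, Lam, Psi, A, G, APGt))
    return Sigma, derivs, extra


def implied_covariance_jacobian(model: SemModel, theta=None) -> np.ndarray:
    """Jacobian of vec(Sigma) with respect to the free parameters (p^2 x k)."""
    _, derivs, _ = implied_covariance_derivs(model, theta)
    if not derivs:
        return np.zeros((model.p * model.p, 0))
    return np.column_stack([d.ravel() for d in derivs])


# ---------------------------------------------------------------------------
# Common-cause path tracing
# ---------------------------------------------------------------------------


def common_cause_cov(effect_to_a: float, effect_to_b: float, var_common: float) -> float:
    """Covariance produced between two effects of one common cause.

    The covariance equals the product of the two causal effects and the
    variance of the common cause.
    """
    if var_common < 0:
        raise ValueError(f"variance of the common cause is negative ({var_common})")
    return float(effect_to_a) * float(effect_to_b) * float(var_common)


# ---------------------------------------------------------------------------
# The three-stage causal chain world
# ---------------------------------------------------------------------------


@dataclass
class ChainWorld:
    """Generative parameters of the eta_A -> eta_B -> eta_C -> y5 chain.

    The spine effects default to 1.0 (the canonical case); ``b_ab``, ``b_bc``
    and ``b_c5`` allow a non-unit spine for exploration.  ``lambda6`` is the
    direct effect of eta_B on the second indicator y6.  All error variances
    are disturbances entering at the named stage, mutually independent and
    independent of upstream variables.
    """

    var_eta3A: float = 1.0
    var_errorB: float = 0.5
    var_errorC: float = 0.5
    var_error5: float = 0.2
    var_error6: float = 0.5
    lambda6: float = 0.8
    b_ab: float = 1.0
    b_bc: float = 1.0
    b_c5: float = 1.0

    def __post_init__(self) -> None:
        for name in ("var_eta3A", "var_errorB", "var_errorC", "var_error5", "var_error6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")

    def replace(self, **kw) -> "ChainWorld":
        return replace(self, **kw)


IDENTITIES = ("A", "B", "C")


def chain_moments(world: ChainWorld) -> dict:
    """Exact population moments of the chain world by path tracing.

    With unit spine effects the variances accumulate down the chain:
    ``Var(eta_B) = Var(eta_A) + Var(errB)``, ``Var(eta_C) = Var(eta_B) +
    Var(errC)``, ``Var(y5) = Var(eta_C) + Var(err5)``, and the common cause
    eta_B gives ``Cov(y5, y6) = lambda6 * Var(eta_B)``.
    """
    w = world
    var_B = w.b_ab**2 * w.var_eta3A + w.var_errorB
    var_C = w.b_bc**2 * var_B + w.var_errorC
    var_y5 = w.b_c5**2 * var_C + w.var_error5
    var_y6 = w.lambda6**2 * var_B + w.var_error6
    cov_56 = common_cause_cov(w.b_bc * w.b_c5, w.lambda6, var_B)
    return {
        "var_eta3A": w.var_eta3A,
        "var_eta3B": var_B,
        "var_eta3C": var_C,
        "var_y5": var_y5,
        "var_y6": var_y6,
        "cov_y5_y6": cov_56,
    }


def _effect_to_y5(world: ChainWorld, identity: str) -> float:
    if identity == "C":
        return world.b_c5
    if identity == "B":
        return world.b_c5 * world.b_bc
    if identity == "A":
        return world.b_c5 * world.b_bc * world.b_ab
    raise ValueError(f"unknown identity {identity!r}; expected one of {IDENTITIES}")


def latent_variance(world: ChainWorld, identity: str) -> float:
    mom = chain_moments(world)
    key = {"A": "var_eta3A", "B": "var_eta3B", "C": "var_eta3C"}.get(identity)
    if key is None:
        raise ValueError(f"unknown identity {identity!r}; expected one of {IDENTITIES}")
    return mom[key]


def accumulated_error_variance(world: ChainWorld, identity: str) -> float:
    """Measurement error variance on y5 when the latent is the chosen identity.

    All disturbances entering the chain between the chosen latent and y5 are
    accumulated into y5's error: ``C -> err5``, ``B -> err5 + errC``,
    ``A -> err5 + errC + errB`` (unit spine; the general form subtracts the
    true-score contribution of the chosen latent from Var(y5)).
    """
    mom = chain_moments(world)
    eff = _effect_to_y5(world, identity)
    return mom["var_y5"] - eff**2 * latent_variance(world, identity)


def compensating_estimate(world: ChainWorld, identity: str) -> float:
    """The y6 loading that exactly matches Cov(y5, y6) under an identity choice.

    Fixing y5's error variance for a given identity fixes the modeled latent
    variance at ``Var(y5) - fixed error``.  The loading to y6 that reproduces
    the observed y5-y6 covariance is then ``Cov(y5, y6) / latent variance``:
    equal to the generating ``lambda6`` for identity B (the true common
    cause), attenuated for C (too much latent variance), inflated for A (too
    little).
    """
    v = latent_variance(world, identity)
    if v <= 0:
        raise ValueError(f"latent variance for identity {identity} is not positive")
    mom = chain_moments(world)
    eff = _effect_to_y5(world, identity)
    # loading expressed in y5's units: latent-as-modeled = eff * latent
    return mom["cov_y5_y6"] / (eff * v)
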