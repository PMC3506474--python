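"""Synthetic data generation and latent-identity selection experiments.

Data are drawn from the normal-theory generative counterpart of a model:
latent disturbances ``zeta ~ N(0, Psi)`` and measurement errors
``eps ~ N(0, Theta)`` are independent, latents propagate through
``eta = (I - B)^-1 zeta`` and indicators through ``y = Lambda eta + eps``.
Seeds are mandatory for Monte-Carlo draws — there is no hidden global RNG.

The identity experiment reproduces the compensating-estimate phenomenon on
the three-stage causal chain: y5 scales a latent whose identity (A, B, or C
along the chain) is selected by the fixed error variance accumulated onto
y5, a second indicator y6 gets a free loading, and the fitted loading shows
the bias the closed-form algebra predicts — unbiased when the modeled latent
is the true common cause (B), attenuated for C, inflated for A.

:func:`assignment_rules` encodes which indicator-to-latent assignments the
chain's causal structure can justify at all; deliberately invalid
assignments are permitted only behind an explicit ``allow_invalid`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .algebra import (
    ChainWorld,
    IDENTITIES,
    accumulated_error_variance,
    chain_moments,
    implied_covariance,
)
from .estimate import FitOptions, FitResult, SampleMoments, fit_ml
from .model import ModelError, ParamCell, SemModel

__all__ = [
    "simulate_data",
    "population_moments",
    "assignment_rules",
    "RuleVerdict",
    "IdentityExperiment",
    "run_identity_experiment",
    "IdentityResult",
    "chain_identity_model",
    "chain_world_embedding",
    "chain_world_moments",
    "InvalidAssignmentError",
]


# ---------------------------------------------------------------------------
# Data generation
# ---------------------------------------------------------------------------


def _psd_factor(M: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    """A factor L with L L^T = M for PSD M (eigendecomposition; allows rank
    deficiency, e.g. Theta = 0)."""
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ModelError(f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_data(
    model: SemModel,
    theta=None,
    n: int = 0,
    seed: Optional[int] = None,
    return_moments: bool = False,
):
    """Draw ``n`` cases of indicator data from the model at parameters ``theta``.

    Returns an ``(n, p)`` array, or a :class:`SampleMoments` of the sample
    covariances when ``return_moments`` is true.  ``seed`` is required.
    """
    if n <= 0:
        raise ValueError("number of cases must be positive")
    if seed is None:
        raise ValueError("a seed is required for simulation (no hidden RNG state)")
    Lam, B, Psi, Theta, = model.materialize(theta)
    m = model.m
    IB = np.eye(m) - B
    if abs(np.linalg.det(IB)) < 1e-12:
        raise ModelError("(I - B) is singular at these parameter values")
    Lpsi = _psd_factor(Psi, "Psi")
    Lth = _psd_factor(Theta, "Theta")
    rng = np.random.default_rng(seed)
    zeta = rng.standard_normal((n, m)) @ Lpsi.T
    eps = rng.standard_normal((n, model.p)) @ Lth.T
    eta = np.linalg.solve(IB, zeta.T).T
    y = eta @ Lam.T + eps
    if return_moments:
        if n < 2:
            raise ValueError("need at least two cases for a sample covariance")
        S = np.cov(y, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        return SampleMoments(S, n, list(model.indicator_names))
    return y


def population_moments(model: SemModel, theta=None, N: int = 100000) -> SampleMoments:
    """Exact Sigma(theta) packaged as sample moments with nominal size ``N``."""
    Sigma = implied_covariance(model, theta).Sigma
    return SampleMoments(Sigma, N, list(model.indicator_names))


# ---------------------------------------------------------------------------
# Indicator-to-latent assignment rules
# ---------------------------------------------------------------------------

DESIGNS = ("y5_single", "y6_single", "both_single", "multiple")


@dataclass
class RuleVerdict:
    valid: bool
    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid


class InvalidAssignmentError(ModelError):
    """An indicator-to-latent assignment the chain's causal structure forbids."""


def assignment_rules(design: str, chosen_identity) -> RuleVerdict:
    """Which latent identities can the y5/y6 indicators justifiably measure?

    The chain's causal structure fixes the answers: disturbances entering
    between a latent and its indicator must dead-end as that indicator's
    measurement error, and the same disturbance cannot simultaneously be
    sequestered as measurement error for one indicator and produce true-score
    variance for another modeled latent.

    * ``y5_single`` (y5 the only indicator): identity A, B, or C — all valid.
    * ``y6_single``: A or B; never C, because the error-C disturbances do not
      cause y6 at all.
    * ``both_single`` (two single-indicator latents, identity given as the
      pair ``(id_for_y5, id_for_y6)``): only (C, B) is valid.  Any pair
      involving A fails because the error-B (and error-C) disturbances would
      have to dead-end as measurement error on one indicator while causing
      true variance in the other's latent; equal identities describe a
      multiple-indicator design, not two single indicators.
    * ``multiple`` (y5 and y6 as two indicators of one latent): only B, the
      common cause of both.
    """
    if design not in DESIGNS:
        return RuleVerdict(False, f"unknown design {design!r}; expected one of {DESIGNS}")

    def check_id(x) -> Optional[str]:
        return None if x in IDENTITIES else f"unknown identity {x!r}"

    if design == "both_single":
        if not (isinstance(chosen_identity, (tuple, list)) and len(chosen_identity) == 2):
            return RuleVerdict(False, "both_single needs an identity pair (id_y5, id_y6)")
        id5, id6 = chosen_identity
        for x in (id5, id6):
            msg = check_id(x)
            if msg:
                return RuleVerdict(False, msg)
        if id6 == "C":
            return RuleVerdict(
                False,
                "y6 can never indicate C: the error-C disturbances do not cause y6, "
                "so there is no error accumulation that makes y6 reflect latent C",
            )
        if id5 == id6:
            return RuleVerdict(
                False,
                "same identity for both single indicators describes a multiple-indicator "
                "design; use design='multiple'",
            )
        if "A" in (id5, id6):
            return RuleVerdict(
                False,
                "a pair involving A is contradictory: the error-B disturbances would be "
                "sequestered as measurement error for the A-indicated latent while "
                "simultaneously causing true-score variance in the other latent",
            )
        # remaining distinct non-A pairs with id6 != C: (C, B) only
        return RuleVerdict(True, "y5 indicates C and y6 indicates B: both latents modelable")

    if not isinstance(chosen_identity, str):
        return RuleVerdict(False, f"{design} needs a single identity, got {chosen_identity!r}")
    msg = check_id(chosen_identity)
    if msg:
        return RuleVerdict(False, msg)
    if design == "y5_single":
        return RuleVerdict(True, "y5 alone can indicate A, B, or C with the matching error accumulation")
    if design == "y6_single":
        if chosen_identity == "C":
            return RuleVerdict(
                False,
                "y6 can never indicate C: y6 correlates with C only through the common "
                "cause B; the error-C disturbances do not cause y6",
            )
        return RuleVerdict(True, "y6 alone can indicate A or B with the matching error accumulation")
    # multiple
    if chosen_identity == "B":
        return RuleVerdict(True, "B is the common cause of y5 and y6")
    return RuleVerdict(
        False,
        f"with y5 and y6 as multiple indicators of one latent only the common cause B "
        f"is modelable, not {chosen_identity}",
    )


# ---------------------------------------------------------------------------
# Chain world as a fittable model
# ---------------------------------------------------------------------------


def chain_identity_model(world: ChainWorld, identity: str) -> SemModel:
    """The two-indicator model an analyst fits after choosing an identity.

    One latent scaled by y5 (loading fixed 1.0, error variance fixed at the
    identity's accumulated value); y6 gets a free loading and free error
    variance; the latent variance is free.
    """
    err5 = accumulated_error_variance(world, identity)
    model = SemModel([f"eta3{identity}"], ["y5", "y6"])
    lat = model.latent_names[0]
    model.set_loading("y5", lat, ParamCell("fixed", 1.0))
    model.set_loading("y6", lat, ParamCell("free", 1.0))
    model.set_psi(lat, lat, ParamCell("free", None))
    model.set_theta("y5", "y5", ParamCell("fixed", err5))
    model.set_theta("y6", "y6", ParamCell("free", None))
    model.validate(strict=False)
    return model


def chain_world_embedding(world: ChainWorld) -> SemModel:
    """The full chain as a SemModel with every parameter fixed at truth.

    Three latents A -> B -> C plus the two indicators; used to cross-check
    the path-tracing closed forms against the general implied-covariance
    machinery (the model has no free parameters).
    """
    w = world
    model = SemModel(["eta3A", "eta3B", "eta3C"], ["y5", "y6"])
    model.set_effect("eta3A", "eta3B", ParamCell("fixed", w.b_ab))
    model.set_effect("eta3B", "eta3C", ParamCell("fixed", w.b_bc))
    model.set_loading("y5", "eta3C", ParamCell("fixed", w.b_c5))
    model.set_loading("y6", "eta3B", ParamCell("fixed", w.lambda6))
    model.set_psi("eta3A", "eta3A", ParamCell("fixed", w.var_eta3A))
    model.set_psi("eta3B", "eta3B", ParamCell("fixed", w.var_errorB))
    model.set_psi("eta3C", "eta3C", ParamCell("fixed", w.var_errorC))
    model.set_theta("y5", "y5", ParamCell("fixed", w.var_error5))
    model.set_theta("y6", "y6", ParamCell("fixed", w.var_error6))
    model.validate(strict=False)
    return model


def chain_world_moments(world: ChainWorld, N: int = 100000) -> SampleMoments:
    """Population covariance matrix of (y5, y6) from the chain's closed forms."""
    mom = chain_moments(world)
    S = np.array(
        [
            [mom["var_y5"], mom["cov_y5_y6"]],
            [mom["cov_y5_y6"], mom["var_y6"]],
        ]
    )
    return SampleMoments(S, N, ["y5", "y6"])


# ---------------------------------------------------------------------------
# Identity experiment
# ---------------------------------------------------------------------------


@dataclass
class IdentityExperiment:
    world: ChainWorld
    chosen_identity: Union[str, tuple] = "B"
    design: str = "multiple"
    mode: str = "population"  # or "monte_carlo"
    n: int = 2000
    seed: Optional[int] = None
    population_N: int = 100000


@dataclass
class IdentityResult:
    lambda6_hat: float
    bias: float
    chisq: float
    df: int
    fit: FitResult
    verdict: RuleVerdict


def run_identity_experiment(
    exp: IdentityExperiment,
    allow_invalid: bool = False,
    options: Optional[FitOptions] = None,
) -> IdentityResult:
    """Fit the chosen-identity model to chain-world moments and measure bias.

    ``bias = lambda6_hat - world.lambda6`` where ``world.lambda6`` is the
    generating direct effect of the true common cause on y6.  Identity
    assignments that the chain's causal structure forbids are refused unless
    ``allow_invalid`` marks the run as a deliberate misspecification demo.
    """
    verdict = assignment_rules(exp.design, exp.chosen_identity)
    if not verdict.valid and not allow_invalid:
        raise InvalidAssignmentError(
            f"{exp.design} with identity {exp.chosen_identity}: {verdict.reason} "
            "(pass allow_invalid=True for a deliberate misspecification demo)"
        )
    if not isinstance(exp.chosen_identity, str):
        raise ModelError(
            "the identity experiment fits the two-indicator common-cause design and "
            "needs a single identity (A, B, or C); the both_single pair has no "
            "compensating loading to estimate"
        )
    model = chain_identity_model(exp.world, exp.chosen_identity)
    if exp.mode == "population":
        moments = chain_world_moments(exp.world, N=exp.population_N)
    elif exp.mode == "monte_carlo":
        truth = chain_world_embedding(exp.world)
        moments = simulate_data(truth, None, n=exp.n, seed=exp.seed, return_moments=True)
    else:
        raise ValueError(f"unknown mode {exp.mode!r}")
    # tight default termination: population-mode results are compared against
    # exact closed forms
    fit = fit_ml(model, moments, options or FitOptions(gtol=1e-9))
    lam_name = f"load:y6~{model.latent_names[0]}"
    lam_hat = fit.estimate(lam_name)
    return IdentityResult(
        lambda6_hat=float(lam_hat),
        bias=float(lam_hat - exp.world.lambda6),
        chisq=fit.chisq,
        df=fit.df,
        fit=fit,
        verdict=verdict,
    )
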