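"""Reference model structures, generated programmatically.

Four catalog entries cover the structures every other module is exercised
against:

* ``saturated_pairs`` — four latents with two indicators each and a fully
  saturated latent block (all 10 latent (co)variances free, no latent
  effects): 4 free loadings + 10 Psi entries + 8 free error variances = 22
  estimates against 36 moments, df = 14.
* ``structured_pairs`` — the same measurement skeleton with the saturated
  block replaced by a recursive causal structure (eta1 -> eta3, eta2 -> eta3,
  eta3 -> eta4, exogenous covariance eta1 ~~ eta2; two fewer free
  latent-level parameters) and a fixed measurement error variance on each
  scaling indicator (four fewer free Theta entries): df = 20.  The concrete
  effect placement is one instance of the "two fewer latent parameters"
  count, which is the tested contract.
* ``chain_world`` — the default three-stage causal chain world.
* ``loop_simplex`` — ten single indicators of ten successive latent states,
  unit persistence effects down the chain, a free self-causative loop and
  free disturbance at each occasion after the first, and each indicator's
  error variance asserted symbolically as 3% of its observed variance
  (``FIXED_PCT 3``).

``structured_pairs`` carries a generating parameterization (``*_truth``)
used for population-moment oracles; ``saturated_pairs_truth`` is the same
population expressed in saturated form, so the two fixtures share one
population covariance matrix and form a properly nested pair.
"""

from __future__ import annotations

import numpy as np

from .algebra import ChainWorld, implied_covariance
from .estimate import SampleMoments
from .model import ParamCell, SemModel

__all__ = [
    "FIXTURE_NAMES",
    "build_fixture",
    "saturated_pairs_model",
    "structured_pairs_model",
    "structured_pairs_truth",
    "saturated_pairs_truth",
    "structured_pairs_population",
    "chain_world_default",
    "loop_simplex_skeleton",
]

FIXTURE_NAMES = ("saturated_pairs", "structured_pairs", "chain_world", "loop_simplex")

_LATENTS = ["eta1", "eta2", "eta3", "eta4"]
_INDICATORS = [f"y{i}" for i in range(1, 9)]
# (scaling indicator, second indicator) per latent
_PAIRS = {"eta1": ("y1", "y2"), "eta2": ("y3", "y4"), "eta3": ("y5", "y6"), "eta4": ("y7", "y8")}

# generating values for structured_pairs
_TRUE_SECOND_LOADINGS = {"y2": 0.8, "y4": 0.9, "y6": 0.7, "y8": 0.85}
_TRUE_EFFECTS = {("eta1", "eta3"): 0.6, ("eta2", "eta3"): 0.4, ("eta3", "eta4"): 0.7}
_TRUE_PSI = {("eta1", "eta1"): 1.0, ("eta2", "eta2"): 1.2, ("eta1", "eta2"): 0.3,
             ("eta3", "eta3"): 0.5, ("eta4", "eta4"): 0.6}
_TRUE_THETA_FIXED = {"y1": 0.3, "y3": 0.25, "y5": 0.35, "y7": 0.3}
_TRUE_THETA_FREE = {"y2": 0.4, "y4": 0.35, "y6": 0.45, "y8": 0.4}


def _measurement_skeleton(model: SemModel) -> None:
    for latent, (scaling, second) in _PAIRS.items():
        model.set_loading(scaling, latent, ParamCell("fixed", 1.0))
        model.set_loading(second, latent, ParamCell("free", None))


def saturated_pairs_model() -> SemModel:
    """Two indicators per latent over a saturated latent block."""
    model = SemModel(_LATENTS, _INDICATORS)
    _measurement_skeleton(model)
    for i, a in enumerate(_LATENTS):
        for b in _LATENTS[: i + 1]:
            model.set_psi(b, a, ParamCell("free", None))
    for y in _INDICATORS:
        model.set_theta(y, y, ParamCell("free", None))
    model.validate(strict=False)
    return model


def structured_pairs_model() -> SemModel:
    """The pairs skeleton with latent causal structure and asserted error
    variances on the scaling indicators."""
    model = SemModel(_LATENTS, _INDICATORS)
    _measurement_skeleton(model)
    for (src, tgt) in _TRUE_EFFECTS:
        model.set_effect(src, tgt, ParamCell("free", None))
    model.set_psi("eta1", "eta1", ParamCell("free", None))
    model.set_psi("eta2", "eta2", ParamCell("free", None))
    model.set_psi("eta1", "eta2", ParamCell("free", None))
    model.set_psi("eta3", "eta3", ParamCell("free", None))
    model.set_psi("eta4", "eta4", ParamCell("free", None))
    for y, v in _TRUE_THETA_FIXED.items():
        model.set_theta(y, y, ParamCell("fixed", v))
    for y in _TRUE_THETA_FREE:
        model.set_theta(y, y, ParamCell("free", None))
    model.validate(strict=False)
    return model


def structured_pairs_truth() -> dict:
    """Generating values for every free parameter of ``structured_pairs``."""
    truth = {}
    for y, v in _TRUE_SECOND_LOADINGS.items():
        latent = next(l for l, pair in _PAIRS.items() if pair[1] == y)
        truth[f"load:{y}~{latent}"] = v
    for (src, tgt), v in _TRUE_EFFECTS.items():
        truth[f"effect:{src}->{tgt}"] = v
    for (a, b), v in _TRUE_PSI.items():
        truth[f"psi:{a},{b}"] = v
    for y, v in _TRUE_THETA_FREE.items():
        truth[f"theta:{y},{y}"] = v
    return truth


def _latent_covariance_truth() -> np.ndarray:
    """Population latent covariance matrix implied by the structured truth."""
    m = len(_LATENTS)
    B = np.zeros((m, m))
    Psi = np.zeros((m, m))
    for (src, tgt), v in _TRUE_EFFECTS.items():
        B[_LATENTS.index(tgt), _LATENTS.index(src)] = v
    for (a, b), v in _TRUE_PSI.items():
        i, j = _LATENTS.index(a), _LATENTS.index(b)
        Psi[i, j] = Psi[j, i] = v
    A = np.linalg.inv(np.eye(m) - B)
    return A @ Psi @ A.T


def saturated_pairs_truth() -> dict:
    """The structured population re-expressed in saturated-block form."""
    truth = {}
    for y, v in _TRUE_SECOND_LOADINGS.items():
        latent = next(l for l, pair in _PAIRS.items() if pair[1] == y)
        truth[f"load:{y}~{latent}"] = v
    C = _latent_covariance_truth()
    for i, a in enumerate(_LATENTS):
        for j in range(i + 1):
            b = _LATENTS[j]
            truth[f"psi:{b},{a}"] = float(C[i, j])
    for y, v in {**_TRUE_THETA_FIXED, **_TRUE_THETA_FREE}.items():
        truth[f"theta:{y},{y}"] = v
    return truth


def structured_pairs_population(N: int = 100000) -> SampleMoments:
    """Exact population covariance matrix of the eight indicators."""
    model = structured_pairs_model()
    Sigma = implied_covariance(model, structured_pairs_truth()).Sigma
    return SampleMoments(Sigma, N, list(_INDICATORS))


def chain_world_default() -> ChainWorld:
    """The worked chain world: unit spine, Var(eta_A)=1, disturbances
    0.5/0.5/0.2, y6 loading 0.8, y6 error variance 0.5."""
    return ChainWorld()


def loop_simplex_skeleton(n_occasions: int = 10) -> SemModel:
    """Repeated single measurements as a loop simplex.

    Each occasion's latent state persists to the next with a fixed unit
    effect; a free self-causative loop (a nonzero B diagonal) and a free
    disturbance act at every occasion after the first.  Each indicator's
    error variance is asserted as 3% of its observed variance, resolved when
    a covariance matrix is supplied.
    """
    latents = [f"state{t}" for t in range(1, n_occasions + 1)]
    indicators = [f"d{t}" for t in range(1, n_occasions + 1)]
    model = SemModel(latents, indicators)
    for lat, ind in zip(latents, indicators):
        model.set_loading(ind, lat, ParamCell("fixed", 1.0))
        model.set_theta(ind, ind, ParamCell("fixed", None, pct=3.0))
    for t in range(n_occasions - 1):
        model.set_effect(latents[t], latents[t + 1], ParamCell("fixed", 1.0))
    model.set_psi(latents[0], latents[0], ParamCell("free", None))
    for t in range(1, n_occasions):
        model.set_effect(latents[t], latents[t], ParamCell("free", 0.0))  # self-loop
        model.set_psi(latents[t], latents[t], ParamCell("free", None))
    model.validate(strict=False)
    return model


def build_fixture(name: str):
    """Catalog lookup: returns a :class:`SemModel` or :class:`ChainWorld`."""
    if name == "saturated_pairs":
        return saturated_pairs_model()
    if name == "structured_pairs":
        return structured_pairs_model()
    if name == "chain_world":
        return chain_world_default()
    if name == "loop_simplex":
        return loop_simplex_skeleton()
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
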