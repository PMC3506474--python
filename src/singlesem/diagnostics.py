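"""Modification indices and expected parameter change for fixed parameters.

The modification index (MI) is the score (Lagrange-multiplier) statistic for
freeing a single fixed parameter at the constrained optimum: with ``g`` the
gradient of the ML discrepancy in the candidate's direction and ``v`` the
expected information for the candidate after partialling out the free
parameters,

    MI = multiplier * g^2 / (2 v),      EPC = -g / v,

asymptotically chi-square with 1 df, approximating the chi-square drop an
actual refit with that parameter freed would produce.  A fixed parameter
whose freeing would leave the model locally unidentified has ``v = 0``: it
cannot generate misfit, so its MI is reported as zero with an explicit flag
— an honestly uninformative diagnostic, not evidence the fixed value is
right.  A refit mode computes the exact chi-square drop by refitting and
doubles as an independent check on the score form.

Error-covariance candidates are annotated with a caution: freed measurement
error covariances tend to become fudge-factors that buy fit without theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .algebra import implied_covariance_derivs
from .estimate import FitOptions, FitResult, SampleMoments, fit_ml
from .model import FREE, ModelError, ParamCell, SemModel

__all__ = [
    "DiagnosticEntry",
    "modification_indices",
    "underidentified_if_freed",
    "default_candidates",
]

_RANK_TOL = 1e-7


@dataclass
class DiagnosticEntry:
    parameter: str
    matrix: str
    row: int
    col: int
    mi: float
    epc: Optional[float]
    identified_if_freed: bool
    note: str = ""
    mi_refit: Optional[float] = None


def default_candidates(model: SemModel) -> list:
    """Fixed Theta diagonals plus structurally absent latent effects."""
    cells = []
    for i in range(model.p):
        if not model.Theta[i, i].is_free:
            cells.append(("Theta", i, i))
    for i in range(model.m):
        for j in range(model.m):
            if i != j and not model.B[i, j].is_free:
                cells.append(("B", i, j))
    return cells


def all_fixed_cells(model: SemModel) -> list:
    """Every fixed cell (full-matrix scan)."""
    cells = []
    for i in range(model.p):
        for j in range(model.m):
            if not model.Lambda[i, j].is_free:
                cells.append(("Lambda", i, j))
    for i in range(model.m):
        for j in range(model.m):
            if not model.B[i, j].is_free:
                cells.append(("B", i, j))
    for i in range(model.m):
        for j in range(i + 1):
            if not model.Psi[i, j].is_free:
                cells.append(("Psi", i, j))
    for i in range(model.p):
        for j in range(i + 1):
            if not model.Theta[i, j].is_free:
                cells.append(("Theta", i, j))
    return cells


def _resolve_cell(model: SemModel, cell) -> tuple:
    """Accept ('Theta', i, j) tuples or parameter-name strings."""
    if isinstance(cell, tuple):
        return cell
    name = str(cell)
    for matrix, rng1, rng2 in (
        ("Lambda", model.p, model.m),
        ("B", model.m, model.m),
        ("Psi", model.m, model.m),
        ("Theta", model.p, model.p),
    ):
        for i in range(rng1):
            for j in range(rng2):
                if model.cell_name(matrix, i, j) == name:
                    return (matrix, i, j)
    # bare indicator name means its error variance
    if name in model.indicator_names:
        i = model.indicator_names.index(name)
        return ("Theta", i, i)
    raise ModelError(f"unknown candidate cell {cell!r}")


def _partialled_information(Sigma_inv, derivs, extra_deriv):
    """(g is computed elsewhere) residual information v for the candidate after
    projecting out the free-parameter directions, plus the relative residual
    norm of the candidate's moment derivative (the rank test)."""
    k = len(derivs)
    SiDc = Sigma_inv @ extra_deriv
    E_cc = float(np.sum(SiDc * SiDc.T))
    if k == 0:
        v = E_cc
        rel_resid = 1.0 if E_cc > 0 else 0.0
        return v, rel_resid
    SiD = [Sigma_inv @ d for d in derivs]
    E_ff = np.empty((k, k))
    for a in range(k):
        for b in range(a + 1):
            E_ff[a, b] = E_ff[b, a] = float(np.sum(SiD[a] * SiD[b].T))
    E_fc = np.array([float(np.sum(SiD[a] * SiDc.T)) for a in range(k)])
    # solve in a rank-aware way: E_ff can itself be near-singular
    sol, *_ = np.linalg.lstsq(E_ff, E_fc, rcond=None)
    v = E_cc - float(E_fc @ sol)
    rel_resid = v / E_cc if E_cc > 0 else 0.0
    return v, rel_resid


def underidentified_if_freed(model: SemModel, cell, theta=None) -> bool:
    """Would freeing this fixed cell leave the model locally unidentified?

    True when the candidate's implied-moment derivative lies (numerically) in
    the span of the free parameters' derivatives at ``theta`` — freeing it
    then adds no new direction to the implied-moment map, so the parameter is
    un-estimable and can never signal its own misspecification.
    """
    matrix, i, j = _resolve_cell(model, cell)
    target = getattr(model, matrix)[i, j]
    if target.is_free:
        raise ModelError(f"candidate {model.cell_name(matrix, i, j)} is already free")
    Sigma, derivs, extra = implied_covariance_derivs(model, theta, [(matrix, i, j)])
    Sigma_inv = np.linalg.inv(Sigma)
    _, rel_resid = _partialled_information(Sigma_inv, derivs, extra[0])
    return bool(rel_resid < _RANK_TOL)


def _freed_copy(model: SemModel, matrix, i, j) -> SemModel:
    out = model.copy()
    old = getattr(out, matrix)[i, j]
    cell = ParamCell(FREE, old.value)
    if matrix == "Lambda":
        out.Lambda[i, j] = cell
    elif matrix == "B":
        out.B[i, j] = cell
    elif matrix == "Psi":
        out.Psi[i, j] = cell
        out.Psi[j, i] = cell
    else:
        out.Theta[i, j] = cell
        out.Theta[j, i] = cell
    return out


def modification_indices(
    model: SemModel,
    fit: FitResult,
    moments: Optional[SampleMoments] = None,
    candidates=None,
    refit: bool = False,
    refit_options: Optional[FitOptions] = None,
) -> list[DiagnosticEntry]:
    """Score-test MI and EPC for each candidate fixed cell at the fitted optimum.

    ``model`` may be the original (pre-resolution) model; computation uses
    the resolved model stored on ``fit``.  With ``refit=True`` each
    identified candidate is also actually freed and refitted, recording the
    exact chi-square drop in ``mi_refit``.
    """
    if not fit.converged:
        raise ModelError("fit did not converge; diagnostics would be unreliable")
    moments = moments or fit.moments
    resolved = fit.model
    S = moments.aligned_to(resolved).S
    cells = candidates if candidates is not None else default_candidates(resolved)
    cells = [_resolve_cell(resolved, c) for c in cells]
    for matrix, i, j in cells:
        if getattr(resolved, matrix)[i, j].is_free:
            raise ModelError(
                f"candidate {resolved.cell_name(matrix, i, j)} is already free"
            )

    Sigma, derivs, extras = implied_covariance_derivs(resolved, fit.theta_hat, cells)
    Sigma_inv = np.linalg.inv(Sigma)
    W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    mult = fit.multiplier

    entries = []
    for (matrix, i, j), dC in zip(cells, extras):
        name = resolved.cell_name(matrix, i, j)
        g = float(np.sum(W * dC))
        v, rel_resid = _partialled_information(Sigma_inv, derivs, dC)
        note = ""
        if matrix == "Theta" and i != j:
            note = "error covariance: freed error covariances tend to become fudge-factors"
        if rel_resid < _RANK_TOL:
            entries.append(
                DiagnosticEntry(
                    name, matrix, i, j, 0.0, None, False,
                    note=(note + "; " if note else "")
                    + "underidentified if freed: MI uninformative even if the fixed value is wrong",
                )
            )
            continue
        mi = mult * g * g / (2.0 * v)
        epc = -g / v
        entry = DiagnosticEntry(name, matrix, i, j, float(mi), float(epc), True, note=note)
        if refit:
            freed = _freed_copy(resolved, matrix, i, j)
            ropts = refit_options or FitOptions(chisq_multiplier="n-1" if mult == moments.N - 1 else "n")
            refit_res = fit_ml(freed, moments, ropts)
            entry.mi_refit = float(max(fit.chisq - refit_res.chisq, 0.0))
        entries.append(entry)
    return entries
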