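"""Specification-assertion workflow for fixed measurement error variances.

Three utilities support the analyst who asserts, rather than estimates, a
measurement error variance for each scaling (best) indicator:

* :func:`elicit_error_variance` turns percent-of-variance judgments about
  the indicator's error sources into an absolute fixed value,
* :func:`half_and_double` refits the model with each asserted value halved
  and doubled, one target at a time, and reports how the monitored estimates
  move — the standard sensitivity probe for assertions that may be
  underidentified-if-freed and hence invisible to fit diagnostics,
* :func:`variance_perturbation_demo` recomputes a variable's variance after
  hand-edited case values, a familiarization exercise for judging how much
  variance plausible error processes can produce.

No threshold declares a sensitivity "substantial": the numbers are reported
and judgment stays with the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .estimate import FitOptions, FitResult, SampleMoments, fit_ml
from .model import ModelError, SemModel

__all__ = [
    "SensitivityReport",
    "elicit_error_variance",
    "half_and_double",
    "variance_perturbation_demo",
]

_REL_CHANGE_FLOOR = 1e-8


def elicit_error_variance(observed_variance: float, error_percents: Sequence[float]) -> float:
    """Fixed error variance = observed variance times the summed error percents.

    Each percent is the share of the indicator's variance the analyst
    attributes to one error source (one disturbance entering between the
    intended latent and the indicator).  Percents are additive because the
    error sources are modeled as independent; their sum cannot exceed 100.
    """
    if observed_variance < 0:
        raise ValueError("observed variance is negative")
    pcts = [float(x) for x in error_percents]
    for x in pcts:
        if not 0.0 <= x <= 100.0:
            raise ValueError(f"error percent {x} outside [0, 100]")
    total = sum(pcts)
    if total > 100.0:
        raise ValueError(
            f"error percents sum to {total} > 100: error variance cannot exceed "
            "the indicator's total variance"
        )
    return observed_variance * total / 100.0


# ---------------------------------------------------------------------------
# Half and double
# ---------------------------------------------------------------------------


@dataclass
class SensitivityReport:
    target: str  # indicator whose fixed error variance is varied
    baseline_value: float
    half_value: float
    double_value: float
    monitored: list  # parameter names
    estimates: dict  # name -> (half, baseline, double)
    chisq: tuple  # (half, baseline, double)
    max_relative_change: float
    flags: list = field(default_factory=list)


def _monitored_params(model: SemModel, target_idx: int, monitor) -> list:
    params = model.free_parameters()
    if monitor == "all":
        return [fp.name for fp in params]
    if isinstance(monitor, (list, tuple)):
        names = [fp.name for fp in params]
        unknown = [m for m in monitor if m not in names]
        if unknown:
            raise ModelError(f"monitored parameters not free in the model: {unknown}")
        return list(monitor)
    if monitor != "auto":
        raise ModelError(f"monitor must be 'auto', 'all', or a list, got {monitor!r}")
    # auto: free parameters directly connected to the latent the target scales
    latents = [
        j
        for j in range(model.m)
        if model.Lambda[target_idx, j].status == "fixed"
        and model.Lambda[target_idx, j].value not in (None, 0.0)
    ]
    if not latents:
        latents = [j for j in range(model.m) if model.Lambda[target_idx, j].is_free]
    lat = set(latents)
    out = []
    for fp in params:
        for matrix, i, j in fp.cells:
            if matrix == "Lambda" and j in lat:
                out.append(fp.name)
                break
            if matrix in ("B", "Psi") and (i in lat or j in lat):
                out.append(fp.name)
                break
    return out


def half_and_double(
    model: SemModel,
    moments: SampleMoments,
    targets: Sequence[str],
    monitor="auto",
    options: Optional[FitOptions] = None,
    baseline_fit: Optional[FitResult] = None,
) -> list[SensitivityReport]:
    """Refit with each target's fixed error variance halved and doubled.

    Targets are varied one at a time with all other fixed values at baseline.
    Each report carries the three fits' monitored estimates and chi-squares
    plus the largest relative estimate change against the baseline.  The
    input model is never modified.
    """
    opts = options or FitOptions()
    moments = moments.aligned_to(model)
    resolved = model.resolve_fixed_pct(moments.S)
    if baseline_fit is None:
        baseline_fit = fit_ml(resolved, moments, opts)
    reports = []
    for target in targets:
        if target not in model.indicator_names:
            raise ModelError(f"unknown target indicator {target!r}")
        ti = model.indicator_names.index(target)
        cell = resolved.Theta[ti, ti]
        if cell.is_free:
            raise ModelError(f"error variance of {target!r} is free, not a fixed assertion")
        base_val = cell.value
        if base_val is None:
            raise ModelError(f"error variance of {target!r} is unresolved")
        if base_val == 0.0:
            raise ModelError(
                f"error variance of {target!r} is fixed at zero; halving and doubling "
                "zero is degenerate — a zero error variance claims an error-free "
                "indicator, which is itself the assertion to reconsider"
            )
        monitored = _monitored_params(resolved, ti, monitor)
        variants = {}
        chisqs = {}
        flags = []
        for tag, factor in (("half", 0.5), ("baseline", 1.0), ("double", 2.0)):
            if tag == "baseline":
                fit = baseline_fit
            else:
                variant = resolved.copy()
                vc = variant.Theta[ti, ti]
                vc.value = base_val * factor
                variant.Theta[ti, ti] = vc
                variant.Theta[ti, ti] = vc
                fit = fit_ml(variant, moments, opts)
                if not fit.converged:
                    flags.append(f"{tag}: non-convergence, estimates are the best point found")
                for f in fit.flags:
                    if f.startswith("heywood"):
                        flags.append(f"{tag}: {f}")
            variants[tag] = fit.estimates()
            chisqs[tag] = fit.chisq
        estimates = {
            name: (
                variants["half"].get(name, np.nan),
                variants["baseline"].get(name, np.nan),
                variants["double"].get(name, np.nan),
            )
            for name in monitored
        }
        max_rel = 0.0
        for name, (h, b, d) in estimates.items():
            denom = max(abs(b), _REL_CHANGE_FLOOR)
            for alt in (h, d):
                if np.isfinite(alt):
                    max_rel = max(max_rel, abs(alt - b) / denom)
        reports.append(
            SensitivityReport(
                target=target,
                baseline_value=float(base_val),
                half_value=float(base_val) / 2.0,
                double_value=float(base_val) * 2.0,
                monitored=monitored,
                estimates=estimates,
                chisq=(chisqs["half"], chisqs["baseline"], chisqs["double"]),
                max_relative_change=float(max_rel),
                flags=flags,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Variance-perturbation familiarization
# ---------------------------------------------------------------------------


def variance_perturbation_demo(values: Sequence[float], edits: Sequence[tuple]) -> dict:
    """Variance before/after hand edits to a *copy* of the values.

    ``edits`` is a list of ``(case_index, new_value)``.  The sample variance
    uses the N-1 denominator.  ``percent_change`` is None when the baseline
    variance is zero (undefined from zero).  The input sequence is never
    modified.
    """
    vals = np.array(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    if vals.size < 2:
        raise ValueError("variance needs at least two cases")
    edited = vals.copy()
    for idx, new in edits:
        if not 0 <= int(idx) < vals.size:
            raise IndexError(f"case index {idx} out of range for {vals.size} cases")
        edited[int(idx)] = float(new)
    before = float(np.var(vals, ddof=1))
    after = float(np.var(edited, ddof=1))
    if before == 0.0:
        pct = None
    else:
        pct = 100.0 * (after - before) / before
    return {
        "variance_before": before,
        "variance_after": after,
        "percent_change": pct,
    }
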