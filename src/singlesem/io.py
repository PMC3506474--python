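"""Readers and writers: covariance CSV, model files, and report output.

Covariance CSV format: first row and first column carry the variable names,
the body is numeric (decimal point, UTF-8).  Symmetry is enforced within
1e-8 at load; asymmetry above 1e-12 is symmetrized by averaging with a
warning.  Reports are written twice — a human-readable text summary and a
TSV twin with a deterministic field order — and embed every warning the run
produced, so the files are self-describing.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticEntry
from .estimate import FitResult, SampleMoments
from .model import ModelError, SemModel, count_df, parse_model, serialize_model
from .sensitivity import SensitivityReport

__all__ = [
    "read_covariance_csv",
    "write_covariance_csv",
    "read_model_file",
    "write_model_file",
    "fit_report_text",
    "fit_report_rows",
    "diagnostics_rows",
    "sensitivity_rows",
    "write_report",
    "write_tsv",
]

logger = logging.getLogger("singlesem")

_SYM_HARD = 1e-8
_SYM_WARN = 1e-12


def read_covariance_csv(path, n: int) -> SampleMoments:
    """Load a labeled square covariance CSV with sample size ``n``."""
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as e:
        raise ModelError(f"cannot parse covariance CSV {path}: {e}") from e
    if df.shape[0] != df.shape[1]:
        raise ModelError(f"covariance matrix in {path} is not square: {df.shape}")
    names = [str(c) for c in df.columns]
    row_names = [str(r) for r in df.index]
    if names != row_names:
        raise ModelError(
            f"row and column names differ in {path}: {row_names} vs {names}"
        )
    try:
        S = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ModelError(f"non-numeric cell in {path}: {e}") from e
    asym = float(np.abs(S - S.T).max()) if S.size else 0.0
    if asym > _SYM_HARD:
        raise ModelError(
            f"covariance matrix in {path} is asymmetric beyond tolerance "
            f"(max |S - S^T| = {asym:.3g} > {_SYM_HARD})"
        )
    if asym > _SYM_WARN:
        logger.warning("symmetrized covariance matrix from %s (max asymmetry %.3g)", path, asym)
    return SampleMoments((S + S.T) / 2.0, n, names)


def write_covariance_csv(moments: SampleMoments, path) -> None:
    df = pd.DataFrame(moments.S, index=moments.variable_names, columns=moments.variable_names)
    # default float formatting is repr-based and round-trips exactly
    df.to_csv(path)


def read_model_file(path) -> SemModel:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def write_model_file(model: SemModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_model(model))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _cell_status(model: SemModel, matrix: str, i: int, j: int) -> str:
    cell = getattr(model, matrix)[i, j]
    if cell.is_free:
        return f"eq:{cell.label}" if cell.label else "free"
    if cell.pct is not None and cell.value is None:
        return f"fixed_pct:{cell.pct:g}"
    return "fixed"


def fit_report_rows(fit: FitResult) -> list[dict]:
    """One TSV row per distinct model parameter (free and fixed-nonzero)."""
    model = fit.model
    est = fit.estimates()
    se_map = (
        {n: float(s) for n, s in zip(fit.param_names, fit.se)} if fit.se is not None else {}
    )
    rows = []
    seen_labels = set()
    for matrix, i, j, cell in model._iter_cells():
        if not cell.is_free and (cell.value in (None, 0.0)) and cell.pct is None:
            continue
        if cell.label is not None:
            if cell.label in seen_labels:
                continue
            seen_labels.add(cell.label)
            name = f"eq:{cell.label}"
        else:
            name = model.cell_name(matrix, i, j)
        if cell.is_free:
            value = est.get(name, np.nan)
            se = se_map.get(name, np.nan)
        else:
            value = cell.value
            se = np.nan
        rows.append(
            {
                "parameter": name,
                "matrix": matrix,
                "row": i,
                "col": j,
                "status": _cell_status(model, matrix, i, j),
                "estimate": value,
                "se": se,
            }
        )
    return rows


def fit_report_text(fit: FitResult, header_lines: Optional[Iterable[str]] = None) -> str:
    audit = fit.audit
    lines = []
    if header_lines:
        lines.extend(f"# {h}" for h in header_lines)
    lines.append("MODEL FIT (maximum likelihood)")
    lines.append(
        f"  latents: {len(fit.model.latent_names)}   indicators: {len(fit.model.indicator_names)}"
        f"   N = {fit.moments.N}"
    )
    bd = audit.breakdown
    lines.append(
        f"  df audit: moments={audit.n_moments}  free={audit.n_free} "
        f"(loadings={bd['Lambda']}, effects={bd['B']}, psi={bd['Psi']}, theta={bd['Theta']})"
        f"  df={audit.df}"
    )
    if audit.under_determined:
        lines.append("  WARNING: model is under-determined (negative df)")
    lines.append(
        f"  F_ML = {fit.F_ML:.10g}   chisq = {fit.chisq:.6g} (multiplier {fit.multiplier:g})"
        f"   df = {fit.df}   p = {fit.p_value:.4g}"
    )
    lines.append(
        f"  converged: {fit.converged}   iterations: {fit.n_iterations}"
        f"   gradient max-norm: {fit.gradient_norm:.3g}   restarts: {fit.restarts_used}"
    )
    if fit.restart_seeds:
        lines.append(f"  restart seeds: {fit.restart_seeds}")
    for flag in fit.flags:
        lines.append(f"  WARNING: {flag}")
    lines.append("")
    lines.append(f"  {'parameter':<28} {'status':<14} {'estimate':>12} {'se':>10}")
    for row in fit_report_rows(fit):
        se = f"{row['se']:.4g}" if np.isfinite(row["se"]) else "-"
        lines.append(
            f"  {row['parameter']:<28} {row['status']:<14} {row['estimate']:>12.6g} {se:>10}"
        )
    return "\n".join(lines) + "\n"


def diagnostics_rows(entries: list[DiagnosticEntry]) -> list[dict]:
    return [
        {
            "parameter": e.parameter,
            "mi": e.mi,
            "epc": e.epc if e.epc is not None else "",
            "identified_if_freed": e.identified_if_freed,
            "mi_refit": e.mi_refit if e.mi_refit is not None else "",
            "note": e.note,
        }
        for e in entries
    ]


def sensitivity_rows(reports: list[SensitivityReport]) -> list[dict]:
    """Long format: one row per target x variant x monitored parameter."""
    rows = []
    for rep in reports:
        for tag, value, k in (
            ("half", rep.half_value, 0),
            ("baseline", rep.baseline_value, 1),
            ("double", rep.double_value, 2),
        ):
            for name in rep.monitored:
                rows.append(
                    {
                        "target": rep.target,
                        "variant": tag,
                        "fixed_value": value,
                        "parameter": name,
                        "estimate": rep.estimates[name][k],
                        "chisq": rep.chisq[k],
                    }
                )
    return rows


def write_tsv(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_report(path_base, fit: Optional[FitResult] = None,
                 diagnostics: Optional[list] = None,
                 sensitivity: Optional[list] = None,
                 header_lines: Optional[Iterable[str]] = None) -> list:
    """Write ``<base>.txt`` plus TSV twins for whichever objects are given."""
    written = []
    base = str(path_base)
    text_parts = []
    if fit is not None:
        text_parts.append(fit_report_text(fit, header_lines))
        write_tsv(fit_report_rows(fit), base + ".tsv")
        written.append(base + ".tsv")
    if diagnostics is not None:
        rows = diagnostics_rows(diagnostics)
        write_tsv(rows, base + "_diagnostics.tsv")
        written.append(base + "_diagnostics.tsv")
        text_parts.append(
            "DIAGNOSTICS (modification indices)\n"
            + "\n".join(
                f"  {r['parameter']:<28} MI={r['mi']:.6g} EPC={r['epc'] if r['epc'] != '' else '-'}"
                f" identified={r['identified_if_freed']} {r['note']}"
                for r in rows
            )
            + "\n"
        )
    if sensitivity is not None:
        rows = sensitivity_rows(sensitivity)
        write_tsv(rows, base + "_sensitivity.tsv")
        written.append(base + "_sensitivity.tsv")
        text_parts.append(
            "SENSITIVITY (half and double)\n"
            + "\n".join(
                f"  target={rep.target} baseline={rep.baseline_value:g} "
                f"max_relative_change={rep.max_relative_change:.4g}"
                + (f" flags={rep.flags}" if rep.flags else "")
                for rep in sensitivity
            )
            + "\n"
        )
    with open(base + ".txt", "w", encoding="utf-8") as fh:
        if header_lines and fit is None:
            fh.write("".join(f"# {h}\n" for h in header_lines))
        fh.write("\n".join(text_parts))
    written.insert(0, base + ".txt")
    return written
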