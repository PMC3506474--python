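"""Model representation for covariance-structure models in LISREL-style notation.

A model is four matrices of parameter cells:

* ``Lambda`` (p x m): effects of latents on indicators ("loadings"),
* ``B`` (m x m): latent-to-latent effects; ``B[t, s]`` is the effect of latent
  ``s`` on latent ``t``.  Diagonal entries may be nonzero (self-causative loops),
* ``Psi`` (m x m, symmetric): latent disturbance (co)variances,
* ``Theta`` (p x p, symmetric): measurement error (co)variances.

Each cell is fixed, free, or free-with-equality-label ("constrained").  The
toolkit follows the single/best-indicator specification convention: each latent
is scaled by one indicator whose loading is fixed at 1.0, and that scaling
indicator carries a *fixed* measurement error variance chosen by the analyst —
either an absolute value or a percent of the indicator's observed variance
(``FIXED_PCT``, resolved against the sample covariance diagonal at fit time).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

__all__ = [
    "ParamCell",
    "SemModel",
    "DfAudit",
    "FreeParam",
    "ModelError",
    "ModelSyntaxError",
    "parse_model",
    "serialize_model",
    "count_df",
    "check_empirical_identification",
    "IdentificationReport",
]


class ModelError(ValueError):
    """A structurally invalid model."""


class ModelSyntaxError(ModelError):
    """Model-grammar text that does not parse; carries a 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# Parameter cells
# ---------------------------------------------------------------------------

FIXED = "fixed"
FREE = "free"
CONSTRAINED = "constrained"  # free, pooled with all cells sharing its label


@dataclass
class ParamCell:
    """One entry of a model matrix.

    ``value`` is the fixed value for fixed cells, or the starting value for
    free cells (``None`` means "use the default start policy at fit time").
    ``label`` pools the cell with every other cell carrying the same label
    into a single underlying parameter.  ``pct`` holds a percent-of-observed-
    variance declaration for a fixed error variance; it is resolved against
    ``diag(S)`` when a sample covariance matrix becomes available.
    """

    status: str = FIXED
    value: Optional[float] = 0.0
    label: Optional[str] = None
    pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in (FIXED, FREE, CONSTRAINED):
            raise ModelError(f"unknown cell status {self.status!r}")
        if self.label is not None and self.status == FIXED:
            raise ModelError("fixed cells cannot carry an equality label")
        if self.label is not None:
            self.status = CONSTRAINED
        if self.pct is not None and self.status != FIXED:
            raise ModelError("FIXED_PCT cells must be fixed")

    @property
    def is_free(self) -> bool:
        return self.status in (FREE, CONSTRAINED)

    def copy(self) -> "ParamCell":
        return ParamCell(self.status, self.value, self.label, self.pct)


def fixed(value: float) -> ParamCell:
    return ParamCell(FIXED, float(value))


def fixed_pct(percent: float) -> ParamCell:
    return ParamCell(FIXED, None, pct=float(percent))


def free(start: Optional[float] = None, label: Optional[str] = None) -> ParamCell:
    return ParamCell(FREE, start, label)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


@dataclass
class FreeParam:
    """One distinct free parameter: possibly several pooled cells."""

    name: str
    matrix: str  # matrix of the first cell, used for the df breakdown
    cells: list  # list of (matrix_name, i, j)
    start: Optional[float]  # explicit start, or None for the default policy


class SemModel:
    """A structural equation model over ``m`` latents and ``p`` indicators."""

    def __init__(self, latent_names: Iterable[str], indicator_names: Iterable[str]):
        self.latent_names = list(latent_names)
        self.indicator_names = list(indicator_names)
        if len(set(self.latent_names)) != len(self.latent_names):
            raise ModelError("duplicate latent names")
        if len(set(self.indicator_names)) != len(self.indicator_names):
            raise ModelError("duplicate indicator names")
        overlap = set(self.latent_names) & set(self.indicator_names)
        if overlap:
            raise ModelError(f"names used as both latent and indicator: {sorted(overlap)}")
        m, p = self.m, self.p
        self.Lambda = np.empty((p, m), dtype=object)
        self.B = np.empty((m, m), dtype=object)
        self.Psi = np.empty((m, m), dtype=object)
        self.Theta = np.empty((p, p), dtype=object)
        for M in (self.Lambda, self.B, self.Psi, self.Theta):
            for idx in np.ndindex(M.shape):
                M[idx] = ParamCell(FIXED, 0.0)
        # symmetric matrices share one cell object across the diagonal
        for i in range(m):
            for j in range(i):
                self.Psi[i, j] = self.Psi[j, i]
        for i in range(p):
            for j in range(i):
                self.Theta[i, j] = self.Theta[j, i]

    # -- dimensions ---------------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.latent_names)

    @property
    def p(self) -> int:
        return len(self.indicator_names)

    # -- name lookup --------------------------------------------------------

    def _latent_index(self, name: str) -> int:
        try:
            return self.latent_names.index(name)
        except ValueError:
            raise ModelError(f"unknown latent {name!r}") from None

    def _indicator_index(self, name: str) -> int:
        try:
            return self.indicator_names.index(name)
        except ValueError:
            raise ModelError(f"unknown indicator {name!r}") from None

    # -- cell setters (symmetric matrices stay symmetric by construction) ---

    def set_loading(self, indicator: str, latent: str, cell: ParamCell) -> None:
        self.Lambda[self._indicator_index(indicator), self._latent_index(latent)] = cell

    def set_effect(self, source: str, target: str, cell: ParamCell) -> None:
        """Latent-to-latent effect source -> target (B[target, source])."""
        self.B[self._latent_index(target), self._latent_index(source)] = cell

    def set_psi(self, a: str, b: str, cell: ParamCell) -> None:
        i, j = self._latent_index(a), self._latent_index(b)
        self.Psi[i, j] = cell
        self.Psi[j, i] = cell

    def set_theta(self, a: str, b: str, cell: ParamCell) -> None:
        i, j = self._indicator_index(a), self._indicator_index(b)
        if i == j and cell.status == FIXED and cell.value is not None and cell.value < 0:
            raise ModelError(f"negative fixed error variance for {a!r}")
        self.Theta[i, j] = cell
        self.Theta[j, i] = cell

    def get_loading(self, indicator: str, latent: str) -> ParamCell:
        return self.Lambda[self._indicator_index(indicator), self._latent_index(latent)]

    def get_effect(self, source: str, target: str) -> ParamCell:
        return self.B[self._latent_index(target), self._latent_index(source)]

    def get_psi(self, a: str, b: str) -> ParamCell:
        return self.Psi[self._latent_index(a), self._latent_index(b)]

    def get_theta(self, a: str, b: str) -> ParamCell:
        return self.Theta[self._indicator_index(a), self._indicator_index(b)]

    def copy(self) -> "SemModel":
        out = SemModel(self.latent_names, self.indicator_names)
        for i in range(self.p):
            for j in range(self.m):
                out.Lambda[i, j] = self.Lambda[i, j].copy()
        for i in range(self.m):
            for j in range(self.m):
                out.B[i, j] = self.B[i, j].copy()
        for i in range(self.m):
            for j in range(i + 1):
                c = self.Psi[i, j].copy()
                out.Psi[i, j] = c
                out.Psi[j, i] = c
        for i in range(self.p):
            for j in range(i + 1):
                c = self.Theta[i, j].copy()
                out.Theta[i, j] = c
                out.Theta[j, i] = c
        return out

    # -- free-parameter indexing -------------------------------------------

    def cell_name(self, matrix: str, i: int, j: int) -> str:
        if matrix == "Lambda":
            return f"load:{self.indicator_names[i]}~{self.latent_names[j]}"
        if matrix == "B":
            return f"effect:{self.latent_names[j]}->{self.latent_names[i]}"
        if matrix == "Psi":
            a, b = sorted((i, j))
            return f"psi:{self.latent_names[a]},{self.latent_names[b]}"
        if matrix == "Theta":
            a, b = sorted((i, j))
            return f"theta:{self.indicator_names[a]},{self.indicator_names[b]}"
        raise ModelError(f"unknown matrix {matrix!r}")

    def _iter_cells(self):
        """All distinct cells in canonical order (symmetric: lower triangle)."""
        for i in range(self.p):
            for j in range(self.m):
                yield "Lambda", i, j, self.Lambda[i, j]
        for i in range(self.m):
            for j in range(self.m):
                yield "B", i, j, self.B[i, j]
        for i in range(self.m):
            for j in range(i + 1):
                yield "Psi", i, j, self.Psi[i, j]
        for i in range(self.p):
            for j in range(i + 1):
                yield "Theta", i, j, self.Theta[i, j]

    def free_parameters(self) -> list[FreeParam]:
        """Distinct free parameters; equality-labeled cells pool into one."""
        params: list[FreeParam] = []
        by_label: dict[str, FreeParam] = {}
        for matrix, i, j, cell in self._iter_cells():
            if not cell.is_free:
                continue
            if cell.label is not None:
                if cell.label in by_label:
                    by_label[cell.label].cells.append((matrix, i, j))
                    continue
                fp = FreeParam(f"eq:{cell.label}", matrix, [(matrix, i, j)], cell.value)
                by_label[cell.label] = fp
                params.append(fp)
            else:
                params.append(
                    FreeParam(self.cell_name(matrix, i, j), matrix, [(matrix, i, j)], cell.value)
                )
        return params

    def has_unresolved_pct(self) -> bool:
        return any(c.pct is not None and c.value is None for _, _, _, c in self._iter_cells())

    def resolve_fixed_pct(self, S: np.ndarray) -> "SemModel":
        """Return a copy with FIXED_PCT error variances resolved against diag(S)."""
        out = self.copy()
        for i in range(out.p):
            cell = out.Theta[i, i]
            if cell.pct is not None:
                cell.value = float(S[i, i]) * cell.pct / 100.0
        return out

    def materialize(self, theta=None):
        """Numeric (Lambda, B, Psi, Theta) at free-parameter values ``theta``.

        ``theta`` may be a vector ordered as ``free_parameters()``, a mapping
        from parameter name to value, or None (all free cells at their starts;
        raises if any start is unset).
        """
        params = self.free_parameters()
        if theta is None:
            values = [fp.start for fp in params]
            if any(v is None for v in values):
                missing = [fp.name for fp, v in zip(params, values) if v is None]
                raise ModelError(f"no value for free parameters {missing}")
        elif isinstance(theta, dict):
            missing = [fp.name for fp in params if fp.name not in theta]
            if missing:
                raise ModelError(f"theta mapping missing parameters {missing}")
            values = [theta[fp.name] for fp in params]
        else:
            theta = np.asarray(theta, dtype=float)
            if theta.shape != (len(params),):
                raise ModelError(
                    f"theta has length {theta.size}, model has {len(params)} free parameters"
                )
            values = list(theta)

        mats = {
            "Lambda": np.zeros((self.p, self.m)),
            "B": np.zeros((self.m, self.m)),
            "Psi": np.zeros((self.m, self.m)),
            "Theta": np.zeros((self.p, self.p)),
        }
        for matrix, i, j, cell in self._iter_cells():
            if cell.is_free:
                continue
            if cell.value is None:
                raise ModelError(
                    f"unresolved FIXED_PCT cell {self.cell_name(matrix, i, j)}; "
                    "resolve against a sample covariance matrix first"
                )
            mats[matrix][i, j] = cell.value
            if matrix in ("Psi", "Theta") and i != j:
                mats[matrix][j, i] = cell.value
        for fp, v in zip(params, values):
            for matrix, i, j in fp.cells:
                mats[matrix][i, j] = v
                if matrix in ("Psi", "Theta") and i != j:
                    mats[matrix][j, i] = v
        return mats["Lambda"], mats["B"], mats["Psi"], mats["Theta"]

    # -- validation ---------------------------------------------------------

    def validate(self, strict: bool = True) -> list[str]:
        """Check structural invariants; returns warnings, raises on hard errors."""
        warnings: list[str] = []
        for i in range(self.m):
            for j in range(i):
                if self.Psi[i, j] is not self.Psi[j, i]:
                    raise ModelError("Psi symmetry broken (use set_psi)")
        for i in range(self.p):
            for j in range(i):
                if self.Theta[i, j] is not self.Theta[j, i]:
                    raise ModelError("Theta symmetry broken (use set_theta)")
        for i in range(self.p):
            cell = self.Theta[i, i]
            if cell.status == FIXED and cell.value is not None and cell.value < 0:
                raise ModelError(
                    f"negative fixed error variance on {self.indicator_names[i]}"
                )
        for j in range(self.m):
            cell = self.Psi[j, j]
            if cell.status == FIXED and cell.value is not None and cell.value < 0:
                raise ModelError(f"negative fixed variance for latent {self.latent_names[j]}")
        # each latent needs a scale: a fixed nonzero loading or a fixed variance
        for j, name in enumerate(self.latent_names):
            fixed_loads = [
                i
                for i in range(self.p)
                if self.Lambda[i, j].status == FIXED
                and self.Lambda[i, j].value not in (None, 0.0)
            ]
            # a fixed disturbance variance (even zero, for fully-determined
            # latents) pins the latent's scale
            psi_fixed = self.Psi[j, j].status == FIXED and self.Psi[j, j].value is not None
            if not fixed_loads and not psi_fixed:
                raise ModelError(f"latent {name!r} has no scale "
                                 "(no fixed nonzero loading and no fixed variance)")
            if len(fixed_loads) > 1:
                warnings.append(
                    f"latent {name!r} has {len(fixed_loads)} fixed nonzero loadings; "
                    "one designated scaling indicator is the convention"
                )
        for i, name in enumerate(self.indicator_names):
            if all(
                self.Lambda[i, j].status == FIXED and not self.Lambda[i, j].value
                for j in range(self.m)
            ):
                warnings.append(f"indicator {name!r} loads on no latent (disconnected)")
        if strict:
            # (I - B) invertibility at starting/fixed values is only a coarse
            # screen here; fit-time code re-checks at every evaluation.
            try:
                _, B, _, _ = self.materialize(np.zeros(len(self.free_parameters())))
                if abs(np.linalg.det(np.eye(self.m) - B)) < 1e-12:
                    warnings.append("(I - B) is singular at zero free values")
            except ModelError:
                pass
        return warnings


# ---------------------------------------------------------------------------
# Degrees-of-freedom audit
# ---------------------------------------------------------------------------


@dataclass
class DfAudit:
    n_moments: int
    n_free: int
    df: int
    breakdown: dict
    under_determined: bool = False

    def __str__(self) -> str:  # pragma: no cover - formatting
        parts = ", ".join(f"{k}={v}" for k, v in self.breakdown.items())
        tail = "  [UNDER-DETERMINED]" if self.under_determined else ""
        return (
            f"moments={self.n_moments}  free={self.n_free} ({parts})  df={self.df}{tail}"
        )


def count_df(model: SemModel) -> DfAudit:
    """Data moments p(p+1)/2 minus distinct free parameters.

    Equality-labeled cells count once per label.  A negative df is reported
    with ``under_determined=True`` rather than raised.
    """
    p = model.p
    n_moments = p * (p + 1) // 2
    params = model.free_parameters()
    breakdown = {"Lambda": 0, "B": 0, "Psi": 0, "Theta": 0}
    for fp in params:
        breakdown[fp.matrix] += 1
    n_free = len(params)
    df = n_moments - n_free
    return DfAudit(n_moments, n_free, df, breakdown, under_determined=df < 0)


# ---------------------------------------------------------------------------
# Empirical identification screening
# ---------------------------------------------------------------------------


@dataclass
class IdentificationReport:
    zero_variance: list
    redundant_pairs: list  # (name_a, name_b, correlation)
    disconnected: list  # names structurally disconnected from the main graph
    rank_deficient: bool
    jacobian_rank: int
    n_free: int
    notes: list = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return (
            not self.zero_variance
            and not self.redundant_pairs
            and not self.disconnected
            and not self.rank_deficient
        )


def _structure_graph(model: SemModel) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(model.latent_names)
    g.add_nodes_from(model.indicator_names)

    def active(cell: ParamCell) -> bool:
        return cell.is_free or (cell.value not in (None, 0.0)) or cell.pct is not None

    for i in range(model.p):
        for j in range(model.m):
            if active(model.Lambda[i, j]):
                g.add_edge(model.indicator_names[i], model.latent_names[j])
    for i in range(model.m):
        for j in range(model.m):
            if i != j and active(model.B[i, j]):
                g.add_edge(model.latent_names[i], model.latent_names[j])
    for i in range(model.m):
        for j in range(i):
            if active(model.Psi[i, j]):
                g.add_edge(model.latent_names[i], model.latent_names[j])
    for i in range(model.p):
        for j in range(i):
            if active(model.Theta[i, j]):
                g.add_edge(model.indicator_names[i], model.indicator_names[j])
    return g


def check_empirical_identification(model, moments, tol: float = 1e-8) -> IdentificationReport:
    """Screen for data-driven identification failures.

    Flags zero-variance indicators, indicator pairs correlated to within
    ``tol`` of +-1 (redundant), structurally disconnected variables, and
    numerical rank deficiency of the implied-moment Jacobian at starting
    values (local underidentification).
    """
    from .estimate import SampleMoments  # cycle-free: estimate imports nothing here at import time

    if isinstance(moments, SampleMoments):
        S = moments.S
    else:
        S = np.asarray(moments, dtype=float)
    if S.shape != (model.p, model.p):
        raise ModelError(
            f"covariance matrix is {S.shape}, model has p={model.p} indicators"
        )

    d = np.sqrt(np.clip(np.diag(S), 0.0, None))
    zero_variance = [model.indicator_names[i] for i in range(model.p) if d[i] <= tol]

    redundant = []
    for i in range(model.p):
        for j in range(i):
            if d[i] <= tol or d[j] <= tol:
                continue
            r = S[i, j] / (d[i] * d[j])
            if abs(r) >= 1.0 - tol:
                redundant.append((model.indicator_names[j], model.indicator_names[i], float(r)))

    g = _structure_graph(model)
    disconnected = []
    if g.number_of_nodes() > 0:
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        for comp in comps[1:]:
            disconnected.extend(sorted(comp))

    # Jacobian of the implied-moment map at starting values
    from .estimate import _default_starts
    from .algebra import implied_covariance_jacobian

    resolved = model.resolve_fixed_pct(S)
    params = resolved.free_parameters()
    rank_deficient = False
    rank = 0
    notes: list[str] = []
    if params:
        theta0 = _default_starts(resolved, S)
        try:
            J = implied_covariance_jacobian(resolved, theta0)
            rank = int(np.linalg.matrix_rank(J, tol=1e-8 * max(1.0, np.abs(J).max())))
            rank_deficient = rank < len(params)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            rank_deficient = True
            notes.append("Jacobian could not be evaluated at starting values")
    return IdentificationReport(
        zero_variance, redundant, disconnected, rank_deficient, rank, len(params), notes
    )


# ---------------------------------------------------------------------------
# Model grammar: parser and serializer
# ---------------------------------------------------------------------------

_FLOAT = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"


def _parse_status(tokens: list[str], line: int, kind: str):
    """Parse trailing status tokens -> ParamCell (without label)."""
    if not tokens:
        raise ModelSyntaxError(f"missing FIXED/FREE status for {kind}", line)
    head = tokens[0].upper()
    if head == "FIXED":
        if len(tokens) != 2 or not re.fullmatch(_FLOAT, tokens[1]):
            raise ModelSyntaxError("FIXED requires one numeric value", line)
        return ParamCell(FIXED, float(tokens[1]))
    if head == "FIXED_PCT":
        if len(tokens) != 2 or not re.fullmatch(_FLOAT, tokens[1]):
            raise ModelSyntaxError("FIXED_PCT requires one numeric percent", line)
        pct = float(tokens[1])
        if not 0.0 <= pct <= 100.0:
            raise ModelSyntaxError("FIXED_PCT percent must be in [0, 100]", line)
        return ParamCell(FIXED, None, pct=pct)
    if head == "FREE":
        if len(tokens) == 1:
            return ParamCell(FREE, None)
        if len(tokens) == 3 and tokens[1].upper() == "START" and re.fullmatch(_FLOAT, tokens[2]):
            return ParamCell(FREE, float(tokens[2]))
        raise ModelSyntaxError("FREE takes optionally START <value>", line)
    raise ModelSyntaxError(f"expected FIXED/FIXED_PCT/FREE, got {tokens[0]!r}", line)


def parse_model(text: str) -> SemModel:
    """Parse the plain-text model grammar into a validated :class:`SemModel`.

    Grammar (one declaration per line, ``#`` starts a comment)::

        LATENT eta1 eta2 ...
        INDICATOR y1 y2 ...
        LOAD <indicator> <latent> FIXED <v> | FREE [START <v>]
        ERRVAR <indicator> FIXED <v> | FIXED_PCT <pct> | FREE [START <v>]
        ERRCOV <ind1> <ind2> FREE [START <v>] | FIXED <v>
        EFFECT <source> <target> FREE [START <v>] | FIXED <v>
        PSI <latent1> <latent2> FREE [START <v>] | FIXED <v>
        EQ <label> <SPEC> ; <SPEC> ; ...     where SPEC in {LOAD y eta,
            EFFECT a b, ERRVAR y, PSI a b}

    Undeclared Psi and Theta diagonals default to free; all other undeclared
    cells are fixed at zero.
    """
    latents: list[str] = []
    indicators: list[str] = []
    decls: list[tuple] = []  # (lineno, kind, args, cell-or-label-spec)
    declared: set = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kw = tokens[0].upper()
        if kw == "LATENT":
            if len(tokens) < 2:
                raise ModelSyntaxError("LATENT needs at least one name", lineno)
            for name in tokens[1:]:
                if name in latents:
                    raise ModelSyntaxError(f"duplicate latent {name!r}", lineno)
                latents.append(name)
        elif kw == "INDICATOR":
            if len(tokens) < 2:
                raise ModelSyntaxError("INDICATOR needs at least one name", lineno)
            for name in tokens[1:]:
                if name in indicators:
                    raise ModelSyntaxError(f"duplicate indicator {name!r}", lineno)
                indicators.append(name)
        elif kw in ("LOAD", "ERRCOV", "EFFECT", "PSI"):
            if len(tokens) < 3:
                raise ModelSyntaxError(f"{kw} needs two names", lineno)
            cell = _parse_status(tokens[3:], lineno, kw)
            decls.append((lineno, kw, (tokens[1], tokens[2]), cell))
        elif kw == "ERRVAR":
            if len(tokens) < 2:
                raise ModelSyntaxError("ERRVAR needs an indicator name", lineno)
            cell = _parse_status(tokens[2:], lineno, kw)
            decls.append((lineno, kw, (tokens[1],), cell))
        elif kw == "EQ":
            if len(tokens) < 3:
                raise ModelSyntaxError("EQ needs a label and cell specs", lineno)
            label = tokens[1]
            specs = [s.split() for s in " ".join(tokens[2:]).split(";")]
            decls.append((lineno, "EQ", label, specs))
        else:
            raise ModelSyntaxError(f"unknown keyword {tokens[0]!r}", lineno)

    if not latents:
        raise ModelSyntaxError("no LATENT declaration", 1)
    if not indicators:
        raise ModelSyntaxError("no INDICATOR declaration", 1)
    model = SemModel(latents, indicators)

    def require(name: str, pool: list[str], kind: str, lineno: int) -> None:
        if name not in pool:
            raise ModelSyntaxError(f"unknown {kind} {name!r}", lineno)

    for lineno, kw, args, payload in decls:
        if kw == "EQ":
            label, specs = args, payload
            for spec in specs:
                if not spec:
                    raise ModelSyntaxError("empty cell spec in EQ", lineno)
                skw = spec[0].upper()
                try:
                    if skw == "LOAD" and len(spec) == 3:
                        cur = model.get_loading(spec[1], spec[2])
                        cell = ParamCell(FREE, cur.value if cur.is_free else None, label)
                        model.set_loading(spec[1], spec[2], cell)
                    elif skw == "EFFECT" and len(spec) == 3:
                        cur = model.get_effect(spec[1], spec[2])
                        cell = ParamCell(FREE, cur.value if cur.is_free else None, label)
                        model.set_effect(spec[1], spec[2], cell)
                    elif skw == "ERRVAR" and len(spec) == 2:
                        cur = model.get_theta(spec[1], spec[1])
                        cell = ParamCell(FREE, cur.value if cur.is_free else None, label)
                        model.set_theta(spec[1], spec[1], cell)
                    elif skw == "PSI" and len(spec) == 3:
                        cur = model.get_psi(spec[1], spec[2])
                        cell = ParamCell(FREE, cur.value if cur.is_free else None, label)
                        model.set_psi(spec[1], spec[2], cell)
                    else:
                        raise ModelSyntaxError(f"bad EQ cell spec {' '.join(spec)!r}", lineno)
                except ModelError as e:
                    if isinstance(e, ModelSyntaxError):
                        raise
                    raise ModelSyntaxError(str(e), lineno) from None
            continue
        if kw == "LOAD":
            require(args[0], indicators, "indicator", lineno)
            require(args[1], latents, "latent", lineno)
            key = ("Lambda", args[0], args[1])
        elif kw == "ERRVAR":
            require(args[0], indicators, "indicator", lineno)
            key = ("Theta", args[0], args[0])
        elif kw == "ERRCOV":
            require(args[0], indicators, "indicator", lineno)
            require(args[1], indicators, "indicator", lineno)
            if args[0] == args[1]:
                raise ModelSyntaxError("ERRCOV needs two distinct indicators", lineno)
            key = ("Theta",) + tuple(sorted(args))
        elif kw == "EFFECT":
            require(args[0], latents, "latent", lineno)
            require(args[1], latents, "latent", lineno)
            key = ("B", args[0], args[1])
        elif kw == "PSI":
            require(args[0], latents, "latent", lineno)
            require(args[1], latents, "latent", lineno)
            key = ("Psi",) + tuple(sorted(args))
        if key in declared:
            raise ModelSyntaxError(f"duplicate declaration for {kw} {' '.join(args)}", lineno)
        declared.add(key)
        try:
            if kw == "LOAD":
                model.set_loading(args[0], args[1], payload)
            elif kw == "ERRVAR":
                model.set_theta(args[0], args[0], payload)
            elif kw == "ERRCOV":
                model.set_theta(args[0], args[1], payload)
            elif kw == "EFFECT":
                model.set_effect(args[0], args[1], payload)
            elif kw == "PSI":
                model.set_psi(args[0], args[1], payload)
        except ModelError as e:
            raise ModelSyntaxError(str(e), lineno) from None

    # defaults: undeclared variances are free
    for j, name in enumerate(latents):
        if ("Psi", name, name) not in declared and not model.Psi[j, j].is_free:
            if model.Psi[j, j].value == 0.0 and model.Psi[j, j].pct is None:
                model.set_psi(name, name, ParamCell(FREE, None))
    for i, name in enumerate(indicators):
        if ("Theta", name, name) not in declared and not model.Theta[i, i].is_free:
            if model.Theta[i, i].value == 0.0 and model.Theta[i, i].pct is None:
                model.set_theta(name, name, ParamCell(FREE, None))

    model.validate(strict=False)
    return model


def _format_cell(cell: ParamCell) -> str:
    if cell.status == FIXED:
        if cell.pct is not None:
            return f"FIXED_PCT {cell.pct:g}"
        return f"FIXED {cell.value:g}"
    if cell.value is None:
        return "FREE"
    return f"FREE START {cell.value:g}"


def serialize_model(model: SemModel) -> str:
    """Write a model back to the grammar; ``parse_model`` round-trips it."""
    out = _io.StringIO()
    out.write("LATENT " + " ".join(model.latent_names) + "\n")
    out.write("INDICATOR " + " ".join(model.indicator_names) + "\n")
    eq_groups: dict[str, list[str]] = {}

    def emit(keyword: str, names: list[str], cell: ParamCell, eq_spec: str) -> None:
        if cell.label is not None:
            eq_groups.setdefault(cell.label, []).append(eq_spec)
            if cell.value is not None:
                out.write(f"{keyword} {' '.join(names)} FREE START {cell.value:g}\n")
            return
        out.write(f"{keyword} {' '.join(names)} {_format_cell(cell)}\n")

    for i, y in enumerate(model.indicator_names):
        for j, eta in enumerate(model.latent_names):
            cell = model.Lambda[i, j]
            if cell.is_free or cell.value not in (None, 0.0) or cell.pct is not None:
                emit("LOAD", [y, eta], cell, f"LOAD {y} {eta}")
    for jt, tgt in enumerate(model.latent_names):
        for js, src in enumerate(model.latent_names):
            cell = model.B[jt, js]
            if cell.is_free or cell.value not in (None, 0.0):
                emit("EFFECT", [src, tgt], cell, f"EFFECT {src} {tgt}")
    for i, a in enumerate(model.latent_names):
        for j in range(i + 1):
            b = model.latent_names[j]
            cell = model.Psi[i, j]
            if cell.is_free or cell.value not in (None, 0.0):
                emit("PSI", [b, a], cell, f"PSI {b} {a}")
    for i, a in enumerate(model.indicator_names):
        cell = model.Theta[i, i]
        if cell.is_free or cell.value not in (None, 0.0) or cell.pct is not None:
            emit("ERRVAR", [a], cell, f"ERRVAR {a}")
    for i, a in enumerate(model.indicator_names):
        for j in range(i):
            b = model.indicator_names[j]
            cell = model.Theta[i, j]
            if cell.is_free or cell.value not in (None, 0.0):
                emit("ERRCOV", [b, a], cell, f"ERRCOV {b} {a}")
    for label, specs in eq_groups.items():
        out.write(f"EQ {label} " + " ; ".join(specs) + "\n")
    return out.getvalue()
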