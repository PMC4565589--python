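"""Biological function model files in a compact line-oriented dialect.

A model file declares its dimensions, its variables with their roles, and one
equation per line::

    dim t x
    var V diff 0.0 mV
    var I arith
    var J arith
    var D const 1.0
    var C dist
    d(V)/d(t) = -I
    I = J + D * d2(V)/d(x)2
    J = piecewise(0 <= t <= 10: C, otherwise: 0)

Roles: ``diff`` (differential variable, advanced in time), ``arith``
(algebraic/arithmetic variable), ``const`` (scalar constant), ``dist``
(distributed parameter — nominally constant but varying by grid location).
The optional third field of a ``var`` line is the initial value (for ``diff``)
or the constant's value (for ``const``); the optional fourth is an opaque
unit string, carried but never checked.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .expressions import (
    Deriv,
    Expr,
    ExpressionError,
    Var,
    free_variables,
    parse_expression,
    to_text,
    walk,
)

ROLES = ("diff", "arith", "const", "dist")


class ModelError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class VariableDecl:
    name: str
    role: str  # one of ROLES
    init: Optional[float] = None
    unit: str = ""


@dataclass(frozen=True)
class Equation:
    lhs: Expr
    rhs: Expr
    label: str = ""


@dataclass(frozen=True)
class ModelDefinition:
    variables: Tuple[VariableDecl, ...]
    equations: Tuple[Equation, ...]
    dims: Tuple[str, ...]  # time dimension first, then space

    def var(self, name: str) -> VariableDecl:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def roles(self) -> dict:
        return {v.name: v.role for v in self.variables}

    def by_role(self, role: str) -> Tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == role)

    @property
    def time_dim(self) -> str:
        return self.dims[0]

    @property
    def space_dims(self) -> Tuple[str, ...]:
        return self.dims[1:]


def _strip(line: str) -> str:
    if "#" in line:
        line = line[: line.index("#")]
    return line.strip()


def parse_model(text: str) -> ModelDefinition:
    """Parse model source; raises :class:`ModelError` with a line number on
    syntax errors, undeclared variables, or duplicate definitions."""
    if not text or not text.strip():
        raise ModelError("empty model source")

    dims: Tuple[str, ...] = ()
    variables = []
    names = set()
    equations = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip(raw)
        if not line:
            continue
        head = line.split()[0]
        if head == "dim":
            if dims:
                raise ModelError("duplicate 'dim' declaration", lineno)
            dims = tuple(line.split()[1:])
            if len(dims) < 1:
                raise ModelError("'dim' needs at least a time dimension", lineno)
            if len(dims) != len(set(dims)):
                raise ModelError("dimension symbols must be unique", lineno)
        elif head == "var":
            parts = line.split()
            if len(parts) < 3:
                raise ModelError("var line needs: var NAME ROLE [init] [unit]", lineno)
            _, name, role, *rest = parts
            if role not in ROLES:
                raise ModelError(f"unknown role {role!r} (expected one of {ROLES})", lineno)
            if name in names:
                raise ModelError(f"duplicate declaration of {name!r}", lineno)
            init = None
            unit = ""
            if rest:
                try:
                    init = float(rest[0])
                    rest = rest[1:]
                except ValueError:
                    pass
                if rest:
                    unit = rest[0]
            names.add(name)
            variables.append(VariableDecl(name, role, init, unit))
        elif "=" in line:
            lhs_text, _, rhs_text = line.partition("=")
            try:
                lhs = parse_expression(lhs_text, lineno)
                rhs = parse_expression(rhs_text, lineno)
            except ExpressionError as exc:
                raise ModelError(f"syntax error: {exc}", lineno) from exc
            equations.append((lineno, Equation(lhs, rhs)))
        else:
            raise ModelError(f"unrecognized line: {raw.strip()!r}", lineno)

    if not dims:
        raise ModelError("missing 'dim' declaration")
    if not equations:
        raise ModelError("model contains no equations")

    declared = names | set(dims)
    labeled = []
    diff_lhs_seen = {}
    for lineno, eq in equations:
        for nm in free_variables(eq.lhs) | free_variables(eq.rhs):
            if nm not in declared:
                raise ModelError(f"undeclared variable {nm!r}", lineno)
        label, target = _classify_lhs(eq, dims, {v.name: v for v in variables}, lineno)
        if target is not None:
            if target in diff_lhs_seen:
                raise ModelError(
                    f"duplicate time-derivative equation for {target!r}", lineno
                )
            diff_lhs_seen[target] = lineno
        labeled.append(Equation(eq.lhs, eq.rhs, label))

    for v in variables:
        if v.role == "diff" and v.name not in diff_lhs_seen:
            raise ModelError(
                f"differential variable {v.name!r} has no d({v.name})/d({dims[0]}) equation"
            )

    model = ModelDefinition(tuple(variables), tuple(labeled), dims)
    _validate(model)
    return model


def _classify_lhs(eq: Equation, dims, vars_by_name, lineno):
    """The LHS of a model equation is either a single first-order time
    derivative of one differential variable, or a bare variable."""
    lhs = eq.lhs
    if isinstance(lhs, Deriv):
        if not isinstance(lhs.arg, Var) or lhs.arg.indices is not None:
            raise ModelError("time-derivative LHS must wrap a bare variable", lineno)
        if lhs.dim != dims[0] or lhs.order != 1:
            raise ModelError(
                "model LHS derivatives must be first-order in time", lineno
            )
        name = lhs.arg.name
        decl = vars_by_name.get(name)
        if decl is None or decl.role != "diff":
            raise ModelError(
                f"{name!r} has a time-derivative equation but is not declared 'diff'",
                lineno,
            )
        return f"eq_{name}", name
    if isinstance(lhs, Var) and lhs.indices is None:
        return f"eq_{lhs.name}", None
    raise ModelError("equation LHS must be d(V)/d(t) or a bare variable", lineno)


def _validate(model: ModelDefinition) -> None:
    for eq in model.equations:
        for node in walk(eq.rhs):
            if isinstance(node, Deriv) and node.dim not in model.dims:
                raise ModelError(
                    f"derivative with respect to undeclared dimension {node.dim!r}"
                )


def serialize_model(model: ModelDefinition) -> str:
    """Canonical textual form; ``parse_model(serialize_model(m)) == m``."""
    lines = ["dim " + " ".join(model.dims)]
    for v in model.variables:
        parts = ["var", v.name, v.role]
        if v.init is not None:
            iv = v.init
            parts.append(str(int(iv)) if iv == int(iv) else repr(iv))
        if v.unit:
            parts.append(v.unit)
        lines.append(" ".join(parts))
    for eq in model.equations:
        lines.append(f"{to_text(eq.lhs)} = {to_text(eq.rhs)}")
    return "\n".join(lines) + "\n"
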