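"""The replacement engine: continuous equations → discrete index templates.

Discretization proceeds by substitution in a fixed order — arithmetic
variables first, then differential variables, then differential operators —
so an operator rule always sees an already-indexed argument and can shift its
time and space indices to build the stencil.  Model variable names are
retained: the scheme's generic symbols appear only inside the scheme
description, never in the discretized output.

Variable replacement gives every arithmetic and differential variable the
full index tuple (time level n, base spatial indices); distributed parameters
get spatially-indexed, time-free references (``C`` → ``C[j]``); scalar
constants stay bare.  Operator replacement consumes each partial-derivative
node and substitutes the scheme's stencil with all index offsets applied
relative to the argument's indices.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .expressions import (
    Deriv,
    Expr,
    Idx,
    Num,
    Var,
    map_children,
    to_text,
    walk,
)
from .model import Equation, ModelDefinition
from .relation import BoundaryDecl, RelationMap
from .schemes import BoundaryRule, SchemeError, SchemeSpec


class DiscretizationError(ValueError):
    pass


@dataclass(frozen=True)
class DiscreteEquation:
    """A discrete equation template over symbolic indices.

    Index entries are (index variable ± integer offset); no derivative
    operators remain.  ``time_shift`` records whether level n+1 is referenced
    anywhere.  ``provenance`` names the source equation and scheme.
    """

    lhs: Expr
    rhs: Expr
    label: str
    scheme: str
    time_shift: bool

    def text(self) -> str:
        return f"{to_text(self.lhs)} = {to_text(self.rhs)}"


@dataclass(frozen=True)
class BoundaryEquation:
    """A discrete boundary equation template, tagged with its boundary ID,
    time level and anchor ('material' node adjacent to the ghost, or the
    'ghost' node itself)."""

    bid: int
    level: int
    anchor: str
    equation: DiscreteEquation
    decl: BoundaryDecl


def _references_np1(e: Expr, time_sym: str) -> bool:
    for node in walk(e):
        if isinstance(node, Var) and node.indices:
            t0 = node.indices[0]
            if isinstance(t0, Idx) and t0.base == time_sym and t0.offset >= 1:
                return True
    return False


# ---------------------------------------------------------------------------
# variable replacement
# ---------------------------------------------------------------------------

def _base_indices(scheme: SchemeSpec) -> Tuple[Idx, ...]:
    return tuple(Idx(s, 0) for s in scheme.indices)


def _replace_role(e: Expr, names, indices) -> Expr:
    def go(node):
        if isinstance(node, Var) and node.indices is None and node.name in names:
            return Var(node.name, indices)
        return map_children(node, go)

    return go(e)


def replace_variables(e: Expr, roles: Dict[str, str], scheme: SchemeSpec) -> Expr:
    """Apply the variable replacement: arithmetic first, then differential,
    then distributed parameters (spatial indices only)."""
    arith = {n for n, r in roles.items() if r == "arithvar"}
    diff = {n for n, r in roles.items() if r == "diffvar"}
    dist = {n for n, r in roles.items() if r == "distributed"}
    base = _base_indices(scheme)
    e = _replace_role(e, arith, base)
    e = _replace_role(e, diff, base)
    e = _replace_role(e, dist, base[1:])
    return e


# ---------------------------------------------------------------------------
# operator replacement
# ---------------------------------------------------------------------------

def _shift_var(var: Var, time_off: int, dim_pos: int, space_off: int) -> Var:
    idx = list(var.indices)
    t = idx[0]
    if not isinstance(t, Idx):
        raise DiscretizationError(f"cannot shift a concrete time index in {var}")
    idx[0] = Idx(t.base, t.offset + time_off)
    if space_off:
        s = idx[dim_pos]
        if isinstance(s, Idx):
            idx[dim_pos] = Idx(s.base, s.offset + space_off)
        else:
            idx[dim_pos] = s + space_off
    return Var(var.name, tuple(idx))


def _apply_stencil(rule: Expr, arg: Var, scheme: SchemeSpec, dim_pos: int) -> Expr:
    """Instantiate an operator rule for a concrete argument.

    Each ``v[...]`` in the rule carries a time offset and (for spatial rules)
    an offset on its own dimension's index variable; both are applied to the
    argument's indices.  Delta symbols pass through unchanged.
    """
    active = scheme.indices[dim_pos] if dim_pos > 0 else None
    tsym = scheme.time_index

    def go(node):
        if isinstance(node, Var) and node.name == scheme.diff_sym and node.indices:
            t_off = 0
            s_off = 0
            for ix in node.indices:
                if isinstance(ix, Idx):
                    if ix.base == tsym:
                        t_off = ix.offset
                    elif active is not None and ix.base == active:
                        s_off = ix.offset
            return _shift_var(arg, t_off, dim_pos, s_off)
        return map_children(node, go)

    return go(rule)


def replace_operators(e: Expr, model: ModelDefinition, scheme: SchemeSpec) -> Expr:
    def go(node):
        node = map_children(node, go)
        if isinstance(node, Deriv):
            if node.direction is not None:
                raise DiscretizationError(
                    "one-sided derivatives appear only in boundary templates"
                )
            if node.dim not in model.dims:
                raise DiscretizationError(f"unknown dimension {node.dim!r}")
            dim_pos = model.dims.index(node.dim)
            if dim_pos >= len(scheme.dims):
                raise DiscretizationError(
                    f"model dimension {node.dim!r} exceeds the scheme's "
                    f"{scheme.ndim} spatial dimension(s)"
                )
            if not isinstance(node.arg, Var) or node.arg.indices is None:
                raise DiscretizationError(
                    f"derivative argument must be a single differential variable, "
                    f"got {to_text(node.arg)!r}"
                )
            try:
                rule = scheme.operator_rule(node.order, dim_pos)
            except SchemeError as exc:
                raise DiscretizationError(str(exc)) from exc
            return _apply_stencil(rule, node.arg, scheme, dim_pos)
        return node

    return go(e)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def discretize_equation(
    eq: Equation, scheme: SchemeSpec, rel: RelationMap, dims: Sequence[str]
) -> DiscreteEquation:
    """Discretize one equation given the model's dimension list (time first):
    R_f⟦equ⟧ = R_o⟦R_v⟦R_y⟦equ⟧⟧⟧ — arithmetic variables first, differential
    variables second, differential operators last."""

    class _Dims:  # minimal carrier for replace_operators
        pass

    m = _Dims()
    m.dims = tuple(dims)
    return discretize_model_equation(eq, m, scheme, rel)


def discretize_model_equation(
    eq: Equation, model, scheme: SchemeSpec, rel: RelationMap
) -> DiscreteEquation:
    roles = {name: rel.scheme_type(name) for name in rel.mapping}
    lhs = replace_variables(eq.lhs, roles, scheme)
    rhs = replace_variables(eq.rhs, roles, scheme)
    lhs = replace_operators(lhs, model, scheme)
    rhs = replace_operators(rhs, model, scheme)
    for side in (lhs, rhs):
        for node in walk(side):
            if isinstance(node, Deriv):
                raise DiscretizationError(
                    f"residual derivative after discretization in {eq.label!r}"
                )
    shift = _references_np1(lhs, scheme.time_index) or _references_np1(rhs, scheme.time_index)
    return DiscreteEquation(lhs, rhs, eq.label, scheme.name, shift)


def discretize_model(
    model: ModelDefinition, scheme: SchemeSpec, rel: RelationMap
) -> List[DiscreteEquation]:
    if len(model.space_dims) != scheme.ndim:
        raise DiscretizationError(
            f"model has {len(model.space_dims)} spatial dimension(s) but the "
            f"scheme is {scheme.ndim}-dimensional"
        )
    return [discretize_model_equation(eq, model, scheme, rel) for eq in model.equations]


def discretize_boundary(
    decl: BoundaryDecl, scheme: SchemeSpec, dim_pos: int, direction: str
) -> List[BoundaryEquation]:
    """Discretize one boundary declaration for one (dimension, direction).

    Returns one template per time level the scheme requires; Dirichlet yields
    value clamps, Neumann a one-sided first difference.  ``dim_pos`` is the
    1-based spatial dimension.
    """
    rule = scheme.boundary_rule(direction, decl.condition, dim_pos)
    out = []
    for tpl in rule.templates:
        lhs = _bind_boundary(tpl.lhs, decl, scheme)
        rhs = _bind_boundary(tpl.rhs, decl, scheme)
        deq = DiscreteEquation(
            lhs, rhs,
            label=f"{decl.condition}_{scheme.dims[dim_pos]}{direction}",
            scheme=scheme.name,
            time_shift=(tpl.level == 1),
        )
        out.append(BoundaryEquation(rule.bid, tpl.level, tpl.anchor, deq, decl))
    return out


def _bind_boundary(e: Expr, decl: BoundaryDecl, scheme: SchemeSpec) -> Expr:
    """Substitute the model variable for the scheme's generic diffvar symbol
    and the declared value for ``bval``; generic indices are kept."""

    def go(node):
        if isinstance(node, Var):
            if node.name == scheme.diff_sym:
                return Var(decl.var, node.indices)
            if node.name == "bval" and node.indices is None:
                return decl.value
        return map_children(node, go)

    return go(e)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityReport:
    passed: bool
    dt: float
    bound: float
    printed_form_bound: float
    message: str


def check_stability(scheme: SchemeSpec, dt: float, dx: float, D: float, d: int) -> StabilityReport:
    """Diffusion CFL check for explicit schemes: Δt ≤ (Δx)²/(2·d·D).

    The check warns, never aborts.  The report also quotes the commonly
    printed first-power form Δx/(2·d·D) for traceability; the implemented
    bound uses (Δx)², the dimensionally consistent criterion for a diffusion
    operator discretized with second-order central differences.
    """
    if scheme.implicit or D == 0:
        return StabilityReport(True, dt, float("inf"), float("inf"),
                               "unconditionally acceptable (implicit scheme or D = 0)")
    bound = dx * dx / (2.0 * d * D)
    printed = dx / (2.0 * d * D)
    passed = dt <= bound
    msg = (
        f"dt = {dt} vs implemented bound (dx)^2/(2 d D) = {bound} "
        f"(first-power form dx/(2 d D) = {printed}): "
        + ("stable" if passed else "explicit diffusion step may be unstable")
    )
    return StabilityReport(passed, dt, bound, printed, msg)
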