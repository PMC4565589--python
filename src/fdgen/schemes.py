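"""Declarative single-step finite-difference scheme descriptions.

A scheme binds the generic variable-type symbols (``v`` differential, ``y``
arithmetic, ``z`` constant) to discrete replacement rules: how an indexed
variable reference looks, how each differential operator turns into a stencil,
and how each kind of boundary condition is discretized on each side of each
spatial dimension.  Built-in constructors provide the classic single-step
schemes — explicit FTCS, fully-implicit BTCS, and Crank–Nicolson — in one to
three space dimensions; user schemes are parsed from the same structured text
format the built-ins serialize to, so they are first-class.

Conventions used in rule templates:

* index symbols are ``n`` (time) and ``j``, ``k``, ``l`` (space);
* a spatial operator rule is written in its own dimension's index variable,
  and its stencil may shift only that index and the time index;
* boundary rules are anchored at the *material* node adjacent to the boundary
  (ghost) node, so a left-side rule reaches the ghost via ``j-1`` and a
  right-side rule via ``j+1``;
* ``bval`` is the placeholder for the declared boundary value.

To keep the generic symbols collision-free, the spatial dimensions beyond
``x`` are named ``y2`` and ``z2`` (``y``/``z`` are taken by the variable-type
symbols), with deltas ``dt``, ``dx``, ``dy2``, ``dz2``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .expressions import (
    BinOp,
    Deriv,
    Expr,
    ExpressionError,
    Idx,
    Num,
    Var,
    div,
    mul,
    parse_expression,
    sub,
    to_text,
    walk,
)

DIM_SYMBOLS = ("t", "x", "y2", "z2")
INDEX_SYMBOLS = ("n", "j", "k", "l")
DELTA_SYMBOLS = ("dt", "dx", "dy2", "dz2")

CONDITIONS = ("dirichlet", "neumann")
DIRECTIONS = ("-", "+")


class SchemeError(ValueError):
    pass


def boundary_id(dim_pos: int, direction: str, condition: str) -> int:
    """Encode a boundary rule key as a positive integer.

    ``dim_pos`` is the 1-based spatial dimension index (1=x, 2=y2, 3=z2);
    the direction bit is 0 for '-' (boundary on the low side of the tissue)
    and 1 for '+'; the condition bit is 0 for Dirichlet and 1 for Neumann.
    """
    return dim_pos * 4 + (0 if direction == "-" else 2) + (0 if condition == "dirichlet" else 1)


def decode_boundary_id(bid: int) -> Tuple[int, str, str]:
    dim_pos, rem = divmod(bid, 4)
    if dim_pos < 1 or dim_pos > 3:
        raise SchemeError(f"bad boundary ID {bid}")
    direction = "-" if rem < 2 else "+"
    condition = "dirichlet" if rem % 2 == 0 else "neumann"
    return dim_pos, direction, condition


@dataclass(frozen=True)
class BoundaryTemplate:
    """One discrete equation emitted for a boundary node.

    ``level`` is the time level (0 = n, 1 = n+1) and ``anchor`` says whether
    the template's base index is the material node next to the ghost
    (``material``) or the ghost node itself (``ghost``).
    """

    level: int
    anchor: str  # 'material' | 'ghost'
    lhs: Expr
    rhs: Expr


@dataclass(frozen=True)
class BoundaryRule:
    bid: int
    dim_pos: int  # 1-based spatial dimension
    direction: str
    condition: str
    continuous: Tuple[Expr, Expr]  # (lhs, rhs) of the continuous condition
    templates: Tuple[BoundaryTemplate, ...]


@dataclass(frozen=True)
class SchemeSpec:
    name: str
    ndim: int  # number of *spatial* dimensions
    implicit: bool
    diff_sym: str = "v"
    arith_sym: str = "y"
    const_sym: str = "z"
    dims: Tuple[str, ...] = ()      # time first
    indices: Tuple[str, ...] = ()   # one per dimension, time first
    deltas: Tuple[str, ...] = ()    # one per dimension, time first
    var_rules: Dict[str, Expr] = field(default_factory=dict)
    # (order, 1-based spatial dim or 0 for time) -> stencil expression
    op_rules: Dict[Tuple[int, int], Expr] = field(default_factory=dict)
    boundary_rules: Dict[int, BoundaryRule] = field(default_factory=dict)

    @property
    def time_index(self) -> str:
        return self.indices[0]

    def space_index(self, dim_pos: int) -> str:
        return self.indices[dim_pos]

    def delta(self, dim_pos: int) -> str:
        return self.deltas[dim_pos]

    def operator_rule(self, order: int, dim_pos: int) -> Expr:
        try:
            return self.op_rules[(order, dim_pos)]
        except KeyError:
            raise SchemeError(
                f"scheme {self.name!r} has no rule for an order-{order} derivative "
                f"in dimension {self.dims[dim_pos]!r}"
            ) from None

    def boundary_rule(self, direction: str, condition: str, dim_pos: int) -> BoundaryRule:
        bid = boundary_id(dim_pos, direction, condition)
        try:
            return self.boundary_rules[bid]
        except KeyError:
            raise SchemeError(
                f"scheme {self.name!r} has no boundary rule for "
                f"({self.dims[dim_pos]}, {direction}, {condition})"
            ) from None


# ---------------------------------------------------------------------------
# built-in schemes
# ---------------------------------------------------------------------------

def _vref(time_off: int, space_off: int = 0, base: str = "j", lvl_base: str = "n") -> Var:
    return Var("v", (Idx(lvl_base, time_off), Idx(base, space_off)))


def _second_difference(level: int, jsym: str, delta: str) -> Expr:
    """(v[level, j+1] - 2 v[level, j] + v[level, j-1]) / delta^2"""
    num = BinOp(
        "+",
        sub(_vref(level, 1, jsym), mul(Num(2), _vref(level, 0, jsym))),
        _vref(level, -1, jsym),
    )
    return div(num, BinOp("^", Var(delta), Num(2)))


def _dirichlet_templates(kind: str) -> Tuple[BoundaryTemplate, ...]:
    """Material-node value clamps at the time levels the scheme reads.

    Explicit FTCS reads boundary values at both n (stencil inputs) and n+1
    (the advanced value is pinned), so both levels are clamped.  BTCS needs
    only level n+1; Crank–Nicolson reads both levels.  Ghost values that
    remain undefined after matching are assigned during dependency analysis
    (the pipeline's ghost-completion pass), not here.
    """
    val = Var("bval")
    v_at = lambda lvl: Var("v", (Idx("n", lvl), Idx("j", 0)))
    if kind == "FTCS":
        levels = (0, 1)
    elif kind == "BTCS":
        levels = (1,)
    else:  # Crank-Nicolson
        levels = (0, 1)
    return tuple(BoundaryTemplate(l, "material", v_at(l), val) for l in levels)


def _neumann_templates(kind: str, direction: str, delta: str) -> Tuple[BoundaryTemplate, ...]:
    """One-sided first differences pinning the boundary flux.

    Left side:  (v[n, j-1] - v[n, j]) / dx = bval
    Right side: (v[n, j] - v[n, j+1]) / dx = bval
    emitted at level n for explicit schemes, n+1 for BTCS, both for CN.
    """
    val = Var("bval")

    def eq(level):
        if direction == "-":
            lhs = div(sub(_vref(level, -1), _vref(level, 0)), Var(delta))
        else:
            lhs = div(sub(_vref(level, 0), _vref(level, 1)), Var(delta))
        return BoundaryTemplate(level, "material", lhs, val)

    if kind == "FTCS":
        levels = (0,)
    elif kind == "BTCS":
        levels = (1,)
    else:
        levels = (0, 1)
    return tuple(eq(l) for l in levels)


def _continuous_boundary(condition: str, direction: str, dim: str) -> Tuple[Expr, Expr]:
    if condition == "dirichlet":
        return (Var("v"), Var("bval"))
    return (Deriv(Var("v"), dim, 1, direction), Var("bval"))


def builtin_scheme(name: str, ndim: int = 1) -> SchemeSpec:
    """Construct one of the built-in single-step schemes.

    ``name`` is ``FTCS``, ``BTCS`` or ``CN`` (Crank–Nicolson); ``ndim`` is the
    number of spatial dimensions (1–3).  For ``ndim > 1`` the Laplacian is the
    sum of per-dimension three-point second differences, which is what the
    per-dimension operator rules produce when the model writes one
    second-derivative term per spatial dimension.
    """
    key = name.upper().replace("-", "")
    if key in ("CN", "CRANKNICOLSON"):
        key = "CN"
    if key not in ("FTCS", "BTCS", "CN"):
        raise SchemeError(f"unknown scheme {name!r} (expected FTCS, BTCS or CN)")
    if not 1 <= ndim <= 3:
        raise SchemeError(f"ndim must be 1..3, got {ndim}")

    dims = DIM_SYMBOLS[: ndim + 1]
    indices = INDEX_SYMBOLS[: ndim + 1]
    deltas = DELTA_SYMBOLS[: ndim + 1]

    base_idx = tuple(Idx(s, 0) for s in indices)
    var_rules = {
        "y": Var("y", base_idx),
        "v": Var("v", base_idx),
    }

    op_rules: Dict[Tuple[int, int], Expr] = {
        # forward difference in time, shared by all three schemes (Table-form)
        (1, 0): div(sub(_vref(1), _vref(0)), Var("dt")),
    }
    for p in range(1, ndim + 1):
        jsym, dsym = indices[p], deltas[p]
        if key == "FTCS":
            stencil = _second_difference(0, jsym, dsym)
        elif key == "BTCS":
            stencil = _second_difference(1, jsym, dsym)
        else:
            half = lambda lvl: div(
                BinOp(
                    "+",
                    sub(_vref(lvl, 1, jsym), mul(Num(2), _vref(lvl, 0, jsym))),
                    _vref(lvl, -1, jsym),
                ),
                mul(Num(2), BinOp("^", Var(dsym), Num(2))),
            )
            stencil = BinOp("+", half(0), half(1))
        op_rules[(2, p)] = stencil

    boundary_rules: Dict[int, BoundaryRule] = {}
    for p in range(1, ndim + 1):
        for direction in DIRECTIONS:
            for condition in CONDITIONS:
                bid = boundary_id(p, direction, condition)
                if condition == "dirichlet":
                    templates = _dirichlet_templates(key)
                else:
                    templates = _neumann_templates(key, direction, deltas[p])
                # templates above are written in the generic 1-D 'j'; expand
                # them onto this dimension's index symbol with the full
                # spatial index tuple (other dimensions at base offset)
                templates = tuple(
                    BoundaryTemplate(
                        tpl.level,
                        tpl.anchor,
                        _rehome(tpl.lhs, indices, p, deltas[p]),
                        _rehome(tpl.rhs, indices, p, deltas[p]),
                    )
                    for tpl in templates
                )
                boundary_rules[bid] = BoundaryRule(
                    bid,
                    p,
                    direction,
                    condition,
                    _continuous_boundary(condition, direction, dims[p]),
                    templates,
                )

    spec = SchemeSpec(
        name=key if key != "CN" else "CN",
        ndim=ndim,
        implicit=(key in ("BTCS", "CN")),
        dims=dims,
        indices=indices,
        deltas=deltas,
        var_rules=var_rules,
        op_rules=op_rules,
        boundary_rules=boundary_rules,
    )
    validate_scheme(spec)
    return spec


def _rehome(e: Expr, indices: Tuple[str, ...], active_pos: int, dsym: str) -> Expr:
    """Expand a template written in the generic 1-D form (time index n,
    spatial index j, delta dx) onto the full index tuple: the active
    dimension's index carries the template's j-offset, every other spatial
    dimension sits at its base index."""
    from .expressions import map_children

    def go(node):
        if isinstance(node, Var):
            if node.name == "dx" and node.indices is None:
                return Var(dsym)
            if node.indices is not None:
                time_entry = node.indices[0]
                j_off = 0
                for ix in node.indices[1:]:
                    if isinstance(ix, Idx) and ix.base == "j":
                        j_off = ix.offset
                spatial = [Idx(sym, 0) for sym in indices[1:]]
                spatial[active_pos - 1] = Idx(indices[active_pos], j_off)
                return Var(node.name, (time_entry, *spatial))
            return node
        return map_children(node, go)

    return go(e)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_scheme(spec: SchemeSpec) -> None:
    declared = set(spec.indices) | set(spec.deltas) | {spec.dims[0]}
    for key, rule in spec.op_rules.items():
        for node in walk(rule):
            if isinstance(node, Var) and node.indices is not None:
                for ix in node.indices:
                    if isinstance(ix, Idx) and ix.base not in spec.indices:
                        raise SchemeError(
                            f"operator rule {key} references undeclared index {ix.base!r}"
                        )
            elif isinstance(node, Var) and node.indices is None:
                if node.name not in declared | {spec.diff_sym, spec.arith_sym, spec.const_sym}:
                    raise SchemeError(
                        f"operator rule {key} references unknown symbol {node.name!r}"
                    )
    # boundary coverage: whenever a (dim, condition) pair appears, both
    # directions must be present — a stencil always reaches both sides
    seen = {(r.dim_pos, r.condition) for r in spec.boundary_rules.values()}
    for dim_pos, condition in seen:
        for direction in DIRECTIONS:
            bid = boundary_id(dim_pos, direction, condition)
            if bid not in spec.boundary_rules:
                raise SchemeError(
                    f"missing {condition} boundary rule for direction {direction!r} "
                    f"in dimension {spec.dims[dim_pos]!r}"
                )
    # implicit flag consistency: implicit iff a spatial stencil reads level n+1
    reads_np1 = False
    for (order, dim_pos), rule in spec.op_rules.items():
        if dim_pos == 0:
            continue
        for node in walk(rule):
            if isinstance(node, Var) and node.indices:
                t0 = node.indices[0]
                if isinstance(t0, Idx) and t0.offset >= 1:
                    reads_np1 = True
    if reads_np1 != spec.implicit:
        raise SchemeError(
            f"scheme {spec.name!r} declared {'implicit' if spec.implicit else 'explicit'} "
            f"but its spatial stencils {'do' if reads_np1 else 'do not'} read level n+1"
        )


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

def serialize_scheme(spec: SchemeSpec) -> str:
    lines = ["[scheme]", f"name = {spec.name}",
             f"kind = {'implicit' if spec.implicit else 'explicit'}", "",
             "[variables]",
             f"diffvar = {spec.diff_sym}",
             f"arithvar = {spec.arith_sym}",
             f"constvar = {spec.const_sym}",
             f"dimensions = {' '.join(spec.dims)}",
             f"indices = {' '.join(spec.indices)}",
             f"deltas = {' '.join(spec.deltas)}", "",
             "[replace]"]
    for sym in (spec.arith_sym, spec.diff_sym):
        if sym in spec.var_rules:
            lines.append(f"{sym} = {to_text(spec.var_rules[sym])}")
    lines.append("")
    lines.append("[operators]")
    for (order, dim_pos), rule in sorted(spec.op_rules.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        dim = spec.dims[dim_pos]
        k = "" if order == 1 else str(order)
        lines.append(f"d{k}({spec.diff_sym})/d({dim}){k} = {to_text(rule)}")
    lines.append("")
    lines.append("[boundary]")
    for bid in sorted(spec.boundary_rules):
        r = spec.boundary_rules[bid]
        cont = f"{to_text(r.continuous[0])} = {to_text(r.continuous[1])}"
        parts = [
            f"{to_text(t.lhs)} = {to_text(t.rhs)} @ {'n+1' if t.level else 'n'} {t.anchor}"
            for t in r.templates
        ]
        lines.append(
            f"{bid} = {spec.dims[r.dim_pos]} {r.direction} {r.condition} : "
            f"{cont} => " + " | ".join(parts)
        )
    return "\n".join(lines) + "\n"


def parse_scheme(text: str) -> SchemeSpec:
    """Parse a scheme description; inverse of :func:`serialize_scheme`."""
    section = None
    kv: Dict[str, Dict[str, str]] = {"scheme": {}, "variables": {}, "replace": {}}
    op_lines, boundary_lines = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        if section in ("scheme", "variables", "replace"):
            key, _, value = line.partition("=")
            if not _:
                raise SchemeError(f"line {lineno}: expected 'key = value'")
            kv[section][key.strip()] = value.strip()
        elif section == "operators":
            op_lines.append((lineno, line))
        elif section == "boundary":
            boundary_lines.append((lineno, line))
        else:
            raise SchemeError(f"line {lineno}: content outside any known section")

    try:
        name = kv["scheme"]["name"]
        kind = kv["scheme"]["kind"]
        dims = tuple(kv["variables"]["dimensions"].split())
        indices = tuple(kv["variables"]["indices"].split())
        deltas = tuple(kv["variables"]["deltas"].split())
        diff_sym = kv["variables"].get("diffvar", "v")
        arith_sym = kv["variables"].get("arithvar", "y")
        const_sym = kv["variables"].get("constvar", "z")
    except KeyError as exc:
        raise SchemeError(f"scheme file missing required field {exc}") from exc
    if not (len(dims) == len(indices) == len(deltas)):
        raise SchemeError("dimensions, indices and deltas must have equal length")
    ndim = len(dims) - 1

    var_rules = {
        sym: parse_expression(src) for sym, src in kv["replace"].items()
    }

    op_rules: Dict[Tuple[int, int], Expr] = {}
    for lineno, line in op_lines:
        lhs_text, _, rhs_text = line.partition("=")
        if not _:
            raise SchemeError(f"line {lineno}: operator rule needs '='")
        try:
            lhs = parse_expression(lhs_text, lineno)
            rhs = parse_expression(rhs_text, lineno)
        except ExpressionError as exc:
            raise SchemeError(str(exc)) from exc
        if not isinstance(lhs, Deriv):
            raise SchemeError(f"line {lineno}: operator rule LHS must be a derivative")
        if lhs.dim not in dims:
            raise SchemeError(f"line {lineno}: unknown dimension {lhs.dim!r}")
        op_rules[(lhs.order, dims.index(lhs.dim))] = rhs

    boundary_rules: Dict[int, BoundaryRule] = {}
    for lineno, line in boundary_lines:
        bid_text, _, rest = line.partition("=")
        try:
            bid = int(bid_text.strip())
        except ValueError:
            raise SchemeError(f"line {lineno}: boundary rule needs an integer ID") from None
        head, _, body = rest.partition(":")
        parts = head.split()
        if len(parts) != 3:
            raise SchemeError(f"line {lineno}: expected 'DIM DIRECTION CONDITION :'")
        dim, direction, condition = parts
        if dim not in dims or direction not in DIRECTIONS or condition not in CONDITIONS:
            raise SchemeError(f"line {lineno}: bad boundary header {head.strip()!r}")
        cont_text, _, tmpl_text = body.partition("=>")
        cl, _, cr = cont_text.partition("=")
        continuous = (parse_expression(cl, lineno), parse_expression(cr, lineno))
        templates = []
        for chunk in tmpl_text.split("|"):
            eq_text, _, at = chunk.partition("@")
            at_parts = at.split()
            if len(at_parts) != 2:
                raise SchemeError(f"line {lineno}: template needs '@ LEVEL ANCHOR'")
            level = 1 if at_parts[0] == "n+1" else 0
            anchor = at_parts[1]
            tl, _, tr = eq_text.partition("=")
            templates.append(
                BoundaryTemplate(level, anchor,
                                 parse_expression(tl, lineno),
                                 parse_expression(tr, lineno))
            )
        expected = boundary_id(dims.index(dim), direction, condition)
        if bid != expected:
            raise SchemeError(
                f"line {lineno}: boundary ID {bid} does not match its "
                f"(dimension, direction, condition) encoding {expected}"
            )
        boundary_rules[bid] = BoundaryRule(
            bid, dims.index(dim), direction, condition, continuous, tuple(templates)
        )

    spec = SchemeSpec(
        name=name,
        ndim=ndim,
        implicit=(kind == "implicit"),
        diff_sym=diff_sym,
        arith_sym=arith_sym,
        const_sym=const_sym,
        dims=dims,
        indices=indices,
        deltas=deltas,
        var_rules=var_rules,
        op_rules=op_rules,
        boundary_rules=boundary_rules,
    )
    validate_scheme(spec)
    return spec
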