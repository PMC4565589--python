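"""Relation files: binding a model to a scheme, a geometry and its conditions.

The relation file is the single per-simulation input.  It maps each model
variable to a scheme variable type, names the geometry (a CSV file or a
built-in synthetic mesh), declares the boundary conditions segment by
segment, attaches distributed-parameter files, and carries the simulation
parameters (time step, space step, constant values, probes, clamps).

Example::

    [map]
    V = diffvar
    I = arithvar
    J = arithvar
    D = constvar
    C = distributed

    [geometry]
    line = 3
    dx = 1.0

    [boundary]
    V : x min neumann 0
    V : x max neumann 0

    [distributed]
    C = param_C.csv

    [params]
    dt = 0.1
    D = 1.0
    steps = 100

Segment selectors are ``AXIS min``, ``AXIS max`` (all boundary nodes on that
side of the tissue, any axis position) or ``nodes (x,y,z) (x,y,z) ...``
(an explicit coordinate list), so a boundary domain can be split into any
number of parts with different condition types (mixed conditions).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .expressions import Expr, ExpressionError, Num, parse_expression, to_text
from .morphology import (
    Coord,
    DistributedParameter,
    MorphologyGrid,
    make_box_mesh,
    make_line_mesh,
    make_square_mesh,
    read_distributed_parameter_csv,
    read_geometry_csv,
)

SCHEME_TYPES = ("diffvar", "arithvar", "constvar", "distributed")

_AXES = {"x": 0, "y": 1, "z": 2}


class RelationError(ValueError):
    pass


@dataclass(frozen=True)
class BoundaryDecl:
    """One boundary-condition declaration for one segment of the boundary."""

    var: str                 # the differential variable the condition constrains
    condition: str           # 'dirichlet' | 'neumann'
    value: Expr              # clamp value / flux value (constant or named constant)
    axis: Optional[int] = None       # 0-based spatial axis, None for node lists
    side: Optional[str] = None       # '-' (min) | '+' (max)
    nodes: Tuple[Coord, ...] = ()    # explicit coordinates, if given

    def matches(self, coord: Coord, axis: int, direction: str) -> bool:
        if self.nodes:
            return coord in self.nodes
        return self.axis == axis and self.side == direction


@dataclass(frozen=True)
class Clamp:
    """An interior value clamp: the variable is held fixed at one node.

    Used for stimulus electrodes: the node's time-update equation is replaced
    by a constant assignment at level n+1 and the initial value is pinned.
    """

    var: str
    coord: Coord
    value: float


@dataclass
class RelationMap:
    mapping: Dict[str, str]                      # model variable -> scheme type
    geometry: Tuple[str, object]                 # ('file', path) | ('line', n) | ('square', n) | ('box', n)
    boundary: List[BoundaryDecl] = field(default_factory=list)
    distributed: Dict[str, str] = field(default_factory=dict)  # var -> csv path
    # in-memory distributed values (built-in fixtures); take precedence
    inline_distributed: Dict[str, Tuple[Tuple[Coord, float], ...]] = field(default_factory=dict)
    # per-node initial-value overrides, applied on top of the model's
    # uniform initial condition: var -> ((coord, value), ...)
    initial_values: Dict[str, Tuple[Tuple[Coord, float], ...]] = field(default_factory=dict)
    params: Dict[str, float] = field(default_factory=dict)
    clamps: List[Clamp] = field(default_factory=list)
    probes: List[Coord] = field(default_factory=list)
    dx: float = 1.0
    base_dir: str = "."

    def scheme_type(self, name: str) -> str:
        try:
            return self.mapping[name]
        except KeyError:
            raise RelationError(f"variable {name!r} is not mapped to a scheme type") from None

    def load_grid(self) -> MorphologyGrid:
        kind, arg = self.geometry
        if kind == "file":
            return read_geometry_csv(os.path.join(self.base_dir, str(arg)), self.dx)
        if kind == "line":
            return make_line_mesh(int(arg), self.dx)
        if kind == "square":
            return make_square_mesh(int(arg), self.dx)
        if kind == "box":
            return make_box_mesh(int(arg), self.dx)
        raise RelationError(f"unknown geometry kind {kind!r}")

    def load_distributed(self, grid: MorphologyGrid) -> Dict[str, DistributedParameter]:
        out = {}
        for name, path in self.distributed.items():
            out[name] = read_distributed_parameter_csv(
                os.path.join(self.base_dir, path), grid, name
            )
        for name, values in self.inline_distributed.items():
            out[name] = DistributedParameter(name, tuple(values))
        return out


def validate_relation(rel: RelationMap, model=None) -> None:
    for name, stype in rel.mapping.items():
        if stype not in SCHEME_TYPES:
            raise RelationError(f"unknown scheme type {stype!r} for variable {name!r}")
    for decl in rel.boundary:
        if decl.condition not in ("dirichlet", "neumann"):
            raise RelationError(f"unknown boundary condition {decl.condition!r}")
        if decl.condition == "dirichlet" and not _value_resolvable(decl.value, rel):
            raise RelationError(
                f"Dirichlet value {to_text(decl.value)!r} is neither a finite "
                f"number nor a declared constant"
            )
    if model is not None:
        role_map = {"diff": "diffvar", "arith": "arithvar",
                    "const": "constvar", "dist": "distributed"}
        for v in model.variables:
            if v.name not in rel.mapping:
                raise RelationError(f"model variable {v.name!r} is unmapped")
            expected = role_map[v.role]
            if rel.mapping[v.name] != expected:
                raise RelationError(
                    f"variable {v.name!r} declared {v.role!r} in the model but "
                    f"mapped to {rel.mapping[v.name]!r}"
                )


def _value_resolvable(value: Expr, rel: RelationMap) -> bool:
    from .expressions import Var, walk

    for node in walk(value):
        if isinstance(node, Var) and node.name not in rel.params:
            return False
    return True


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

def parse_relation(text: str, base_dir: str = ".") -> RelationMap:
    section = None
    mapping: Dict[str, str] = {}
    geometry = None
    dx = 1.0
    boundary: List[BoundaryDecl] = []
    distributed: Dict[str, str] = {}
    params: Dict[str, float] = {}
    clamps: List[Clamp] = []
    probes: List[Coord] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        if section == "map":
            name, _, stype = line.partition("=")
            name, stype = name.strip(), stype.strip()
            if name in mapping and mapping[name] != stype:
                raise RelationError(
                    f"line {lineno}: contradictory duplicate mapping for {name!r}"
                )
            mapping[name] = stype
        elif section == "geometry":
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "dx":
                dx = float(value)
            elif key in ("file", "line", "square", "box"):
                geometry = (key, value if key == "file" else int(value))
            else:
                raise RelationError(f"line {lineno}: unknown geometry key {key!r}")
        elif section == "boundary":
            boundary.append(_parse_boundary_decl(line, lineno))
        elif section == "distributed":
            name, _, path = line.partition("=")
            distributed[name.strip()] = path.strip()
        elif section == "params":
            _parse_param_line(line, lineno, params, clamps, probes)
        else:
            raise RelationError(f"line {lineno}: content outside any known section")

    if geometry is None:
        raise RelationError("relation file declares no geometry")
    rel = RelationMap(mapping, geometry, boundary=boundary,
                      distributed=distributed, params=params, clamps=clamps,
                      probes=probes, dx=dx, base_dir=base_dir)
    validate_relation(rel)
    return rel


def _parse_coord(tok: str, lineno: int) -> Coord:
    tok = tok.strip().strip("()")
    parts = [p for p in tok.split(",") if p.strip() != ""]
    if len(parts) > 3:
        raise RelationError(f"line {lineno}: bad coordinate {tok!r}")
    vals = [int(p) for p in parts] + [0] * (3 - len(parts))
    return (vals[0], vals[1], vals[2])


def _parse_boundary_decl(line: str, lineno: int) -> BoundaryDecl:
    var, colon, rest = line.partition(":")
    if not colon:
        raise RelationError(f"line {lineno}: boundary line needs 'VAR : selector ...'")
    var = var.strip()
    parts = rest.split()
    if not parts:
        raise RelationError(f"line {lineno}: empty boundary declaration")
    if parts[0] == "nodes":
        # VAR : nodes (x,y,z) (x,y,z) CONDITION VALUE
        coords = []
        i = 1
        while i < len(parts) and parts[i].startswith("("):
            coords.append(_parse_coord(parts[i], lineno))
            i += 1
        if i + 1 > len(parts):
            raise RelationError(f"line {lineno}: missing condition/value")
        condition = parts[i].lower()
        value_text = " ".join(parts[i + 1:]) or "0"
        return BoundaryDecl(var, condition, _parse_value(value_text, lineno),
                            nodes=tuple(coords))
    # VAR : AXIS min|max CONDITION VALUE
    if len(parts) < 3:
        raise RelationError(f"line {lineno}: expected 'AXIS min|max CONDITION [VALUE]'")
    axis_name, side_name, condition = parts[0], parts[1], parts[2].lower()
    if axis_name not in _AXES or side_name not in ("min", "max"):
        raise RelationError(f"line {lineno}: bad segment selector {parts[:2]}")
    value_text = " ".join(parts[3:]) or "0"
    return BoundaryDecl(
        var, condition, _parse_value(value_text, lineno),
        axis=_AXES[axis_name], side="-" if side_name == "min" else "+",
    )


def _parse_value(text: str, lineno: int) -> Expr:
    try:
        return parse_expression(text, lineno)
    except ExpressionError as exc:
        raise RelationError(f"line {lineno}: bad value expression: {exc}") from exc


def _parse_param_line(line, lineno, params, clamps, probes):
    if line.startswith("clamp "):
        # clamp VAR (x,y,z) = VALUE
        body = line[len("clamp "):]
        head, _, value = body.partition("=")
        parts = head.split()
        if len(parts) != 2 or not _:
            raise RelationError(f"line {lineno}: expected 'clamp VAR (x,y,z) = VALUE'")
        clamps.append(Clamp(parts[0], _parse_coord(parts[1], lineno), float(value)))
        return
    key, _, value = line.partition("=")
    key, value = key.strip(), value.strip()
    if not _:
        raise RelationError(f"line {lineno}: expected 'key = value'")
    if key == "probe":
        probes.append(_parse_coord(value, lineno))
        return
    try:
        params[key] = float(value)
    except ValueError:
        raise RelationError(f"line {lineno}: parameter {key!r} must be numeric") from None


def serialize_relation(rel: RelationMap) -> str:
    lines = ["[map]"]
    for name in rel.mapping:
        lines.append(f"{name} = {rel.mapping[name]}")
    lines += ["", "[geometry]"]
    kind, arg = rel.geometry
    lines.append(f"{kind} = {arg}")
    lines.append(f"dx = {rel.dx}")
    lines += ["", "[boundary]"]
    for d in rel.boundary:
        if d.nodes:
            sel = "nodes " + " ".join(f"({c[0]},{c[1]},{c[2]})" for c in d.nodes)
        else:
            axis = {v: k for k, v in _AXES.items()}[d.axis]
            sel = f"{axis} {'min' if d.side == '-' else 'max'}"
        lines.append(f"{d.var} : {sel} {d.condition} {to_text(d.value)}")
    if rel.distributed:
        lines += ["", "[distributed]"]
        for name, path in rel.distributed.items():
            lines.append(f"{name} = {path}")
    lines += ["", "[params]"]
    for key, value in rel.params.items():
        lines.append(f"{key} = {value}")
    for c in rel.clamps:
        lines.append(f"clamp {c.var} ({c.coord[0]},{c.coord[1]},{c.coord[2]}) = {c.value}")
    for p in rel.probes:
        lines.append(f"probe = ({p[0]},{p[1]},{p[2]})")
    return "\n".join(lines) + "\n"
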