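"""Program code generation: loops, Newton blocks, emission and execution.

The ordered equation instances coming out of dependency analysis are first
reconstructed into loops: a loop is created for every maximal run of
instances that share one equation template over consecutive nodes, and runs
that tile a full rectangle become nested loops.  Strongly connected blocks
(simultaneous equations) are emitted as Newton iterations with a symbolically
derived Jacobian.  The emitter then assembles a complete, self-contained
simulation program — array declarations, initial conditions, a time loop
containing the boundary and spatial loops in dependency order, two-level
time rotation, and optional probe recording.

Targets: ``host`` (a single self-contained Python source file; used by the
test harness and the default) and ``c`` (C99, explicit schemes only).
Each equation is rearranged symbolically (sympy) so that its matched unknown
stands alone on the left-hand side before printing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import sympy as sp
from sympy.printing.c import C99CodePrinter
from sympy.printing.pycode import PythonCodePrinter

from .dependency import DependencyGraph, format_occurrence
from .expressions import (
    And,
    BinOp,
    Compare,
    Deriv,
    Expr,
    Idx,
    Neg,
    Num,
    Piecewise,
    Var,
    map_children,
    to_text,
    walk,
)
from .instantiate import EquationInstance
from .morphology import Coord, MorphologyGrid


class CodegenError(ValueError):
    pass


class SolveError(CodegenError):
    """The matched unknown cannot be isolated in closed form; the emitter
    falls back to a Newton iteration for the affected instances."""


LOOP_SYMS = ("j", "k", "l")


# ---------------------------------------------------------------------------
# sympy bridge
# ---------------------------------------------------------------------------

def _mangle(var: Var) -> str:
    if var.indices is None:
        return f"S0_{var.name}"
    parts = [f"S1_{var.name}"]
    for ix in var.indices:
        if isinstance(ix, Idx):
            if ix.offset == 0:
                parts.append(ix.base)
            else:
                parts.append(f"{ix.base}{'p' if ix.offset > 0 else 'm'}{abs(ix.offset)}")
        else:
            parts.append(f"c{ix}" if ix >= 0 else f"cm{abs(ix)}")
    return "_".join(parts)


_CMP = {"<": sp.Lt, "<=": sp.Le, ">": sp.Gt, ">=": sp.Ge, "==": sp.Eq}


def to_sympy(e: Expr, registry: Dict[str, Var]) -> sp.Expr:
    """Convert an expression tree to sympy; ``registry`` collects the symbol
    name → variable-reference map needed to print the result back out."""
    if isinstance(e, Num):
        v = e.value
        return sp.Integer(int(v)) if v == int(v) else sp.Float(v)
    if isinstance(e, Var):
        name = _mangle(e)
        registry[name] = e
        return sp.Symbol(name, real=True)
    if isinstance(e, Neg):
        return -to_sympy(e.operand, registry)
    if isinstance(e, BinOp):
        l, r = to_sympy(e.left, registry), to_sympy(e.right, registry)
        if e.op == "+":
            return l + r
        if e.op == "-":
            return l - r
        if e.op == "*":
            return l * r
        if e.op == "/":
            return l / r
        if e.op == "^":
            return l ** r
    if isinstance(e, Compare):
        return _CMP[e.op](to_sympy(e.left, registry), to_sympy(e.right, registry))
    if isinstance(e, And):
        return sp.And(to_sympy(e.left, registry), to_sympy(e.right, registry))
    if isinstance(e, Piecewise):
        pairs = [
            (to_sympy(v, registry), to_sympy(c, registry)) for c, v in e.branches
        ]
        pairs.append((to_sympy(e.default, registry), sp.true))
        return sp.Piecewise(*pairs)
    if isinstance(e, Deriv):
        raise CodegenError("derivative operator survived discretization")
    raise CodegenError(f"cannot convert {e!r} to sympy")


class _PyPrinter(PythonCodePrinter):
    def __init__(self, symmap):
        super().__init__()
        self._symmap = symmap

    def _print_Symbol(self, expr):
        return self._symmap.get(expr.name, expr.name)


class _CPrinter(C99CodePrinter):
    def __init__(self, symmap):
        super().__init__()
        self._symmap = symmap

    def _print_Symbol(self, expr):
        return self._symmap.get(expr.name, expr.name)


# ---------------------------------------------------------------------------
# loop blocks
# ---------------------------------------------------------------------------

@dataclass
class LoopBlock:
    """A unit of emitted code.

    kind 'stmt': one instance, concrete indices.
    kind 'loop': a template iterated over a box of nodes (``lo``..``hi``
    inclusive per axis); instances listed in iteration order.
    kind 'newton': a simultaneous block solved jointly.
    """

    kind: str
    instances: List[EquationInstance]
    lo: Optional[Coord] = None
    hi: Optional[Coord] = None
    key: Optional[tuple] = None


def _relativize(e: Expr, node: Coord, ndim: int) -> Expr:
    """Turn concrete spatial indices into loop-variable offsets relative to
    ``node`` (so instances of one template become structurally identical)."""

    def go(x):
        if isinstance(x, Var) and x.indices is not None:
            new = []
            spatial_axis = 0
            has_time = x.indices and isinstance(x.indices[0], Idx)
            for pos, ix in enumerate(x.indices):
                if isinstance(ix, Idx):
                    new.append(ix)
                else:
                    axis = pos - 1 if has_time else pos
                    new.append(Idx(LOOP_SYMS[axis], ix - node[axis]))
            return Var(x.name, tuple(new))
        return map_children(x, go)

    return go(e)


def _group_key(inst: EquationInstance, ndim: int) -> tuple:
    rl = _relativize(inst.lhs, inst.node, ndim)
    rr = _relativize(inst.rhs, inst.node, ndim)
    un = inst.unknown
    rel_un = (un[0], un[1], tuple(un[2][a] - inst.node[a] for a in range(3)))
    return (to_text(rl), to_text(rr), rel_un)


def build_loops(
    dep: DependencyGraph, ndim: int, unroll: bool = False
) -> List[LoopBlock]:
    """Reconstruct loops from the ordered instance blocks.

    Maximal runs of consecutive nodes sharing one template merge into a loop;
    consecutive loops over identical x-ranges on adjacent rows merge into
    nested (boxed) loops.  SCC blocks of size > 1 become Newton blocks, as do
    self-referential singletons.  With ``unroll=True`` every instance stays a
    separate statement (used to validate loop reconstruction).
    """
    instances = dep.instances
    blocks: List[LoopBlock] = []
    for scc in dep.ordered_blocks():
        members = [instances[i] for i in scc]
        if len(members) > 1:
            blocks.append(LoopBlock("newton", members))
            continue
        inst = members[0]
        i = scc[0]
        if dep.digraph.has_edge(i, i):
            blocks.append(LoopBlock("newton", members))
            continue
        blocks.append(
            LoopBlock("stmt", members, inst.node, inst.node, _group_key(inst, ndim))
        )
    if unroll:
        return blocks

    # stage 1: merge x-consecutive statements
    merged: List[LoopBlock] = []
    for b in blocks:
        if (
            b.kind == "stmt"
            and merged
            and merged[-1].kind in ("stmt", "loop")
            and merged[-1].key == b.key
            and _is_next(merged[-1].hi, b.lo, axis=0)
        ):
            prev = merged[-1]
            prev.kind = "loop"
            prev.hi = b.lo
            prev.instances.extend(b.instances)
            continue
        merged.append(b)

    # stage 2+: merge runs into boxes along y, then z
    for axis in (1, 2):
        if ndim <= axis:
            break
        boxed: List[LoopBlock] = []
        for b in merged:
            if (
                b.kind == "loop"
                and boxed
                and boxed[-1].kind == "loop"
                and boxed[-1].key == b.key
                and _same_span(boxed[-1], b, axis)
                and _is_next(boxed[-1].hi, b.lo, axis=axis)
            ):
                prev = boxed[-1]
                prev.hi = tuple(
                    max(a, c) for a, c in zip(prev.hi, b.hi)
                )
                prev.instances.extend(b.instances)
                continue
            boxed.append(b)
        merged = boxed
    return merged


def _is_next(prev_hi: Coord, lo: Coord, axis: int) -> bool:
    if prev_hi is None or lo is None:
        return False
    for a in range(3):
        want = prev_hi[a] + 1 if a == axis else prev_hi[a]
        if lo[a] != want:
            return False
    return True


def _same_span(a: LoopBlock, b: LoopBlock, merge_axis: int) -> bool:
    for ax in range(3):
        if ax == merge_axis:
            continue
        if a.lo[ax] != b.lo[ax] or a.hi[ax] != b.hi[ax]:
            return False
    return True


# ---------------------------------------------------------------------------
# emission context
# ---------------------------------------------------------------------------

@dataclass
class CodegenContext:
    model: object
    scheme: object
    rel: object
    grid: MorphologyGrid
    dists: Dict[str, object]          # distributed parameters
    roles: Dict[str, str]             # scheme types per variable
    consts: Dict[str, float]
    inits: Dict[str, float]           # per differential/arith variable
    ndim: int
    # Dirichlet-clamped material nodes: the initial arrays are made
    # consistent with the boundary values
    boundary_inits: List[Tuple[str, Coord, Expr]] = field(default_factory=list)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.grid.shape

    def delta_values(self) -> Dict[str, float]:
        out = {"dt": float(self.rel.params.get("dt", 0.1))}
        names = ("dx", "dy2", "dz2")
        for a in range(self.ndim):
            out[names[a]] = float(self.grid.dx[a] if a < len(self.grid.dx) else self.grid.dx[0])
        return out


def make_context(model, scheme, rel, grid, dists, bnodes=()) -> CodegenContext:
    roles = {name: rel.scheme_type(name) for name in rel.mapping}
    consts = {}
    inits = {}
    for v in model.variables:
        if v.role == "const":
            consts[v.name] = float(v.init) if v.init is not None else None
        elif v.init is not None:
            inits[v.name] = float(v.init)
        elif v.role in ("diff", "arith"):
            inits[v.name] = 0.0
    for key, value in rel.params.items():
        if key in ("dt", "steps", "record_every", "t_end"):
            continue
        consts[key] = float(value)
    for name, value in list(consts.items()):
        if value is None:
            raise CodegenError(f"unresolved constant {name!r}")
    boundary_inits = []
    seen = set()
    for b in bnodes:
        decl = rel.boundary[b.decl_index]
        if decl.condition != "dirichlet":
            continue
        step = 1 if b.direction == "-" else -1
        m = list(b.coord)
        m[b.axis] += step
        key = (decl.var, tuple(m))
        if key not in seen:
            seen.add(key)
            boundary_inits.append((decl.var, tuple(m), decl.value))
    return CodegenContext(model, scheme, rel, grid, dists, roles, consts, inits,
                          grid.ndim, boundary_inits)


@dataclass
class GeneratedProgram:
    source: str
    target: str
    metadata: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# statement solving
# ---------------------------------------------------------------------------

class _Solver:
    """Rearranges equations so the matched unknown stands alone on the LHS.

    Results are cached on the relativized template, so a loop over thousands
    of nodes costs one symbolic solve.
    """

    def __init__(self):
        self.cache: Dict[tuple, tuple] = {}

    def solve(self, lhs: Expr, rhs: Expr, unknown: Var):
        key = (to_text(lhs), to_text(rhs), to_text(unknown))
        if key in self.cache:
            return self.cache[key]
        registry: Dict[str, Var] = {}
        L = to_sympy(lhs, registry)
        R = to_sympy(rhs, registry)
        uname = _mangle(unknown)
        usym = sp.Symbol(uname, real=True)
        if L == usym and usym not in R.free_symbols:
            sol = R
        else:
            try:
                sols = sp.solve(L - R, usym)
            except Exception as exc:  # sympy can fail on exotic forms
                raise SolveError(
                    f"cannot isolate {to_text(unknown)}: {exc}"
                ) from exc
            if len(sols) != 1:
                raise SolveError(
                    f"cannot isolate {to_text(unknown)} in "
                    f"{to_text(lhs)} = {to_text(rhs)} "
                    f"({len(sols)} symbolic solutions)"
                )
            sol = sols[0]
        self.cache[key] = (sol, registry)
        return sol, registry


def _unknown_var(inst: EquationInstance) -> Var:
    name, level, coords = inst.unknown
    return Var(name, (Idx("n", level),) + tuple(coords))


def _trim(var: Var, ndim: int) -> Var:
    """Drop trailing padding zeros beyond ndim from concrete coordinates."""
    if var.indices is None:
        return var
    has_time = isinstance(var.indices[0], Idx) and var.indices[0].base == "n"
    spatial = var.indices[1:] if has_time else var.indices
    spatial = spatial[:ndim] if len(spatial) > ndim else spatial
    return Var(var.name, (var.indices[0],) + tuple(spatial) if has_time else tuple(spatial))


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

class HostRenderer:
    lang = "host"

    def __init__(self, ctx: CodegenContext):
        self.ctx = ctx
        self.deltas = ctx.delta_values()

    def array(self, name: str, level: int) -> str:
        return f"{name}_{level}"

    def dist_array(self, name: str) -> str:
        return f"{name}_d"

    def index(self, entries, binding) -> str:
        parts = []
        for a, ix in enumerate(entries[: self.ctx.ndim]):
            if isinstance(ix, Idx):
                if ix.base in binding:
                    parts.append(str(binding[ix.base] + ix.offset))
                elif ix.offset == 0:
                    parts.append(ix.base)
                else:
                    parts.append(f"{ix.base}{'+' if ix.offset > 0 else '-'}{abs(ix.offset)}")
            else:
                parts.append(str(ix))
        return "".join(f"[{p}]" for p in parts)

    def ref(self, var: Var, binding) -> str:
        name = var.name
        if var.indices is None:
            if name == self.ctx.model.time_dim:
                return "t"
            if name in self.deltas or name in self.ctx.consts:
                return name
            raise CodegenError(f"unresolved constant {name!r}")
        first = var.indices[0]
        if isinstance(first, Idx) and first.base == "n":
            level = first.offset
            role = self.ctx.roles.get(name)
            if role == "arithvar":
                level = 0
            return f"{self.array(name, level)}{self.index(var.indices[1:], binding)}"
        return f"{self.dist_array(name)}{self.index(var.indices, binding)}"

    def symmap(self, registry: Dict[str, Var], binding, overrides=None) -> Dict[str, str]:
        out = {}
        for mangled, var in registry.items():
            if overrides and mangled in overrides:
                out[mangled] = overrides[mangled]
            else:
                out[mangled] = self.ref(var, binding)
        return out

    def print_expr(self, expr: sp.Expr, symmap) -> str:
        return _PyPrinter(symmap).doprint(expr)


class CRenderer(HostRenderer):
    lang = "c"

    def index(self, entries, binding) -> str:
        shape = self.ctx.shape
        parts = []
        for a, ix in enumerate(entries[: self.ctx.ndim]):
            if isinstance(ix, Idx):
                if ix.base in binding:
                    parts.append(str(binding[ix.base] + ix.offset))
                elif ix.offset == 0:
                    parts.append(ix.base)
                else:
                    parts.append(f"{ix.base}{'+' if ix.offset > 0 else '-'}{abs(ix.offset)}")
            else:
                parts.append(str(ix))
        flat = parts[0]
        for a in range(1, len(parts)):
            flat = f"({flat})*{shape[a]} + ({parts[a]})"
        return f"[{flat}]"

    def print_expr(self, expr: sp.Expr, symmap) -> str:
        return _CPrinter(symmap).doprint(expr)


# ---------------------------------------------------------------------------
# program emission
# ---------------------------------------------------------------------------

def emit_program(
    blocks: Sequence[LoopBlock],
    ctx: CodegenContext,
    target: str = "host",
) -> GeneratedProgram:
    if target == "host":
        return _emit_host(blocks, ctx)
    if target == "c":
        return _emit_c(blocks, ctx)
    raise CodegenError(f"unsupported target {target!r}")


def _block_statements(block: LoopBlock, ctx: CodegenContext, renderer, solver: _Solver):
    """Return (binding-free) statement lines for one stmt/loop block."""
    inst = block.instances[0]
    rl = _relativize(inst.lhs, inst.node, ctx.ndim)
    rr = _relativize(inst.rhs, inst.node, ctx.ndim)
    un = _relativize(_trim(_unknown_var(inst), ctx.ndim), inst.node, ctx.ndim)
    sol, registry = solver.solve(rl, rr, un)
    if block.kind == "stmt":
        binding = {LOOP_SYMS[a]: inst.node[a] for a in range(ctx.ndim)}
    else:
        binding = {}
    symmap = renderer.symmap(registry, binding)
    target_code = renderer.ref(un, binding)
    rhs_code = renderer.print_expr(sol, symmap)
    return target_code, rhs_code


def _newton_lines(block: LoopBlock, ctx: CodegenContext, renderer, indent: str):
    """Emit a Newton iteration for a simultaneous block.

    Residuals are F_i = lhs_i - rhs_i; the Jacobian entries are symbolic
    partial derivatives with respect to the block's unknowns; the initial
    guess is the previous-time-level (or previous-step) value of each
    unknown.  Policy: absolute residual tolerance 1e-10, at most 50
    iterations, divergence aborts with the step index.
    """
    registry: Dict[str, Var] = {}
    residuals = []
    for inst in block.instances:
        L = to_sympy(inst.lhs, registry)
        R = to_sympy(inst.rhs, registry)
        residuals.append(L - R)
    unknown_vars = [_trim(_unknown_var(i), ctx.ndim) for i in block.instances]
    usyms = []
    overrides = {}
    for q, uv in enumerate(unknown_vars):
        m = _mangle(uv)
        registry.setdefault(m, uv)
        usyms.append(sp.Symbol(m, real=True))
        overrides[m] = f"_u[{q}]"

    jac = []
    for fi in residuals:
        row = [sp.diff(fi, u) for u in usyms]
        if all(r == 0 for r in row):
            raise CodegenError(
                "structurally singular Jacobian: a simultaneous equation is "
                "independent of every unknown in its block"
            )
        jac.append(row)

    binding: Dict[str, int] = {}
    symmap = renderer.symmap(registry, binding, overrides)

    guesses = []
    for uv in unknown_vars:
        name, first = uv.name, uv.indices[0]
        level = first.offset if isinstance(first, Idx) else 0
        if ctx.roles.get(name) == "diffvar" and level >= 1:
            prev = Var(name, (Idx("n", 0),) + uv.indices[1:])
        else:
            prev = uv
        guesses.append(renderer.ref(prev, binding))

    K = len(block.instances)
    lines = [f"{indent}# simultaneous block: {K} equations (Newton)"]
    lines.append(f"{indent}_u = [{', '.join(guesses)}]")
    lines.append(f"{indent}for _it in range(50):")
    fexprs = ", ".join(renderer.print_expr(f, symmap) for f in residuals)
    lines.append(f"{indent}    _F = [{fexprs}]")
    lines.append(f"{indent}    _r = 0.0")
    lines.append(f"{indent}    for _f in _F:")
    lines.append(f"{indent}        _a = _f if _f >= 0 else -_f")
    lines.append(f"{indent}        if _a > _r:")
    lines.append(f"{indent}            _r = _a")
    lines.append(f"{indent}    if _r < 1e-10:")
    lines.append(f"{indent}        break")
    rows = []
    for row in jac:
        rows.append("[" + ", ".join(renderer.print_expr(e, symmap) for e in row) + "]")
    lines.append(f"{indent}    _Jm = [{', '.join(rows)}]")
    lines.append(f"{indent}    _d = _linsolve(_Jm, _F)")
    lines.append(f"{indent}    for _q in range({K}):")
    lines.append(f"{indent}        _u[_q] -= _d[_q]")
    lines.append(f"{indent}else:")
    lines.append(
        f"{indent}    raise RuntimeError('Newton solver failed to converge at step %d' % n)"
    )
    for q, uv in enumerate(unknown_vars):
        lines.append(f"{indent}{renderer.ref(uv, binding)} = _u[{q}]")
    return lines


_LINSOLVE_SRC = '''\
def _linsolve(A, b):
    """Dense Gaussian elimination with partial pivoting (small systems)."""
    K = len(b)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(K):
        piv = max(range(col, K), key=lambda r: abs(M[r][col]))
        if M[piv][col] == 0.0:
            raise RuntimeError("singular Jacobian in Newton solver")
        if piv != col:
            M[col], M[piv] = M[piv], M[col]
        inv = 1.0 / M[col][col]
        for r in range(col + 1, K):
            f = M[r][col] * inv
            if f != 0.0:
                for c in range(col, K + 1):
                    M[r][c] -= f * M[col][c]
    x = [0.0] * K
    for r in range(K - 1, -1, -1):
        s = M[r][K]
        for c in range(r + 1, K):
            s -= M[r][c] * x[c]
        x[r] = s / M[r][r]
    return x
'''


def _nested_zeros(shape, fill="0.0"):
    if len(shape) == 1:
        return f"[{fill}] * {shape[0]}"
    inner = _nested_zeros(shape[1:], fill)
    return f"[{inner} for _ in range({shape[0]})]"


def _emit_host(blocks: Sequence[LoopBlock], ctx: CodegenContext) -> GeneratedProgram:
    renderer = HostRenderer(ctx)
    solver = _Solver()
    ndim = ctx.ndim
    shape = ctx.shape
    diffvars = [n for n, r in ctx.roles.items() if r == "diffvar"]
    arithvars = [n for n, r in ctx.roles.items() if r == "arithvar"]
    distvars = [n for n, r in ctx.roles.items() if r == "distributed"]

    src: List[str] = []
    A = src.append
    A('"""Simulation program generated by fdgen '
      f'({ctx.scheme.name} scheme, {ndim}-D grid {"x".join(map(str, shape))})."""')
    A("")
    A(_LINSOLVE_SRC)
    A("")
    A("def simulate(steps, probes=None, record_every=None):")
    deltas = renderer.deltas
    for name, value in deltas.items():
        A(f"    {name} = {value!r}")
    for name, value in sorted(ctx.consts.items()):
        A(f"    {name} = {float(value)!r}")
    dimnames = ["NX", "NY", "NZ"]
    for a in range(ndim):
        A(f"    {dimnames[a]} = {shape[a]}")
    A("")
    for name in diffvars:
        init = ctx.inits.get(name, 0.0)
        A(f"    {name}_0 = {_nested_zeros(shape, repr(float(init)))}")
        A(f"    {name}_1 = {_nested_zeros(shape, repr(float(init)))}")
    for name in arithvars:
        init = ctx.inits.get(name, 0.0)
        A(f"    {name}_0 = {_nested_zeros(shape, repr(float(init)))}")
    for name in distvars:
        A(f"    {name}_d = {_nested_zeros(shape)}")
        dist = ctx.dists.get(name)
        if dist is not None:
            for coord, value in dist.values:
                idx = "".join(f"[{coord[a]}]" for a in range(ndim))
                A(f"    {name}_d{idx} = {float(value)!r}")
    for name, overrides in getattr(ctx.rel, "initial_values", {}).items():
        level_suffixes = ("_0", "_1") if name in diffvars else ("_0",)
        for coord, value in overrides:
            idx = "".join(f"[{coord[a]}]" for a in range(ndim))
            for suf in level_suffixes:
                A(f"    {name}{suf}{idx} = {float(value)!r}")
    for name, coord, value in ctx.boundary_inits:
        reg: Dict[str, Var] = {}
        code = renderer.print_expr(to_sympy(value, reg), renderer.symmap(reg, {}))
        idx = "".join(f"[{coord[a]}]" for a in range(ndim))
        A(f"    {name}_0{idx} = {code}")
        A(f"    {name}_1{idx} = {code}")
    for clamp in ctx.rel.clamps:
        idx = "".join(f"[{clamp.coord[a]}]" for a in range(ndim))
        A(f"    {clamp.var}_0{idx} = {float(clamp.value)!r}")
        A(f"    {clamp.var}_1{idx} = {float(clamp.value)!r}")
    A("")
    A("    _probes = [tuple(p) for p in (probes or [])]")
    A("    _series = {}")
    A("    _times = []")
    A("    for _p in _probes:")
    for name in diffvars:
        A(f"        _series[({name!r}, _p)] = []")
    A("    def _record(_n):")
    A("        _times.append(_n * dt)")
    A("        for _p in _probes:")
    for name in diffvars:
        idx = "".join(f"[_p[{a}]]" for a in range(ndim))
        A(f"            _v = {name}_0{idx}")
        A("            if _v != _v:")
        A("                raise RuntimeError('NaN detected at step %d' % _n)")
        A(f"            _series[({name!r}, _p)].append(_v)")
    A("    _record(0)")
    A("")
    A("    n = 0")
    A("    for n in range(steps):")
    A(f"        t = n * dt")

    newton_blocks = 0
    loop_count = 0
    stmt_count = 0
    for block in blocks:
        if block.kind == "newton":
            newton_blocks += 1
            src.extend(_newton_lines(block, ctx, renderer, "        "))
            continue
        try:
            target_code, rhs_code = _block_statements(block, ctx, renderer, solver)
        except SolveError:
            # no closed-form rearrangement: solve each instance iteratively
            for inst in block.instances:
                newton_blocks += 1
                src.extend(
                    _newton_lines(LoopBlock("newton", [inst]), ctx, renderer,
                                  "        ")
                )
            continue
        if block.kind == "stmt":
            stmt_count += 1
            A(f"        {target_code} = {rhs_code}")
        else:
            loop_count += 1
            indent = "        "
            # outer loops over higher axes, x innermost
            for a in range(ndim - 1, 0, -1):
                A(f"{indent}for {LOOP_SYMS[a]} in range({block.lo[a]}, {block.hi[a] + 1}):")
                indent += "    "
            A(f"{indent}for {LOOP_SYMS[0]} in range({block.lo[0]}, {block.hi[0] + 1}):")
            A(f"{indent}    {target_code} = {rhs_code}")

    names = ", ".join(f"{n}_0, {n}_1" for n in diffvars)
    swapped = ", ".join(f"{n}_1, {n}_0" for n in diffvars)
    A(f"        {names} = {swapped}")
    for clamp in ctx.rel.clamps:
        idx = "".join(f"[{clamp.coord[a]}]" for a in range(ndim))
        A(f"        {clamp.var}_1{idx} = {float(clamp.value)!r}")
    A("        if record_every and (n + 1) % record_every == 0 and n + 1 != steps:")
    A("            _record(n + 1)")
    A("    if steps > 0:")
    A("        _record(steps)")
    A("")
    finals = []
    for name in diffvars:
        finals.append(f"{name!r}: {name}_0")
    for name in arithvars:
        finals.append(f"{name!r}: {name}_0")
    for name in distvars:
        finals.append(f"{name!r}: {name}_d")
    A("    return {'final': {" + ", ".join(finals) + "},")
    A("            'series': _series, 'times': _times, 'steps': steps}")
    A("")

    meta = {
        "target": "host",
        "ndim": ndim,
        "shape": shape,
        "newton_blocks": newton_blocks,
        "loops": loop_count,
        "statements": stmt_count,
        "blocks": len(blocks),
    }
    return GeneratedProgram("\n".join(src), "host", meta)


def _emit_c(blocks: Sequence[LoopBlock], ctx: CodegenContext) -> GeneratedProgram:
    if any(b.kind == "newton" for b in blocks):
        raise CodegenError(
            "the C target supports explicit schemes only; simultaneous "
            "blocks (Newton) emit in the host target"
        )
    renderer = CRenderer(ctx)
    solver = _Solver()
    ndim = ctx.ndim
    shape = ctx.shape
    total = math.prod(shape)
    diffvars = [n for n, r in ctx.roles.items() if r == "diffvar"]
    arithvars = [n for n, r in ctx.roles.items() if r == "arithvar"]
    distvars = [n for n, r in ctx.roles.items() if r == "distributed"]

    src: List[str] = []
    A = src.append
    A(f"/* Simulation program generated by fdgen ({ctx.scheme.name} scheme). */")
    A("#include <stdio.h>")
    A("#include <stdlib.h>")
    A("#include <math.h>")
    A("")
    for name in diffvars:
        A(f"static double {name}_0_buf[{total}], {name}_1_buf[{total}];")
    for name in arithvars:
        A(f"static double {name}_0_buf[{total}];")
    for name in distvars:
        A(f"static double {name}_d_buf[{total}];")
    A("")
    A("int main(int argc, char **argv) {")
    A("    long steps = argc > 1 ? atol(argv[1]) : 1;")
    for name, value in renderer.deltas.items():
        A(f"    const double {name} = {value!r};")
    for name, value in sorted(ctx.consts.items()):
        A(f"    const double {name} = {float(value)!r};")
    for name in diffvars:
        A(f"    double *{name}_0 = {name}_0_buf, *{name}_1 = {name}_1_buf;")
    for name in arithvars:
        A(f"    double *{name}_0 = {name}_0_buf;")
    for name in distvars:
        A(f"    double *{name}_d = {name}_d_buf;")
    A(f"    for (long _i = 0; _i < {total}; _i++) {{")
    for name in diffvars:
        init = float(ctx.inits.get(name, 0.0))
        A(f"        {name}_0[_i] = {init!r}; {name}_1[_i] = {init!r};")
    for name in arithvars:
        A(f"        {name}_0[_i] = {float(ctx.inits.get(name, 0.0))!r};")
    A("    }")

    def flat(coord):
        f = str(coord[0])
        for a in range(1, ndim):
            f = f"({f})*{shape[a]} + {coord[a]}"
        return f

    for name in distvars:
        dist = ctx.dists.get(name)
        if dist is not None:
            for coord, value in dist.values:
                A(f"    {name}_d[{flat(coord)}] = {float(value)!r};")
    for name, coord, value in ctx.boundary_inits:
        reg: Dict[str, Var] = {}
        code = renderer.print_expr(to_sympy(value, reg), renderer.symmap(reg, {}))
        A(f"    {name}_0[{flat(coord)}] = {code}; {name}_1[{flat(coord)}] = {code};")
    for clamp in ctx.rel.clamps:
        A(f"    {clamp.var}_0[{flat(clamp.coord)}] = {float(clamp.value)!r};")
        A(f"    {clamp.var}_1[{flat(clamp.coord)}] = {float(clamp.value)!r};")
    A("")
    A("    for (long n = 0; n < steps; n++) {")
    A("        double t = n * dt;")
    A("        (void)t;")
    for block in blocks:
        target_code, rhs_code = _block_statements(block, ctx, renderer, solver)
        if block.kind == "stmt":
            A(f"        {target_code} = {rhs_code};")
        else:
            indent = "        "
            for a in range(ndim - 1, 0, -1):
                A(f"{indent}for (long {LOOP_SYMS[a]} = {block.lo[a]}; {LOOP_SYMS[a]} <= {block.hi[a]}; {LOOP_SYMS[a]}++)")
                indent += "    "
            A(f"{indent}for (long {LOOP_SYMS[0]} = {block.lo[0]}; {LOOP_SYMS[0]} <= {block.hi[0]}; {LOOP_SYMS[0]}++)")
            A(f"{indent}    {target_code} = {rhs_code};")
    for name in diffvars:
        A(f"        {{ double *_tmp = {name}_0; {name}_0 = {name}_1; {name}_1 = _tmp; }}")
    for clamp in ctx.rel.clamps:
        A(f"        {clamp.var}_1[{flat(clamp.coord)}] = {float(clamp.value)!r};")
    A("    }")
    A("")
    # final state dump: name,x,y,z,value
    idxvars = ["_x", "_y", "_z"][:ndim]
    indent = "    "
    for a in range(ndim):
        A(f"{indent}for (long {idxvars[a]} = 0; {idxvars[a]} < {shape[a]}; {idxvars[a]}++)")
        indent += "    "
    coords_out = ", ".join(idxvars + ["0L"] * (3 - ndim))
    flat_out = idxvars[0]
    for a in range(1, ndim):
        flat_out = f"({flat_out})*{shape[a]} + {idxvars[a]}"
    A(f"{indent}{{")
    for name in diffvars:
        A(f'{indent}    printf("{name},%ld,%ld,%ld,%.17g\\n", {coords_out}, {name}_0[{flat_out}]);')
    A(f"{indent}}}")
    A("    return 0;")
    A("}")

    meta = {"target": "c", "ndim": ndim, "shape": shape, "blocks": len(blocks)}
    return GeneratedProgram("\n".join(src), "c", meta)


# ---------------------------------------------------------------------------
# execution harness
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    finals: Dict[str, "object"]
    series: Dict[tuple, "object"]
    times: "object"
    steps: int

    def probe(self, name: str, coord: Coord):
        return self.series[(name, tuple(coord))]


def run_program(
    prog: GeneratedProgram,
    steps: int,
    probes: Optional[Sequence[Coord]] = None,
    record_every: Optional[int] = None,
) -> SimResult:
    """Execute a generated program and collect results.

    The host target runs in-process and is bit-identical across repeated
    runs (there is no randomness in the explicit path and a fixed Newton
    policy in the implicit path).  The C target requires a C compiler on
    PATH and reports final state only.
    """
    import numpy as np

    if prog.target == "host":
        ns: Dict[str, object] = {}
        exec(compile(prog.source, "<generated>", "exec"), ns)
        out = ns["simulate"](steps, probes=probes, record_every=record_every)
        finals = {k: np.array(v, dtype=float) for k, v in out["final"].items()}
        for name, arr in finals.items():
            if np.isnan(arr).any():
                raise RuntimeError(f"NaN in final state of {name!r} after {steps} steps")
        series = {k: np.array(v, dtype=float) for k, v in out["series"].items()}
        return SimResult(finals, series, np.array(out["times"], dtype=float), steps)
    if prog.target == "c":
        return _run_c(prog, steps)
    raise CodegenError(f"cannot run target {prog.target!r}")


def _run_c(prog: GeneratedProgram, steps: int) -> SimResult:
    import numpy as np
    import shutil
    import subprocess
    import tempfile
    import os

    cc = shutil.which("cc") or shutil.which("gcc")
    if cc is None:
        raise RuntimeError("no C compiler found on PATH; use the host target")
    with tempfile.TemporaryDirectory() as tmp:
        cpath = os.path.join(tmp, "sim.c")
        binpath = os.path.join(tmp, "sim")
        with open(cpath, "w") as fh:
            fh.write(prog.source)
        subprocess.run([cc, "-O2", "-o", binpath, cpath, "-lm"], check=True)
        out = subprocess.run([binpath, str(steps)], check=True,
                             capture_output=True, text=True).stdout
    shape = prog.metadata["shape"]
    ndim = prog.metadata["ndim"]
    finals: Dict[str, object] = {}
    for line in out.splitlines():
        name, x, y, z, value = line.split(",")
        arr = finals.setdefault(name, np.zeros(shape))
        idx = tuple(int(c) for c in (x, y, z)[:ndim])
        arr[idx] = float(value)
    return SimResult(finals, {}, np.array([steps]), steps)
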