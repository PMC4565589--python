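"""End-to-end orchestration: parse → discretize → instantiate → analyze → emit.

This is the programmatic spine of the tool; the command-line interface is a
thin wrapper around :func:`analyze_system` and :func:`generate`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import dependency as dep_mod
from .codegen import (
    CodegenContext,
    GeneratedProgram,
    LoopBlock,
    build_loops,
    emit_program,
    make_context,
)
from .discretize import (
    BoundaryEquation,
    DiscreteEquation,
    check_stability,
    discretize_boundary,
    discretize_model,
)
from .expressions import Idx, Num, Var
from .instantiate import EquationInstance, instantiate_boundary, instantiate_model
from .model import ModelDefinition
from .morphology import BoundaryNode, MorphologyGrid, detect_boundary_nodes
from .relation import RelationMap, validate_relation
from .schemes import SchemeSpec

log = logging.getLogger("fdgen")


@dataclass
class Analysis:
    model: ModelDefinition
    scheme: SchemeSpec
    rel: RelationMap
    grid: MorphologyGrid
    bnodes: List[BoundaryNode]
    deqs: List[DiscreteEquation]
    instances: List[EquationInstance]
    ctx: dep_mod.UnknownContext
    dep: dep_mod.DependencyGraph
    stability: Optional[object] = None
    ghost_completions: int = 0

    @property
    def n_equations(self) -> int:
        return len(self.instances)

    @property
    def n_unknowns(self) -> int:
        return len(self.dep.unknowns)

    def scc_sizes(self) -> List[int]:
        return self.dep.scc_sizes()


def _unknown_context(model, rel, grid, bnodes) -> dep_mod.UnknownContext:
    roles = {name: rel.scheme_type(name) for name in rel.mapping}
    has_init = {
        v.name for v in model.variables if v.role == "diff" and v.init is not None
    }
    material = set(grid.material_nodes())
    clamped = set()
    for b in bnodes:
        decl = rel.boundary[b.decl_index]
        if decl.condition == "dirichlet":
            step = 1 if b.direction == "-" else -1
            m = list(b.coord)
            m[b.axis] += step
            clamped.add((decl.var, tuple(m)))
    known_names = set(rel.params) | set(model.dims)
    for v in model.variables:
        if v.role == "const":
            known_names.add(v.name)
    return dep_mod.UnknownContext(roles, has_init, material, clamped, known_names)


def _apply_clamps(instances, model, rel, ndim) -> List[EquationInstance]:
    """Replace the time-update equation at each clamped node by a constant
    assignment at level n+1 (the level-n value is pinned by the initial
    condition and the two-level rotation)."""
    if not rel.clamps:
        return list(instances)
    drop = {(c.var, c.coord): c for c in rel.clamps}
    out = []
    for inst in instances:
        key = None
        for (var, coord), clamp in drop.items():
            if inst.node == coord and inst.label == f"eq_{var}":
                key = (var, coord)
        if key is None:
            out.append(inst)
    for c in rel.clamps:
        lhs = Var(c.var, (Idx("n", 1),) + tuple(c.coord[:ndim]))
        out.append(
            EquationInstance(lhs, Num(c.value), c.coord, f"clamp_{c.var}",
                             "clamp", kind="clamp")
        )
    return out


def _ghost_completion(exc, rel, grid, bnodes, ndim) -> List[EquationInstance]:
    """Assign declared Dirichlet values to unmatched ghost unknowns.

    When a Dirichlet boundary leaves a ghost value with no defining equation
    (the adjacent material equations are already spoken for), the declared
    boundary value is assigned to the ghost directly — the same completion
    the worked backward-time example needs for its ghost nodes at the new
    time level.
    """
    flags = grid.flags
    by_coord: Dict[tuple, object] = {}
    for b in bnodes:
        decl = rel.boundary[b.decl_index]
        if decl.condition == "dirichlet":
            by_coord.setdefault((decl.var, b.coord), decl)
    added = []
    for name, level, coords in exc.unmatched_unknowns:
        if level is None:
            continue
        if flags.get(coords) == 0 and (name, coords) in by_coord:
            decl = by_coord[(name, coords)]
            lhs = Var(name, (Idx("n", level),) + tuple(coords[:ndim]))
            added.append(
                EquationInstance(lhs, decl.value, coords,
                                 f"dirichlet_ghost_{name}", "ghost", kind="ghost")
            )
    return added


def analyze_system(
    model: ModelDefinition,
    scheme: SchemeSpec,
    rel: RelationMap,
    algorithm: str = "ford_fulkerson",
) -> Analysis:
    validate_relation(rel, model)
    grid = rel.load_grid()
    if grid.ndim != scheme.ndim:
        raise ValueError(
            f"grid is {grid.ndim}-D but scheme {scheme.name!r} is {scheme.ndim}-D"
        )
    ndim = grid.ndim
    dists = rel.load_distributed(grid)

    bnodes = detect_boundary_nodes(grid, scheme, rel.boundary)
    deqs = discretize_model(model, scheme, rel)
    log.info("discretized %d model equations", len(deqs))

    stability = None
    if not scheme.implicit:
        consts = {v.name: v.init for v in model.variables if v.role == "const"}
        consts.update({k: v for k, v in rel.params.items()})
        D = consts.get("D")
        if D is not None and "dt" in rel.params:
            stability = check_stability(
                scheme, float(rel.params["dt"]), float(grid.dx[0]), float(D), ndim
            )
            if not stability.passed:
                log.warning("stability: %s", stability.message)

    beqs: Dict[Tuple[int, int], List[BoundaryEquation]] = {}
    for b in bnodes:
        key = (b.bid, b.decl_index)
        if key not in beqs:
            decl = rel.boundary[b.decl_index]
            beqs[key] = discretize_boundary(decl, scheme, b.axis + 1, b.direction)

    instances = instantiate_model(deqs, grid, scheme)
    instances = _apply_clamps(instances, model, rel, ndim)
    instances += instantiate_boundary(beqs, bnodes, scheme)
    log.info("instantiated %d equations", len(instances))

    ctx = _unknown_context(model, rel, grid, bnodes)
    ghost_added = 0
    try:
        dep = dep_mod.analyze(instances, ctx, ndim, algorithm)
    except dep_mod.UnsolvableSystemError as exc:
        completions = _ghost_completion(exc, rel, grid, bnodes, ndim)
        if not completions:
            raise
        instances = instances + completions
        ghost_added = len(completions)
        log.info("added %d ghost value assignments for Dirichlet boundaries",
                 ghost_added)
        dep = dep_mod.analyze(instances, ctx, ndim, algorithm)

    log.info(
        "dependency analysis: %d unknowns, matching %d, %d SCCs (%d nontrivial)",
        len(dep.unknowns), len(dep.matching), len(dep.sccs),
        sum(1 for c in dep.sccs if len(c) > 1),
    )
    return Analysis(model, scheme, rel, grid, bnodes, deqs, dep.instances,
                    ctx, dep, stability, ghost_added)


def generate(
    model: ModelDefinition,
    scheme: SchemeSpec,
    rel: RelationMap,
    target: str = "host",
    unroll: bool = False,
    algorithm: str = "ford_fulkerson",
) -> Tuple[Analysis, GeneratedProgram]:
    analysis = analyze_system(model, scheme, rel, algorithm)
    blocks = build_loops(analysis.dep, analysis.grid.ndim, unroll=unroll)
    dists = rel.load_distributed(analysis.grid)
    ctx = make_context(model, scheme, rel, analysis.grid, dists, analysis.bnodes)
    prog = emit_program(blocks, ctx, target)
    log.info("emitted %s program: %s", target, prog.metadata)
    return analysis, prog
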