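"""Expansion of discrete equation templates into per-node instances.

Every discrete model equation is instantiated once per material node by
replacing its symbolic spatial indices with the node's coordinates; every
discrete boundary equation is instantiated at each boundary node carrying a
matching boundary ID.  Time indices stay symbolic (n / n+1) — the generated
program's time loop owns them.  Instantiation deliberately generates *all*
equations, one per node, with no loop shortcuts: loop reconstruction happens
later in code generation, which keeps this stage scheme- and
boundary-agnostic.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .expressions import Expr, Idx, Var, map_children, to_text
from .discretize import BoundaryEquation, DiscreteEquation
from .morphology import BoundaryNode, Coord, MorphologyGrid


class InstantiationError(ValueError):
    pass


@dataclass(frozen=True)
class EquationInstance:
    """A discrete equation bound to one concrete node.

    Spatial indices are concrete integers; the time index is still symbolic.
    ``unknown`` is filled by dependency analysis with the occurrence key this
    instance is matched to (and hence computes).
    """

    lhs: Expr
    rhs: Expr
    node: Coord
    label: str
    scheme: str
    bid: Optional[int] = None      # boundary ID for boundary instances
    kind: str = "model"            # 'model' | 'boundary' | 'clamp' | 'ghost'
    unknown: Optional[tuple] = None

    def text(self) -> str:
        return f"{to_text(self.lhs)} = {to_text(self.rhs)}"

    def with_unknown(self, key) -> "EquationInstance":
        return replace(self, unknown=key)


def _concretize(e: Expr, spatial: Dict[str, int]) -> Expr:
    """Replace symbolic spatial index entries with concrete integers."""

    def go(node):
        if isinstance(node, Var) and node.indices is not None:
            new = []
            changed = False
            for ix in node.indices:
                if isinstance(ix, Idx) and ix.base in spatial:
                    new.append(spatial[ix.base] + ix.offset)
                    changed = True
                else:
                    new.append(ix)
            return Var(node.name, tuple(new)) if changed else node
        return map_children(node, go)

    return go(e)


def instantiate_model(
    deqs: Sequence[DiscreteEquation], grid: MorphologyGrid, scheme
) -> List[EquationInstance]:
    """One instance per (material node, discrete equation), node-major:
    nodes iterate in lexicographic (z, y, x) order, equations in model order
    within each node."""
    space_syms = scheme.indices[1 : scheme.ndim + 1]
    out = []
    for node in grid.material_nodes():
        spatial = {sym: node[a] for a, sym in enumerate(space_syms)}
        for deq in deqs:
            out.append(
                EquationInstance(
                    _concretize(deq.lhs, spatial),
                    _concretize(deq.rhs, spatial),
                    node,
                    deq.label,
                    deq.scheme,
                )
            )
    return out


def instantiate_boundary(
    beqs: Dict[Tuple[int, int], Sequence[BoundaryEquation]],
    bnodes: Sequence[BoundaryNode],
    scheme,
) -> List[EquationInstance]:
    """Instantiate boundary templates at each boundary node.

    ``beqs`` maps (boundary ID, declaration index) to that declaration's
    discretized templates.  Templates anchored at ``material`` are
    instantiated at the material node adjacent to the ghost; ``ghost``
    templates at the ghost node itself.
    """
    space_syms = scheme.indices[1 : scheme.ndim + 1]
    out = []
    for b in bnodes:
        key = (b.bid, b.decl_index)
        if key not in beqs and (b.bid, -1) in beqs:
            key = (b.bid, -1)
        if key not in beqs:
            raise InstantiationError(
                f"no discrete boundary equation for boundary ID {b.bid} at {b.coord}"
            )
        step = 1 if b.direction == "-" else -1
        material = list(b.coord)
        material[b.axis] += step
        material = tuple(material)
        for beq in beqs[key]:
            anchor_node = material if beq.anchor == "material" else b.coord
            spatial = {sym: anchor_node[a] for a, sym in enumerate(space_syms)}
            out.append(
                EquationInstance(
                    _concretize(beq.equation.lhs, spatial),
                    _concretize(beq.equation.rhs, spatial),
                    anchor_node,
                    beq.equation.label,
                    beq.equation.scheme,
                    bid=b.bid,
                    kind="boundary",
                )
            )
    # distinct declarations can cover adjacent directions of one corner node
    # and would clamp the same material value twice; keep first occurrence
    seen = set()
    unique = []
    for inst in out:
        key = (to_text(inst.lhs), to_text(inst.rhs))
        if key in seen:
            continue
        seen.add(key)
        unique.append(inst)
    return unique
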