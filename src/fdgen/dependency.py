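"""Solvability check and computation ordering.

Dependency analysis confirms that the instantiated equation set can actually
be computed: every unknown variable occurrence must have exactly one equation
to define it (a perfect matching of the variable–equation bipartite graph),
and the directed graph induced by the matching must admit an evaluation
order (topological order of its strongly connected components).  Nontrivial
components are simultaneous equations — they arise when the model itself
contains algebraic loops or when an implicit finite-difference scheme couples
the new time level, and they are later handed to a Newton solver.

Two matching algorithms are selectable: a hand-written Ford–Fulkerson
augmenting-path search (the default; deterministic, and seeded so that an
equation whose left-hand side is a lone unknown is matched to it, which keeps
the generated code in the familiar "unknown on the left" arrangement) and
Hopcroft–Karp via networkx.  Both always return matchings of equal
cardinality; the choice only affects which valid assignment is found.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .expressions import Expr, Idx, Var, walk
from .instantiate import EquationInstance
from .morphology import Coord

# An occurrence key: (variable name, time level or None, spatial coordinates)
OccKey = Tuple[str, Optional[int], Tuple[int, ...]]


class UnsolvableSystemError(ValueError):
    def __init__(self, unmatched_unknowns, unmatched_equations, instances=None):
        self.unmatched_unknowns = list(unmatched_unknowns)
        self.unmatched_equations = list(unmatched_equations)
        parts = []
        if self.unmatched_unknowns:
            parts.append(
                "unmatched unknowns: "
                + ", ".join(format_occurrence(u) for u in self.unmatched_unknowns[:10])
                + (" ..." if len(self.unmatched_unknowns) > 10 else "")
            )
        if self.unmatched_equations:
            names = []
            for i in self.unmatched_equations[:10]:
                if instances is not None:
                    names.append(f"{instances[i].label}@{instances[i].node}")
                else:
                    names.append(str(i))
            parts.append("unmatched equations: " + ", ".join(names)
                         + (" ..." if len(self.unmatched_equations) > 10 else ""))
        super().__init__("no perfect variable-equation matching; " + "; ".join(parts))


def format_occurrence(key: OccKey) -> str:
    name, level, coords = key
    if level is None:
        return f"{name}[{','.join(map(str, coords))}]"
    lvl = "n" if level == 0 else f"n+{level}"
    return f"{name}[{lvl},{','.join(map(str, coords))}]"


@dataclass(frozen=True)
class UnknownContext:
    """Everything needed to decide whether an occurrence is known.

    Knowns: scalar constants and simulation parameters, distributed
    parameters, dimension/index/delta symbols, and level-n values of
    differential variables that have an initial condition at a material node
    — unless the node is Dirichlet-clamped, in which case the boundary
    equations own the value at every time level.
    """

    roles: Dict[str, str]            # model var -> diffvar|arithvar|constvar|distributed
    has_init: Set[str]               # diffvars with a declared initial value
    material: Set[Coord]
    clamped: Set[Tuple[str, Coord]]  # Dirichlet-clamped (variable, node)
    known_names: Set[str]            # constants, params, dims, deltas, indices


def iter_occurrences(e: Expr, ndim: int):
    """Yield occurrence keys for every indexed variable reference."""
    for node in walk(e):
        if isinstance(node, Var) and node.indices is not None:
            t0 = node.indices[0] if node.indices else None
            if isinstance(t0, Idx):
                level = t0.offset
                coords = tuple(int(c) for c in node.indices[1:])
            else:
                level = None
                coords = tuple(int(c) for c in node.indices)
            coords = coords + (0,) * (3 - len(coords))
            yield (node.name, level, coords)


def is_unknown(key: OccKey, ctx: UnknownContext) -> bool:
    name, level, coords = key
    if name in ctx.known_names:
        return False
    role = ctx.roles.get(name)
    if role in ("constvar", "distributed") or role is None:
        return False
    if role == "arithvar":
        return True
    # differential variable
    if (name, coords) in ctx.clamped:
        return True
    if level is None:
        return False
    if level >= 1:
        return True
    # level n: known iff it is a material node with an initial condition
    return not (coords in ctx.material and name in ctx.has_init)


def classify_unknowns(
    instances: Sequence[EquationInstance], ctx: UnknownContext, ndim: int
) -> List[OccKey]:
    """All unknown occurrences referenced anywhere in the instance set,
    in canonical sorted order."""
    unknowns = set()
    for inst in instances:
        for side in (inst.lhs, inst.rhs):
            for key in iter_occurrences(side, ndim):
                if is_unknown(key, ctx):
                    unknowns.add(key)
    return sorted(unknowns, key=_occ_sort_key)


def _occ_sort_key(key: OccKey):
    name, level, coords = key
    return (name, -1 if level is None else level, coords)


def instance_unknowns(inst: EquationInstance, ctx: UnknownContext, ndim: int) -> List[OccKey]:
    """Unknowns referenced by one instance, deduplicated, deterministic order."""
    seen = []
    for side in (inst.lhs, inst.rhs):
        for key in iter_occurrences(side, ndim):
            if is_unknown(key, ctx) and key not in seen:
                seen.append(key)
    return seen


def lhs_sole_unknown(inst: EquationInstance, ctx: UnknownContext, ndim: int) -> Optional[OccKey]:
    """The LHS occurrence if the LHS is exactly one unknown variable reference."""
    if isinstance(inst.lhs, Var) and inst.lhs.indices is not None:
        keys = list(iter_occurrences(inst.lhs, ndim))
        if len(keys) == 1 and is_unknown(keys[0], ctx):
            return keys[0]
    return None


# ---------------------------------------------------------------------------
# maximum matching
# ---------------------------------------------------------------------------

def ford_fulkerson_matching(
    adjacency: Sequence[Sequence[OccKey]],
    seeds: Optional[Dict[int, OccKey]] = None,
) -> Dict[int, OccKey]:
    """Augmenting-path maximum matching, equations → unknowns.

    ``adjacency[i]`` lists the unknowns of equation i in deterministic order.
    ``seeds`` pre-matches equations to their left-hand-side unknowns (the
    simultaneous-equation rule); seeds are honoured first-come and then the
    matching is extended to maximum by augmentation, so seeding never reduces
    cardinality.
    """
    match_eq: Dict[int, OccKey] = {}
    match_un: Dict[OccKey, int] = {}
    if seeds:
        for i in sorted(seeds):
            u = seeds[i]
            if u not in match_un and u in adjacency[i]:
                match_eq[i] = u
                match_un[u] = i

    def augment(i: int, visited: Set[OccKey]) -> bool:
        for u in adjacency[i]:
            if u in visited:
                continue
            visited.add(u)
            owner = match_un.get(u)
            if owner is None or augment(owner, visited):
                match_eq[i] = u
                match_un[u] = i
                return True
        return False

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000 + 5 * len(adjacency)))
    try:
        for i in range(len(adjacency)):
            if i not in match_eq:
                augment(i, set())
    finally:
        sys.setrecursionlimit(old_limit)
    return match_eq


def hopcroft_karp_matching(adjacency: Sequence[Sequence[OccKey]]) -> Dict[int, OccKey]:
    G = nx.Graph()
    eq_nodes = [("eq", i) for i in range(len(adjacency))]
    G.add_nodes_from(eq_nodes, bipartite=0)
    for i, unknowns in enumerate(adjacency):
        for u in unknowns:
            G.add_edge(("eq", i), ("un", u))
    if not G.edges:
        return {}
    m = nx.bipartite.hopcroft_karp_matching(G, top_nodes=eq_nodes)
    return {node[1]: partner[1] for node, partner in m.items() if node[0] == "eq"}


def maximum_matching(
    adjacency: Sequence[Sequence[OccKey]],
    algorithm: str = "ford_fulkerson",
    seeds: Optional[Dict[int, OccKey]] = None,
) -> Dict[int, OccKey]:
    if algorithm == "ford_fulkerson":
        return ford_fulkerson_matching(adjacency, seeds)
    if algorithm == "hopcroft_karp":
        return hopcroft_karp_matching(adjacency)
    raise ValueError(f"unknown matching algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# the dependency graph
# ---------------------------------------------------------------------------

@dataclass
class DependencyGraph:
    instances: List[EquationInstance]
    unknowns: List[OccKey]
    adjacency: List[List[OccKey]]          # per instance
    matching: Dict[int, OccKey]            # instance index -> matched unknown
    digraph: nx.DiGraph = field(default_factory=nx.DiGraph)
    sccs: List[List[int]] = field(default_factory=list)
    order: List[int] = field(default_factory=list)  # SCC indices in topological order

    @property
    def perfect(self) -> bool:
        return len(self.matching) == len(self.instances) == len(self.unknowns)

    def matched_instance(self, key: OccKey) -> int:
        return self._owner[key]

    def ordered_blocks(self) -> List[List[int]]:
        """Instance-index blocks (one per SCC) in computation order; instances
        inside a block keep ascending instance order."""
        return [sorted(self.sccs[s]) for s in self.order]

    def scc_sizes(self) -> List[int]:
        return [len(self.sccs[s]) for s in self.order]

    def to_dot(self) -> str:
        lines = ["digraph dependencies {", "  rankdir=LR;"]
        for i in sorted(self.matching):
            label = format_occurrence(self.matching[i])
            lines.append(f'  n{i} [label="{label}"];')
        for a, b in sorted(self.digraph.edges):
            lines.append(f"  n{a} -> n{b};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def analyze(
    instances: Sequence[EquationInstance],
    ctx: UnknownContext,
    ndim: int,
    algorithm: str = "ford_fulkerson",
    template_ids: Optional[Sequence[int]] = None,
) -> DependencyGraph:
    """Full dependency analysis: matching, SCCs, topological order.

    Raises :class:`UnsolvableSystemError` when no perfect matching exists —
    that is, whenever boundary coverage leaves a stencil read without a
    defining equation, or equations outnumber unknowns.
    """
    instances = list(instances)
    adjacency = [instance_unknowns(inst, ctx, ndim) for inst in instances]
    unknowns = sorted({u for a in adjacency for u in a}, key=_occ_sort_key)

    seeds = {}
    for i, inst in enumerate(instances):
        key = lhs_sole_unknown(inst, ctx, ndim)
        if key is not None:
            seeds[i] = key
    matching = maximum_matching(adjacency, algorithm, seeds)

    if len(matching) < len(instances) or len(matching) < len(unknowns):
        matched_un = set(matching.values())
        raise UnsolvableSystemError(
            [u for u in unknowns if u not in matched_un],
            [i for i in range(len(instances)) if i not in matching],
            instances,
        )

    owner = {u: i for i, u in matching.items()}
    G = nx.DiGraph()
    G.add_nodes_from(range(len(instances)))
    for i, deps in enumerate(adjacency):
        for u in deps:
            j = owner[u]
            if j != i:
                G.add_edge(j, i)

    sccs = [sorted(c) for c in nx.strongly_connected_components(G)]
    sccs.sort(key=lambda c: min(c))
    order = _topological_order(G, sccs, instances, template_ids)

    graph = DependencyGraph(instances, unknowns, adjacency, matching, G, sccs, order)
    graph._owner = owner
    # annotate instances with their matched unknowns
    graph.instances = [
        inst.with_unknown(matching[i]) for i, inst in enumerate(instances)
    ]
    return graph


def _topological_order(G, sccs, instances, template_ids) -> List[int]:
    """Layered topological order of the SCC condensation.

    Blocks are ranked by their longest-path depth from the sources (every
    dependency edge strictly increases depth, so sorting by depth is a valid
    topological order); within a layer, ties break by (equation template,
    instance index).  The layering keeps all instances of one template over
    consecutive nodes adjacent, which is what lets loop reconstruction
    recover compact loops instead of interleaved singletons.
    """
    if template_ids is None:
        by_label = {}
        template_ids = []
        for inst in instances:
            key = (inst.label, inst.kind, inst.bid)
            if key not in by_label:
                by_label[key] = len(by_label)
            template_ids.append(by_label[key])

    scc_of = {}
    for s, comp in enumerate(sccs):
        for i in comp:
            scc_of[i] = s
    indeg = [0] * len(sccs)
    cond_edges = [set() for _ in sccs]
    for a, b in G.edges:
        sa, sb = scc_of[a], scc_of[b]
        if sa != sb and sb not in cond_edges[sa]:
            cond_edges[sa].add(sb)
            indeg[sb] += 1

    depth = [0] * len(sccs)
    queue = [s for s in range(len(sccs)) if indeg[s] == 0]
    seen = 0
    while queue:
        nxt = []
        for s in queue:
            seen += 1
            for t in cond_edges[s]:
                depth[t] = max(depth[t], depth[s] + 1)
                indeg[t] -= 1
                if indeg[t] == 0:
                    nxt.append(t)
        queue = nxt
    if seen != len(sccs):  # pragma: no cover - condensation is acyclic
        raise RuntimeError("cycle in SCC condensation")

    def key_of(s):
        i = min(sccs[s])
        return (depth[s], template_ids[i], i)

    return sorted(range(len(sccs)), key=key_of)


def find_sccs(G: nx.DiGraph) -> List[List[int]]:
    """Strongly connected components (Tarjan-style) of a directed graph."""
    comps = [sorted(c) for c in nx.strongly_connected_components(G)]
    comps.sort(key=lambda c: min(c))
    return comps
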