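"""Geometry, boundary-node and distributed-parameter handling.

A morphology is a rectilinear lattice of integer-coordinate nodes, each
flagged ``1`` (material: part of the simulated tissue) or ``0`` (background /
empty space).  Boundary nodes are the background nodes stencil-adjacent to
material; each carries a boundary-condition ID encoding its direction
relative to the material and the declared condition type.  All coordinates
are stored as three-dimensional tuples with unused axes fixed at zero, and
physical position is ``index * dx`` per axis.

The CSV formats are deliberately plain: ``geometry.csv`` rows are
``x,y,z,flag``; ``boundary.csv`` rows are ``x,y,z,boundaryID``;
``param_<NAME>.csv`` rows are ``x,y,z,value``.  A header row is optional and
auto-detected.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

Coord = Tuple[int, int, int]


class MorphologyError(ValueError):
    pass


@dataclass(frozen=True)
class MorphologyGrid:
    ndim: int
    nodes: Tuple[Tuple[Coord, int], ...]  # (coordinate, material flag), sorted
    dx: Tuple[float, ...] = (1.0,)        # spatial step per spatial axis

    def __post_init__(self):
        coords = [c for c, _ in self.nodes]
        if len(coords) != len(set(coords)):
            raise MorphologyError("duplicate node coordinates")
        for c, f in self.nodes:
            if f not in (0, 1):
                raise MorphologyError(f"morphology value must be 0 or 1, got {f} at {c}")

    @property
    def flags(self) -> Dict[Coord, int]:
        return dict(self.nodes)

    def material_nodes(self) -> List[Coord]:
        """Material coordinates in deterministic node-major order: sorted by
        (z, y, x) so the x index varies fastest."""
        return sorted((c for c, f in self.nodes if f == 1), key=lambda c: (c[2], c[1], c[0]))

    def extents(self) -> Tuple[Tuple[int, int], ...]:
        """(min, max) per axis over all listed nodes."""
        coords = [c for c, _ in self.nodes]
        return tuple(
            (min(c[a] for c in coords), max(c[a] for c in coords)) for a in range(3)
        )

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(hi + 1 for _, hi in self.extents()[: max(self.ndim, 1)])


@dataclass(frozen=True)
class BoundaryNode:
    coord: Coord
    bid: int
    axis: int = 0          # 0-based spatial axis of adjacency
    direction: str = "-"   # side of the material the node sits on
    decl_index: int = -1   # index of the covering condition declaration


@dataclass(frozen=True)
class DistributedParameter:
    """Per-node values of a location-dependent constant; unlisted nodes are 0."""

    name: str
    values: Tuple[Tuple[Coord, float], ...] = ()

    def value_at(self, coord: Coord) -> float:
        for c, v in self.values:
            if c == coord:
                return v
        return 0.0

    def as_dict(self) -> Dict[Coord, float]:
        return dict(self.values)


# ---------------------------------------------------------------------------
# synthetic meshes
# ---------------------------------------------------------------------------

def make_line_mesh(length: int, dx: float = 1.0) -> MorphologyGrid:
    """A 1-D line of ``length`` material nodes padded by one background node
    on each end (coordinates 0..length+1, material at 1..length)."""
    if length < 1:
        raise MorphologyError("length must be >= 1")
    nodes = tuple(
        ((i, 0, 0), 1 if 1 <= i <= length else 0) for i in range(length + 2)
    )
    return MorphologyGrid(1, nodes, (dx,))


def make_square_mesh(side: int, dx: float = 1.0) -> MorphologyGrid:
    """A 2-D ``side`` × ``side`` material block padded with one background
    layer on every face (material coordinates 1..side per axis)."""
    if side < 1:
        raise MorphologyError("side must be >= 1")
    nodes = []
    for y in range(side + 2):
        for x in range(side + 2):
            flag = 1 if (1 <= x <= side and 1 <= y <= side) else 0
            nodes.append(((x, y, 0), flag))
    return MorphologyGrid(2, tuple(nodes), (dx, dx))


def make_box_mesh(side: int, dx: float = 1.0) -> MorphologyGrid:
    """3-D analog of :func:`make_square_mesh`."""
    if side < 1:
        raise MorphologyError("side must be >= 1")
    nodes = []
    for z in range(side + 2):
        for y in range(side + 2):
            for x in range(side + 2):
                flag = 1 if all(1 <= c <= side for c in (x, y, z)) else 0
                nodes.append(((x, y, z), flag))
    return MorphologyGrid(3, tuple(nodes), (dx, dx, dx))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv(path, ncols: int, colnames) -> pd.DataFrame:
    # header auto-detection: if the first row fails numeric conversion it is
    # treated as a header
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=colnames)
    if df.shape[1] != ncols:
        raise MorphologyError(
            f"{path}: expected {ncols} columns, found {df.shape[1]}"
        )
    try:
        df = df.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
        try:
            df = df.astype(float)
        except (ValueError, TypeError) as exc:
            raise MorphologyError(f"{path}: non-numeric data row: {exc}") from exc
    if df.isna().any().any():
        raise MorphologyError(f"{path}: ragged or missing values")
    df.columns = colnames
    return df


def read_geometry_csv(path, dx: float | Sequence[float] = 1.0,
                      ndim: Optional[int] = None) -> MorphologyGrid:
    """Load a geometry node list (rows ``x,y,z,flag``)."""
    df = _read_csv(path, 4, ["x", "y", "z", "flag"])
    nodes = []
    for row in df.itertuples(index=False):
        coord = (int(row.x), int(row.y), int(row.z))
        flag = row.flag
        if flag not in (0.0, 1.0):
            raise MorphologyError(f"{path}: morphology value must be 0 or 1, got {flag}")
        nodes.append((coord, int(flag)))
    if ndim is None:
        ndim = _infer_ndim([c for c, _ in nodes])
    if isinstance(dx, (int, float)):
        dx = (float(dx),) * ndim
    return MorphologyGrid(ndim, tuple(sorted(nodes, key=lambda n: (n[0][2], n[0][1], n[0][0]))),
                          tuple(dx))


def _infer_ndim(coords: Iterable[Coord]) -> int:
    coords = list(coords)
    ndim = 1
    if any(c[1] != 0 for c in coords):
        ndim = 2
    if any(c[2] != 0 for c in coords):
        ndim = 3
    return ndim


def write_geometry_csv(grid: MorphologyGrid, path) -> None:
    df = pd.DataFrame(
        [(c[0], c[1], c[2], f) for c, f in grid.nodes], columns=["x", "y", "z", "flag"]
    )
    df.to_csv(path, index=False)


def read_distributed_parameter_csv(path, grid: MorphologyGrid,
                                   name: Optional[str] = None) -> DistributedParameter:
    """Load per-node values for one distributed parameter.

    Unlisted material nodes default to zero; coordinates outside the grid and
    duplicate rows are errors.
    """
    df = _read_csv(path, 4, ["x", "y", "z", "value"])
    flags = grid.flags
    seen = set()
    values = []
    for row in df.itertuples(index=False):
        coord = (int(row.x), int(row.y), int(row.z))
        if coord not in flags:
            raise MorphologyError(f"{path}: coordinate {coord} not in the grid")
        if coord in seen:
            raise MorphologyError(f"{path}: duplicate coordinate {coord}")
        seen.add(coord)
        values.append((coord, float(row.value)))
    pname = name or str(path)
    return DistributedParameter(pname, tuple(sorted(values, key=lambda v: (v[0][2], v[0][1], v[0][0]))))


def write_boundary_csv(bnodes: Sequence[BoundaryNode], path) -> None:
    df = pd.DataFrame(
        [(b.coord[0], b.coord[1], b.coord[2], b.bid) for b in bnodes],
        columns=["x", "y", "z", "boundaryID"],
    )
    df.to_csv(path, index=False)


def read_boundary_csv(path) -> List[BoundaryNode]:
    from .schemes import decode_boundary_id

    df = _read_csv(path, 4, ["x", "y", "z", "bid"])
    out = []
    for row in df.itertuples(index=False):
        bid = int(row.bid)
        dim_pos, direction, _cond = decode_boundary_id(bid)
        out.append(
            BoundaryNode((int(row.x), int(row.y), int(row.z)), bid, dim_pos - 1, direction)
        )
    return out


# ---------------------------------------------------------------------------
# boundary-node detection
# ---------------------------------------------------------------------------

def _unit(axis: int) -> Coord:
    e = [0, 0, 0]
    e[axis] = 1
    return tuple(e)  # type: ignore[return-value]


def adjacent_pairs(grid: MorphologyGrid):
    """Yield (background coordinate, axis, direction) for every background
    node read by a per-dimension three-point stencil centred on material.

    ``direction`` '-' means the background node sits on the low-coordinate
    side of its material neighbour.  Diagonal-only neighbours are never
    yielded: the per-dimension stencil does not read them.
    """
    flags = grid.flags
    for coord, flag in grid.nodes:
        if flag != 0:
            continue
        for axis in range(grid.ndim):
            e = _unit(axis)
            up = tuple(c + d for c, d in zip(coord, e))
            dn = tuple(c - d for c, d in zip(coord, e))
            if flags.get(up) == 1:
                yield coord, axis, "-"
            if flags.get(dn) == 1:
                yield coord, axis, "+"


def detect_boundary_nodes(grid: MorphologyGrid, scheme, conditions) -> List[BoundaryNode]:
    """Assign a boundary ID to every (background node, adjacent direction).

    ``conditions`` is a sequence of declarations with ``matches(coord, axis,
    direction)``, a ``condition`` attribute ('dirichlet'/'neumann'), and the
    axis/direction they cover (see :class:`fdgen.relation.BoundaryDecl`).
    Every adjacency must be covered by exactly one declaration; uncovered or
    doubly-covered adjacencies raise with the offending coordinates.
    """
    from .schemes import boundary_id

    out = []
    for coord, axis, direction in sorted(
        adjacent_pairs(grid), key=lambda p: (p[0][2], p[0][1], p[0][0], p[1], p[2])
    ):
        covering = [
            (i, decl)
            for i, decl in enumerate(conditions)
            if decl.matches(coord, axis, direction)
        ]
        if not covering:
            raise MorphologyError(
                f"boundary node {coord} (axis {axis}, side {direction!r}) is not "
                f"covered by any boundary-condition declaration"
            )
        if len(covering) > 1:
            raise MorphologyError(
                f"conflicting boundary declarations for node {coord}: "
                f"{[i for i, _ in covering]}"
            )
        idx, decl = covering[0]
        bid = boundary_id(axis + 1, direction, decl.condition)
        out.append(BoundaryNode(coord, bid, axis, direction, idx))
    return out
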