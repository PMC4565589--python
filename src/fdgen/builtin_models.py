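"""Built-in model and relation fixtures.

Three models ship with the package:

* the three-equation membrane potential propagation example (a diffusive
  voltage V driven by an ionic current I and a time-gated, spatially
  distributed stimulus J) used throughout the boundary-condition and
  dependency-analysis studies;
* the FitzHugh–Nagumo (FHN) excitable-cell model in dimensionless form,
  with a voltage-like variable V, recovery (gating) variable W, and the
  standard parameter set ϵ = 0.03, β = 1.2, γ = 0.3;
* a bare linear diffusion model for numerical-accuracy studies.

Relations for common study setups (line meshes with Neumann or Dirichlet
ends; padded square meshes with a centre stimulus clamp) are built
programmatically so every fixture is reproducible from code alone.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .expressions import Num, Var, parse_expression
from .model import ModelDefinition, parse_model
from .relation import BoundaryDecl, Clamp, RelationMap

MEMBRANE_MODEL_SRC = """\
# membrane potential propagation example: dV/dt = -I, I = J + D d2V/dx2
dim t x
var V diff 0.0
var I arith
var J arith
var D const 1.0
var C dist
d(V)/d(t) = -I
I = J + D * d2(V)/d(x)2
J = piecewise(0 <= t <= 10: C, otherwise: 0)
"""

MEMBRANE_MAPPING = {
    "V": "diffvar",
    "I": "arithvar",
    "J": "arithvar",
    "D": "constvar",
    "C": "distributed",
}

FHN_EPS = 0.03
FHN_BETA = 1.2
FHN_GAMMA = 0.3


def fhn_rest_state() -> Tuple[float, float]:
    """The resting fixed point of the FHN model.

    Setting both time derivatives to zero and eliminating W gives the cubic
    V^3 + 7V + 12 = 0 (for ϵ=0.03, β=1.2, γ=0.3); its single real root is the
    resting potential, W follows from the W-nullcline W = (V + β)/γ.
    """
    roots = np.roots([1.0, 0.0, 7.0, 12.0])
    v = float(roots[np.abs(roots.imag).argmin()].real)
    w = (v + FHN_BETA) / FHN_GAMMA
    return v, w


def fhn_model(ndim: int = 2, init_at_rest: bool = True) -> ModelDefinition:
    """The FitzHugh–Nagumo model with per-dimension diffusion of V."""
    if init_at_rest:
        v0, w0 = fhn_rest_state()
    else:
        v0, w0 = 0.0, 0.0
    dims = ("t", "x", "y", "z")[: ndim + 1]
    lap = " + ".join(f"d2(V)/d({d})2" for d in dims[1:])
    src = f"""\
dim {' '.join(dims)}
var V diff {v0!r}
var W diff {w0!r}
var J const 0
var D const 1.0
var eps const {FHN_EPS}
var beta const {FHN_BETA}
var gamma const {FHN_GAMMA}
d(V)/d(t) = V - V^3/3 - W + J + D*({lap})
d(W)/d(t) = eps*(V + beta - gamma*W)
"""
    return parse_model(src)


FHN_MAPPING = {
    "V": "diffvar",
    "W": "diffvar",
    "J": "constvar",
    "D": "constvar",
    "eps": "constvar",
    "beta": "constvar",
    "gamma": "constvar",
}


def diffusion_model(ndim: int = 1, init: float = 0.0) -> ModelDefinition:
    dims = ("t", "x", "y", "z")[: ndim + 1]
    lap = " + ".join(f"d2(V)/d({d})2" for d in dims[1:])
    src = f"""\
dim {' '.join(dims)}
var V diff {init!r}
var D const 1.0
d(V)/d(t) = D*({lap})
"""
    return parse_model(src)


DIFFUSION_MAPPING = {"V": "diffvar", "D": "constvar"}


def membrane_model() -> ModelDefinition:
    return parse_model(MEMBRANE_MODEL_SRC)


def membrane_relation(
    boundary: str = "neumann",
    length: int = 3,
    dt: float = 0.1,
    dx: float = 1.0,
    D: float = 1.0,
    a: float = 1.0,
    b: float = 0.0,
    c_value: float = 1.0,
) -> RelationMap:
    """Relation for the worked 1-D example: a line of ``length`` material
    nodes, the stimulus amplitude C supplied only at the first material node
    (the rest default to zero), and either zero-flux Neumann or fixed-value
    Dirichlet conditions V(0)=a, V(L)=b at the two ends."""
    if boundary == "neumann":
        decls = [
            BoundaryDecl("V", "neumann", Num(0), axis=0, side="-"),
            BoundaryDecl("V", "neumann", Num(0), axis=0, side="+"),
        ]
    elif boundary == "dirichlet":
        decls = [
            BoundaryDecl("V", "dirichlet", Var("a"), axis=0, side="-"),
            BoundaryDecl("V", "dirichlet", Var("b"), axis=0, side="+"),
        ]
    else:
        raise ValueError(f"unknown boundary kind {boundary!r}")
    return RelationMap(
        mapping=dict(MEMBRANE_MAPPING),
        geometry=("line", length),
        boundary=decls,
        inline_distributed={"C": (((1, 0, 0), c_value),)},
        params={"dt": dt, "D": D, "a": a, "b": b},
        dx=dx,
    )


def diffusion_relation(
    boundary: str = "neumann",
    length: int = 5,
    ndim: int = 1,
    dt: float = 0.1,
    dx: float = 1.0,
    D: float = 1.0,
    a: float = 0.0,
    b: float = 0.0,
) -> RelationMap:
    if boundary == "neumann":
        decls = [
            BoundaryDecl("V", "neumann", Num(0), axis=ax, side=s)
            for ax in range(ndim)
            for s in ("-", "+")
        ]
    else:
        decls = [
            BoundaryDecl("V", "dirichlet", Var("a"), axis=0, side="-"),
            BoundaryDecl("V", "dirichlet", Var("b"), axis=0, side="+"),
        ] + [
            BoundaryDecl("V", "dirichlet", Var("a"), axis=ax, side=s)
            for ax in range(1, ndim)
            for s in ("-", "+")
        ]
    geometry = ("line", length) if ndim == 1 else ("square", length)
    return RelationMap(
        mapping=dict(DIFFUSION_MAPPING),
        geometry=geometry,
        boundary=decls,
        params={"dt": dt, "D": D, "a": a, "b": b},
        dx=dx,
    )


def fhn_relation(
    boundary: str = "neumann",
    side: int = 25,
    dt: float = 0.001,
    dx: float = 1.0,
    D: float = 200.0,
    stimulus: float = -1.0,
    dirichlet_value: float = -1.7,
    clamp_center: bool = True,
) -> RelationMap:
    """Relation for the two-dimensional FHN cell-to-cell coupling study:
    a ``side`` × ``side`` square tissue, a fixed subthreshold stimulus
    (V clamped to −1.0) at the mesh centre, and either zero-flux Neumann
    boundaries or Dirichlet boundaries holding V at −1.7."""
    if side % 2 == 0:
        raise ValueError("side must be odd so a centre node exists")
    if boundary == "neumann":
        decls = [
            BoundaryDecl("V", "neumann", Num(0), axis=ax, side=s)
            for ax in (0, 1)
            for s in ("-", "+")
        ]
    elif boundary == "dirichlet":
        decls = [
            BoundaryDecl("V", "dirichlet", Var("Vb"), axis=ax, side=s)
            for ax in (0, 1)
            for s in ("-", "+")
        ]
    else:
        raise ValueError(f"unknown boundary kind {boundary!r}")
    center = 1 + side // 2
    clamps = [Clamp("V", (center, center, 0), stimulus)] if clamp_center else []
    return RelationMap(
        mapping=dict(FHN_MAPPING),
        geometry=("square", side),
        boundary=decls,
        params={"dt": dt, "D": D, "Vb": dirichlet_value},
        clamps=clamps,
        dx=dx,
    )
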