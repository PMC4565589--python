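"""Discretization fidelity: variable/operator replacement and boundaries."""
import pytest
import sympy as sp

from fdgen.builtin_models import membrane_model, membrane_relation
from fdgen.codegen import to_sympy
from fdgen.discretize import (
    DiscretizationError,
    check_stability,
    discretize_boundary,
    discretize_equation,
    discretize_model,
)
from fdgen.expressions import parse_expression, to_text
from fdgen.model import Equation, parse_model
from fdgen.relation import BoundaryDecl, RelationMap
from fdgen.schemes import builtin_scheme


def _equiv(a_text, b_text):
    reg = {}
    a = to_sympy(parse_expression(a_text), reg)
    b = to_sympy(parse_expression(b_text), reg)
    return sp.simplify(a - b) == 0


def _eq_equiv(deq, lhs_text, rhs_text):
    """Symbolic term-by-term equality after canonicalization: the residual
    (lhs - rhs) of both equations must be identical."""
    reg = {}
    got = to_sympy(deq.lhs, reg) - to_sympy(deq.rhs, reg)
    want = to_sympy(parse_expression(lhs_text), reg) - to_sympy(
        parse_expression(rhs_text), reg
    )
    return sp.simplify(got - want) == 0


@pytest.fixture(scope="module")
def membrane_deqs():
    model = membrane_model()
    rel = membrane_relation("neumann")
    return discretize_model(model, builtin_scheme("FTCS", 1), rel)


class TestModelDiscretization:
    def test_time_update_equation(self, membrane_deqs):
        # dV/dt = -I  ->  (V[n+1,j] - V[n,j])/dt = -I[n,j]
        assert _eq_equiv(membrane_deqs[0], "(V[n+1,j] - V[n,j])/dt", "-I[n,j]")

    def test_current_equation_with_stencil(self, membrane_deqs):
        assert _eq_equiv(
            membrane_deqs[1],
            "I[n,j]",
            "J[n,j] + D*(V[n,j+1] - 2*V[n,j] + V[n,j-1])/dx^2",
        )

    def test_distributed_parameter_is_time_free(self, membrane_deqs):
        # the stimulus amplitude C discretizes to a spatial-only reference
        assert "C[j]" in membrane_deqs[2].text()
        assert membrane_deqs[2].time_shift is False

    def test_no_derivatives_remain_and_names_are_retained(self, membrane_deqs):
        for deq in membrane_deqs:
            text = deq.text()
            assert "d(" not in text and "d2(" not in text
        assert "V[" in membrane_deqs[1].text()  # model names, not scheme symbols

    def test_membrane_potential_propagation_equation(self):
        """The full 1-D propagation equation under FTCS: forward difference in
        time, three-point second difference in space, reaction at level n."""
        src = """\
dim t x
var V diff 0.0
var I arith
var J arith
var D const 1.0
var Cm const 1.0
d(V)/d(t) = D * d2(V)/d(x)2 - (I + J)/Cm
I = V
J = V
"""
        model = parse_model(src)
        rel = RelationMap(
            mapping={"V": "diffvar", "I": "arithvar", "J": "arithvar",
                     "D": "constvar", "Cm": "constvar"},
            geometry=("line", 3),
            params={"dt": 0.1},
        )
        deq = discretize_model(model, builtin_scheme("FTCS", 1), rel)[0]
        assert _eq_equiv(
            deq,
            "(V[n+1,j] - V[n,j])/dt",
            "D*(V[n,j+1] - 2*V[n,j] + V[n,j-1])/dx^2 - (I[n,j] + J[n,j])/Cm",
        )

    def test_constants_only_equation(self):
        eq = Equation(parse_expression("y"), parse_expression("z"), "eq_y")
        rel = RelationMap(mapping={"y": "arithvar", "z": "constvar"},
                          geometry=("line", 1))
        deq = discretize_equation(eq, builtin_scheme("FTCS", 1), rel, ("t", "x"))
        assert deq.text() == "y[n, j] = z"

    def test_linearity_over_equation_structure(self):
        rel = RelationMap(mapping={"u": "arithvar", "w": "arithvar", "s": "arithvar"},
                          geometry=("line", 1))
        scheme = builtin_scheme("FTCS", 1)
        a = Equation(parse_expression("s"), parse_expression("u"), "ea")
        b = Equation(parse_expression("s"), parse_expression("w"), "eb")
        ab = Equation(parse_expression("s"), parse_expression("u + w"), "eab")
        da = discretize_equation(a, scheme, rel, ("t", "x"))
        db = discretize_equation(b, scheme, rel, ("t", "x"))
        dab = discretize_equation(ab, scheme, rel, ("t", "x"))
        assert to_text(dab.rhs) == f"{to_text(da.rhs)} + {to_text(db.rhs)}"

    def test_idempotence_on_discrete_input(self, membrane_deqs):
        """Re-running the replacement on an already-discrete equation is the
        identity: there are no bare variables or derivative operators left."""
        rel = membrane_relation("neumann")
        scheme = builtin_scheme("FTCS", 1)
        deq = membrane_deqs[1]
        again = discretize_equation(
            Equation(deq.lhs, deq.rhs, deq.label), scheme, rel, ("t", "x")
        )
        assert (again.lhs, again.rhs) == (deq.lhs, deq.rhs)

    def test_missing_operator_rule_reports_order_and_dimension(self):
        rel = RelationMap(mapping={"V": "diffvar"}, geometry=("line", 1))
        eq = Equation(parse_expression("V"), parse_expression("d3(V)/d(x)3"), "e")
        with pytest.raises(DiscretizationError, match="order-3.*'x'"):
            discretize_equation(eq, builtin_scheme("FTCS", 1), rel, ("t", "x"))


class TestBoundaryDiscretization:
    def test_neumann_one_sided_differences(self):
        scheme = builtin_scheme("FTCS", 1)
        decl = BoundaryDecl("V", "neumann", parse_expression("0"), axis=0, side="-")
        (left,) = discretize_boundary(decl, scheme, 1, "-")
        assert _eq_equiv(left.equation, "(V[n,j-1] - V[n,j])/dx", "0")
        assert left.level == 0 and left.anchor == "material"
        decl_r = BoundaryDecl("V", "neumann", parse_expression("0"), axis=0, side="+")
        (right,) = discretize_boundary(decl_r, scheme, 1, "+")
        assert _eq_equiv(right.equation, "(V[n,j] - V[n,j+1])/dx", "0")

    def test_dirichlet_explicit_covers_both_levels(self):
        scheme = builtin_scheme("FTCS", 1)
        decl = BoundaryDecl("V", "dirichlet", parse_expression("a"), axis=0, side="-")
        eqs = discretize_boundary(decl, scheme, 1, "-")
        assert [(b.level, b.anchor) for b in eqs] == [(0, "material"), (1, "material")]
        assert eqs[0].equation.text() == "V[n, j] = a"
        assert eqs[1].equation.text() == "V[n+1, j] = a"

    def test_dirichlet_implicit_is_new_level_only(self):
        scheme = builtin_scheme("BTCS", 1)
        decl = BoundaryDecl("V", "dirichlet", parse_expression("a"), axis=0, side="-")
        eqs = discretize_boundary(decl, scheme, 1, "-")
        assert [(b.level, b.anchor) for b in eqs] == [(1, "material")]

    def test_crank_nicolson_boundaries_cover_both_levels(self):
        scheme = builtin_scheme("CN", 1)
        decl = BoundaryDecl("V", "neumann", parse_expression("0"), axis=0, side="-")
        eqs = discretize_boundary(decl, scheme, 1, "-")
        assert sorted(b.level for b in eqs) == [0, 1]


class TestStability:
    def test_fhn_study_parameters_pass(self):
        # dt = 0.001, dx = 1, D = 200, two dimensions: bound 1/(2*2*200)
        r = check_stability(builtin_scheme("FTCS", 2), 0.001, 1.0, 200.0, 2)
        assert r.passed and r.bound == pytest.approx(0.00125)

    def test_zero_diffusion_always_passes(self):
        r = check_stability(builtin_scheme("FTCS", 1), 10.0, 1.0, 0.0, 1)
        assert r.passed

    def test_bound_is_inclusive(self):
        r = check_stability(builtin_scheme("FTCS", 1), 0.5, 1.0, 1.0, 1)
        assert r.bound == 0.5 and r.passed

    def test_violation_warns_and_quotes_both_forms(self):
        r = check_stability(builtin_scheme("FTCS", 1), 1.0, 1.0, 1.0, 1)
        assert not r.passed
        assert "(dx)^2/(2 d D)" in r.message and "dx/(2 d D)" in r.message

    def test_implicit_scheme_unconditional(self):
        r = check_stability(builtin_scheme("BTCS", 1), 100.0, 1.0, 100.0, 1)
        assert r.passed
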