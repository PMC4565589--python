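"""Scheme descriptions: built-in stencils, validation, file round-trips."""
import importlib.resources

import pytest
import sympy as sp

from fdgen.codegen import to_sympy
from fdgen.expressions import Idx, Var, parse_expression, walk
from fdgen.schemes import (
    SchemeError,
    boundary_id,
    builtin_scheme,
    decode_boundary_id,
    parse_scheme,
    serialize_scheme,
)


def _sym(e):
    return to_sympy(e, {})


def _equiv(a, b):
    return sp.simplify(_sym(a) - _sym(b)) == 0


class TestBuiltinStencils:
    def test_ftcs_matches_forward_time_centred_space(self):
        s = builtin_scheme("FTCS", 1)
        assert _equiv(s.operator_rule(1, 0), parse_expression("(v[n+1,j]-v[n,j])/dt"))
        assert _equiv(
            s.operator_rule(2, 1),
            parse_expression("(v[n,j+1] - 2*v[n,j] + v[n,j-1])/dx^2"),
        )
        assert not s.implicit

    def test_btcs_spatial_stencil_at_new_level(self):
        s = builtin_scheme("BTCS", 1)
        assert _equiv(
            s.operator_rule(2, 1),
            parse_expression("(v[n+1,j+1] - 2*v[n+1,j] + v[n+1,j-1])/dx^2"),
        )
        assert s.implicit

    def test_crank_nicolson_averages_levels(self):
        s = builtin_scheme("CN", 1)
        expected = parse_expression(
            "(v[n,j+1] - 2*v[n,j] + v[n,j-1])/(2*dx^2)"
            " + (v[n+1,j+1] - 2*v[n+1,j] + v[n+1,j-1])/(2*dx^2)"
        )
        assert _equiv(s.operator_rule(2, 1), expected)
        assert s.implicit

    @pytest.mark.parametrize("name", ["FTCS", "BTCS", "CN"])
    def test_stencil_coefficients_sum_to_zero(self, name):
        # a difference approximation of a derivative must vanish on constants
        s = builtin_scheme(name, 1)
        one = Var("one")
        for rule in s.op_rules.values():
            reg = {}
            expr = to_sympy(rule, reg)
            subs = {sp.Symbol(k, real=True): 1.0 for k, v in reg.items()
                    if v.indices is not None}
            assert sp.simplify(expr.subs(subs)) == 0

    def test_swapping_ftcs_for_btcs_changes_only_time_indices(self):
        f = builtin_scheme("FTCS", 1).operator_rule(2, 1)
        b = builtin_scheme("BTCS", 1).operator_rule(2, 1)

        def spatial_offsets(rule):
            return sorted(
                ix.offset
                for node in walk(rule)
                if isinstance(node, Var) and node.indices
                for ix in node.indices[1:]
                if isinstance(ix, Idx)
            )

        def time_offsets(rule):
            return sorted(
                node.indices[0].offset
                for node in walk(rule)
                if isinstance(node, Var) and node.indices
            )

        assert spatial_offsets(f) == spatial_offsets(b)
        assert time_offsets(f) != time_offsets(b)

    def test_2d_laplacian_is_sum_of_per_dimension_stencils(self):
        s = builtin_scheme("FTCS", 2)
        # x rule in j/dx, y rule in k/dy2; both three-point second differences
        assert _equiv(
            s.operator_rule(2, 2),
            parse_expression("(v[n,k+1] - 2*v[n,k] + v[n,k-1])/dy2^2"),
        )

    def test_unknown_scheme_name(self):
        with pytest.raises(SchemeError):
            builtin_scheme("LAX_WENDROFF", 1)


class TestBoundaryIDs:
    def test_encoding_round_trip(self):
        for dim in (1, 2, 3):
            for direction in ("-", "+"):
                for cond in ("dirichlet", "neumann"):
                    bid = boundary_id(dim, direction, cond)
                    assert decode_boundary_id(bid) == (dim, direction, cond)

    def test_ids_unique_within_scheme(self):
        s = builtin_scheme("FTCS", 3)
        assert len(s.boundary_rules) == 3 * 2 * 2


class TestSchemeFiles:
    @pytest.mark.parametrize("name", ["FTCS", "BTCS", "CN"])
    @pytest.mark.parametrize("ndim", [1, 2])
    def test_serialize_parse_round_trip(self, name, ndim):
        spec = builtin_scheme(name, ndim)
        back = parse_scheme(serialize_scheme(spec))
        assert back.op_rules == spec.op_rules
        assert back.boundary_rules == spec.boundary_rules
        assert back.var_rules == spec.var_rules
        assert back.implicit == spec.implicit

    @pytest.mark.parametrize("fname,builtin,ndim", [
        ("ftcs1d.scheme", "FTCS", 1),
        ("btcs1d.scheme", "BTCS", 1),
        ("cn1d.scheme", "CN", 1),
        ("ftcs2d.scheme", "FTCS", 2),
    ])
    def test_shipped_files_match_builtins(self, fname, builtin, ndim):
        text = (importlib.resources.files("fdgen") / "schemes" / fname).read_text()
        spec = parse_scheme(text)
        ref = builtin_scheme(builtin, ndim)
        assert spec.op_rules == ref.op_rules
        assert spec.boundary_rules == ref.boundary_rules

    def test_missing_direction_rule_is_an_error(self):
        text = serialize_scheme(builtin_scheme("FTCS", 1))
        # drop the right-side (x +) Neumann rule, ID 7
        lines = [l for l in text.splitlines() if not l.startswith("7 =")]
        with pytest.raises(SchemeError, match="missing neumann.*'\\+'"):
            parse_scheme("\n".join(lines))

    def test_inconsistent_implicit_flag_rejected(self):
        text = serialize_scheme(builtin_scheme("BTCS", 1)).replace(
            "kind = implicit", "kind = explicit"
        )
        with pytest.raises(SchemeError, match="declared explicit"):
            parse_scheme(text)
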