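"""Generated-program correctness: loops, Newton blocks, targets, harness."""
import shutil

import numpy as np
import pytest

from fdgen.builtin_models import (
    diffusion_model,
    diffusion_relation,
    fhn_model,
    fhn_relation,
    membrane_model,
    membrane_relation,
)
from fdgen.codegen import CodegenError, build_loops, run_program
from fdgen.model import parse_model
from fdgen.pipeline import analyze_system, generate
from fdgen.relation import RelationMap
from fdgen.schemes import builtin_scheme


class TestExplicitPrograms:
    def test_constant_field_is_steady_under_no_flux(self):
        """Diffusion of a uniform field with zero-flux boundaries leaves the
        field unchanged (a steady state)."""
        m = diffusion_model(1, init=1.0)
        rel = diffusion_relation("neumann", length=3, dt=0.1, D=1.0)
        _, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        res = run_program(prog, 1)
        assert np.allclose(res.finals["V"][1:4], 1.0, atol=0, rtol=0)

    def test_single_step_stencil_arithmetic(self):
        """V=(0,1,0) with r = D*dt/dx^2 = 0.1 steps to (0.1, 0.8, 0.1)."""
        m = diffusion_model(1)
        rel = diffusion_relation("neumann", length=3, dt=0.1, D=1.0)
        rel.initial_values = {"V": (((2, 0, 0), 1.0),)}
        _, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        res = run_program(prog, 1)
        assert res.finals["V"][1:4] == pytest.approx([0.1, 0.8, 0.1], abs=1e-15)

    def test_zero_steps_echoes_initial_conditions(self):
        m = diffusion_model(1, init=0.25)
        rel = diffusion_relation("neumann", length=3, dt=0.1)
        _, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        res = run_program(prog, 0, probes=[(2, 0, 0)])
        assert res.finals["V"][2] == 0.25
        assert list(res.probe("V", (2, 0, 0))) == [0.25]

    def test_conservation_under_zero_flux(self):
        """Pure diffusion with zero-flux ends conserves the total amount of V
        over the material nodes to round-off at every step."""
        m = diffusion_model(1)
        rel = diffusion_relation("neumann", length=9, dt=0.1, D=1.0)
        rel.initial_values = {"V": (((5, 0, 0), 1.0), ((3, 0, 0), 0.5))}
        _, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        probes = [(i, 0, 0) for i in range(1, 10)]
        res = run_program(prog, 60, probes=probes, record_every=1)
        totals = np.sum([res.probe("V", p) for p in probes], axis=0)
        assert np.all(np.abs(np.diff(totals)) < 1e-12)

    def test_dirichlet_nodes_hold_declared_values(self):
        m = diffusion_model(1)
        rel = diffusion_relation("dirichlet", length=5, dt=0.1, D=1.0, a=1.0, b=-0.5)
        _, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        res = run_program(prog, 40, probes=[(1, 0, 0), (5, 0, 0)], record_every=1)
        assert np.all(res.probe("V", (1, 0, 0)) == 1.0)
        assert np.all(res.probe("V", (5, 0, 0)) == -0.5)

    def test_repeated_runs_are_bit_identical(self):
        m = fhn_model(2)
        rel = fhn_relation("neumann", side=5)
        _, prog = generate(m, builtin_scheme("FTCS", 2), rel)
        a = run_program(prog, 300)
        b = run_program(prog, 300)
        assert np.array_equal(a.finals["V"], b.finals["V"])
        assert np.array_equal(a.finals["W"], b.finals["W"])


class TestLoopReconstruction:
    def test_consecutive_instances_merge_into_loops(self):
        m = membrane_model()
        rel = membrane_relation("neumann", length=12)
        analysis, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        assert prog.metadata["loops"] >= 3  # J, I, V runs over the line
        assert "for j in range(" in prog.source

    def test_non_consecutive_nodes_stay_separate(self):
        from fdgen.dependency import DependencyGraph

        m = diffusion_model(1)
        rel = diffusion_relation("neumann", length=7, dt=0.01)
        analysis = analyze_system(m, builtin_scheme("FTCS", 1), rel)
        blocks = build_loops(analysis.dep, 1)
        # interior run merges; the two edge updates (waiting on ghosts) and
        # the two ghost assignments stay as separate statements
        kinds = [b.kind for b in blocks]
        assert "loop" in kinds and "stmt" in kinds

    def test_unrolled_equals_looped(self):
        m = fhn_model(2)
        rel = fhn_relation("neumann", side=5)
        s = builtin_scheme("FTCS", 2)
        _, looped = generate(m, s, rel)
        _, unrolled = generate(m, s, rel, unroll=True)
        assert looped.source != unrolled.source
        a = run_program(looped, 250)
        b = run_program(unrolled, 250)
        for name in ("V", "W"):
            assert np.array_equal(a.finals[name], b.finals[name])

    def test_2d_runs_merge_into_nested_loops(self):
        m = fhn_model(2)
        rel = fhn_relation("neumann", side=7, clamp_center=False)
        _, prog = generate(m, builtin_scheme("FTCS", 2), rel)
        assert "for k in range(" in prog.source  # outer row loop exists


class TestNewton:
    def test_btcs_step_equals_dense_linear_solve(self):
        """One implicit diffusion step: the Newton block must land on the
        solution of (I - r L) v_new = v_old with the boundary rows pinned."""
        m = diffusion_model(1)
        rel = diffusion_relation("dirichlet", length=5, dt=0.1, D=1.0, a=1.0, b=0.0)
        _, prog = generate(m, builtin_scheme("BTCS", 1), rel)
        assert prog.metadata["newton_blocks"] == 1
        res = run_program(prog, 1)
        r = 0.1
        A = np.eye(5)
        rhs = np.array([1.0, 0, 0, 0, 0.0])
        for i in range(1, 4):
            A[i, i] = 1 + 2 * r
            A[i, i - 1] = A[i, i + 1] = -r
        oracle = np.linalg.solve(A, rhs)
        assert np.max(np.abs(res.finals["V"][1:6] - oracle)) < 1e-12

    def test_newton_converges_in_one_iteration_on_linear_systems(self):
        """For a linear system the Newton correction is exact, so the
        residual check passes after a single update (iteration count is
        observable through an iteration-limit of 2 still succeeding)."""
        m = diffusion_model(1)
        rel = diffusion_relation("dirichlet", length=5, dt=0.1, D=1.0, a=1.0, b=0.0)
        _, prog = generate(m, builtin_scheme("BTCS", 1), rel)
        limited = prog.source.replace("for _it in range(50):", "for _it in range(2):")
        prog.source = limited
        res = run_program(prog, 5)  # would raise if >2 iterations were needed
        assert np.isfinite(res.finals["V"]).all()

    def test_scalar_nonlinear_root(self):
        """A self-referential algebraic equation u = 4/u with guess 3
        converges to the root u = 2."""
        src = """\
dim t x
var V diff 0.0
var A arith 3.0
d(V)/d(t) = A - A
A = 4 / A
"""
        m = parse_model(src)
        rel = RelationMap(
            mapping={"V": "diffvar", "A": "arithvar"},
            geometry=("line", 1),
            boundary=list(diffusion_relation("neumann", 1).boundary),
            params={"dt": 0.1},
        )
        _, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        assert prog.metadata["newton_blocks"] == 1
        res = run_program(prog, 1)
        assert res.finals["A"][1] == pytest.approx(2.0, abs=1e-9)

    def test_structurally_singular_jacobian_is_reported(self):
        from fdgen.codegen import LoopBlock, _newton_lines, make_context
        from fdgen.expressions import Idx, Num, Var
        from fdgen.instantiate import EquationInstance

        m = diffusion_model(1)
        rel = diffusion_relation("neumann", length=3, dt=0.1)
        analysis = analyze_system(m, builtin_scheme("FTCS", 1), rel)
        ctx = make_context(m, builtin_scheme("FTCS", 1), rel, analysis.grid, {})
        # a residual that references none of the block's unknowns
        inst = EquationInstance(Num(1.0), Num(2.0), (1, 0, 0), "bad", "FTCS",
                                unknown=("V", 1, (1, 0, 0)))
        with pytest.raises(CodegenError, match="singular"):
            _newton_lines(LoopBlock("newton", [inst]), ctx, None, "    ")


class TestCTarget:
    @pytest.mark.skipif(
        shutil.which("cc") is None and shutil.which("gcc") is None,
        reason="no C compiler on PATH",
    )
    def test_c_program_matches_host(self):
        m = membrane_model()
        rel = membrane_relation("neumann")
        s = builtin_scheme("FTCS", 1)
        _, pc = generate(m, s, rel, target="c")
        _, ph = generate(m, s, rel, target="host")
        rc = run_program(pc, 25)
        rh = run_program(ph, 25)
        assert np.max(np.abs(rc.finals["V"][1:4] - rh.finals["V"][1:4])) < 1e-14

    def test_c_target_rejects_implicit_schemes(self):
        m = diffusion_model(1)
        rel = diffusion_relation("dirichlet", length=5, dt=0.1, a=0.0, b=0.0)
        with pytest.raises(CodegenError, match="explicit"):
            generate(m, builtin_scheme("BTCS", 1), rel, target="c")


class TestHarness:
    def test_nan_is_surfaced_with_step_index(self):
        # violate the diffusion CFL badly so the explicit update blows up
        m = diffusion_model(1)
        rel = diffusion_relation("neumann", length=9, dt=10.0, D=1.0)
        rel.initial_values = {"V": (((5, 0, 0), 1.0),)}
        _, prog = generate(m, builtin_scheme("FTCS", 1), rel)
        with pytest.raises(RuntimeError):
            run_program(prog, 2000, probes=[(5, 0, 0)], record_every=50)
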