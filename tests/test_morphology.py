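"""Grids, boundary-node detection and CSV I/O."""
import random

import pytest

from fdgen.expressions import Num
from fdgen.morphology import (
    MorphologyError,
    MorphologyGrid,
    detect_boundary_nodes,
    make_line_mesh,
    make_square_mesh,
    read_distributed_parameter_csv,
    read_geometry_csv,
    write_geometry_csv,
)
from fdgen.relation import BoundaryDecl
from fdgen.schemes import boundary_id, builtin_scheme


def neumann_decls(ndim):
    return [
        BoundaryDecl("V", "neumann", Num(0), axis=a, side=s)
        for a in range(ndim)
        for s in ("-", "+")
    ]


class TestMeshes:
    def test_line_mesh_is_padded(self):
        g = make_line_mesh(3)
        assert len(g.material_nodes()) == 3
        flags = g.flags
        assert flags[(0, 0, 0)] == 0 and flags[(4, 0, 0)] == 0
        assert [c[0] for c in g.material_nodes()] == [1, 2, 3]

    def test_square_mesh_counts(self):
        assert len(make_square_mesh(50).material_nodes()) == 2500
        assert len(make_square_mesh(1).material_nodes()) == 1

    def test_single_node_square_has_four_adjacent_background_nodes(self):
        g = make_square_mesh(1)
        bnodes = detect_boundary_nodes(g, builtin_scheme("FTCS", 2), neumann_decls(2))
        assert len(bnodes) == 4


class TestGeometryCSV:
    def test_five_row_line(self, tmp_path):
        p = tmp_path / "geom.csv"
        p.write_text("x,y,z,flag\n0,0,0,0\n1,0,0,1\n2,0,0,1\n3,0,0,1\n4,0,0,0\n")
        g = read_geometry_csv(p)
        assert g.ndim == 1
        assert len(g.material_nodes()) == 3
        assert g.extents()[0] == (0, 4)

    def test_bad_flag_rejected(self, tmp_path):
        p = tmp_path / "geom.csv"
        p.write_text("0,0,0,0\n1,0,0,2\n")
        with pytest.raises(MorphologyError, match="0 or 1"):
            read_geometry_csv(p)

    def test_duplicate_coordinate_rejected(self, tmp_path):
        p = tmp_path / "geom.csv"
        p.write_text("0,0,0,1\n0,0,0,1\n")
        with pytest.raises(MorphologyError, match="duplicate"):
            read_geometry_csv(p)

    def test_large_square_round_trip(self, tmp_path):
        g = make_square_mesh(100)
        assert len(g.material_nodes()) == 10000
        p = tmp_path / "square.csv"
        write_geometry_csv(g, p)
        g2 = read_geometry_csv(p)
        assert g2.ndim == 2
        assert len(g2.material_nodes()) == 10000
        assert g2.shape == (102, 102)


class TestBoundaryDetection:
    def test_line_neumann_both_sides(self):
        g = make_line_mesh(3)
        bnodes = detect_boundary_nodes(g, builtin_scheme("FTCS", 1), neumann_decls(1))
        assert len(bnodes) == 2
        left, right = bnodes
        assert left.coord == (0, 0, 0)
        assert left.bid == boundary_id(1, "-", "neumann")
        assert right.coord == (4, 0, 0)
        assert right.bid == boundary_id(1, "+", "neumann")

    def test_empty_material_yields_empty_list(self):
        g = MorphologyGrid(1, (((0, 0, 0), 0), ((1, 0, 0), 0)))
        assert detect_boundary_nodes(g, builtin_scheme("FTCS", 1), neumann_decls(1)) == []

    def test_3x3_block_has_12_boundary_pairs_corners_excluded(self):
        # brute-force oracle: background nodes axis-adjacent to material
        g = make_square_mesh(3)
        flags = g.flags
        expected = 0
        for (x, y, z), f in g.nodes:
            if f != 0:
                continue
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if flags.get((x + dx, y + dy, z)) == 1:
                    expected += 1
        bnodes = detect_boundary_nodes(g, builtin_scheme("FTCS", 2), neumann_decls(2))
        assert len(bnodes) == expected == 12

    @pytest.mark.parametrize("d,side", [(1, 7), (2, 4)])
    def test_rectangular_block_count_formula(self, d, side):
        g = make_line_mesh(side) if d == 1 else make_square_mesh(side)
        bnodes = detect_boundary_nodes(
            g, builtin_scheme("FTCS", d), neumann_decls(d)
        )
        assert len(bnodes) == 2 * d * side ** (d - 1)

    def test_output_independent_of_node_order(self):
        g = make_square_mesh(4)
        nodes = list(g.nodes)
        random.Random(0).shuffle(nodes)
        g2 = MorphologyGrid(2, tuple(nodes), g.dx)
        b1 = detect_boundary_nodes(g, builtin_scheme("FTCS", 2), neumann_decls(2))
        b2 = detect_boundary_nodes(g2, builtin_scheme("FTCS", 2), neumann_decls(2))
        assert b1 == b2

    def test_uncovered_boundary_reports_coordinates(self):
        g = make_line_mesh(3)
        decls = [BoundaryDecl("V", "neumann", Num(0), axis=0, side="-")]
        with pytest.raises(MorphologyError, match=r"\(4, 0, 0\)"):
            detect_boundary_nodes(g, builtin_scheme("FTCS", 1), decls)

    def test_conflicting_declarations_rejected(self):
        g = make_line_mesh(3)
        decls = neumann_decls(1) + [
            BoundaryDecl("V", "dirichlet", Num(1), nodes=((0, 0, 0),))
        ]
        with pytest.raises(MorphologyError, match="conflicting"):
            detect_boundary_nodes(g, builtin_scheme("FTCS", 1), decls)


class TestDistributedParameters:
    def test_value_only_at_first_node(self, tmp_path):
        g = make_line_mesh(3)
        p = tmp_path / "param_C.csv"
        p.write_text("1,0,0,2.5\n")
        c = read_distributed_parameter_csv(p, g, "C")
        assert c.value_at((1, 0, 0)) == 2.5
        assert c.value_at((2, 0, 0)) == 0.0
        assert c.value_at((3, 0, 0)) == 0.0

    @pytest.mark.parametrize("content", ["", "x,y,z,value\n"])
    def test_empty_file_means_all_zero(self, tmp_path, content):
        g = make_line_mesh(3)
        p = tmp_path / "param_C.csv"
        p.write_text(content)
        c = read_distributed_parameter_csv(p, g, "C")
        assert all(c.value_at(n) == 0.0 for n in g.material_nodes())

    def test_duplicate_rows_rejected(self, tmp_path):
        g = make_line_mesh(3)
        p = tmp_path / "param_C.csv"
        p.write_text("1,0,0,1.0\n1,0,0,2.0\n")
        with pytest.raises(MorphologyError, match="duplicate"):
            read_distributed_parameter_csv(p, g, "C")

    def test_coordinate_outside_grid_rejected(self, tmp_path):
        g = make_line_mesh(3)
        p = tmp_path / "param_C.csv"
        p.write_text("9,0,0,1.0\n")
        with pytest.raises(MorphologyError, match="not in the grid"):
            read_distributed_parameter_csv(p, g, "C")
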