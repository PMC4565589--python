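"""Matching, SCC detection and computation ordering."""
import random

import pytest

from fdgen.builtin_models import membrane_model, membrane_relation
from fdgen.dependency import (
    UnsolvableSystemError,
    ford_fulkerson_matching,
    hopcroft_karp_matching,
    maximum_matching,
)
from fdgen.pipeline import analyze_system
from fdgen.schemes import builtin_scheme


def brute_force_max_matching(adjacency):
    """Exhaustive search over all assignment subsets (oracle, tiny graphs)."""

    def best(i, used):
        if i == len(adjacency):
            return 0
        score = best(i + 1, used)  # leave equation i unmatched
        for u in adjacency[i]:
            if u not in used:
                score = max(score, 1 + best(i + 1, used | {u}))
        return score

    return best(0, frozenset())


def random_bigraph(rng, n_eq, n_un, p=0.35):
    unknowns = [("u", k, ()) for k in range(n_un)]
    return [
        [u for u in unknowns if rng.random() < p] for _ in range(n_eq)
    ]


class TestMatchingAlgorithms:
    def test_two_unknowns_one_equation_is_unsolvable(self):
        adjacency = [[("u", 0, ()), ("u", 1, ())]]
        m = maximum_matching(adjacency)
        assert len(m) == 1  # maximum matching exists but is not perfect

    @pytest.mark.parametrize("seed", range(30))
    def test_ff_equals_hk_equals_brute_force(self, seed):
        rng = random.Random(seed)
        adjacency = random_bigraph(rng, rng.randint(1, 8), rng.randint(1, 8))
        ff = ford_fulkerson_matching(adjacency)
        hk = hopcroft_karp_matching(adjacency)
        expected = brute_force_max_matching(adjacency)
        assert len(ff) == len(hk) == expected

    def test_seeding_never_reduces_cardinality(self):
        rng = random.Random(99)
        for _ in range(50):
            adjacency = random_bigraph(rng, rng.randint(1, 8), rng.randint(1, 8))
            seeds = {
                i: adj[0] for i, adj in enumerate(adjacency) if adj and rng.random() < 0.5
            }
            seeded = ford_fulkerson_matching(adjacency, seeds)
            plain = ford_fulkerson_matching(adjacency)
            assert len(seeded) == len(plain)


class TestWorkedExampleGraphs:
    def test_lhs_matching_rule(self):
        """Every model equation whose LHS is a lone unknown is matched to it
        (the arrangement shown with the unknown on the left)."""
        analysis = analyze_system(
            membrane_model(), builtin_scheme("FTCS", 1), membrane_relation("neumann")
        )
        for inst in analysis.instances:
            if inst.label == "eq_I":
                assert inst.unknown == ("I", 0, inst.node)
            if inst.label == "eq_J":
                assert inst.unknown == ("J", 0, inst.node)
            if inst.label == "eq_V":
                assert inst.unknown == ("V", 1, inst.node)

    def test_explicit_scheme_yields_only_singletons(self):
        analysis = analyze_system(
            membrane_model(), builtin_scheme("FTCS", 1), membrane_relation("neumann")
        )
        assert analysis.scc_sizes() == [1] * 11

    def test_implicit_scheme_yields_nontrivial_scc(self):
        analysis = analyze_system(
            membrane_model(), builtin_scheme("BTCS", 1), membrane_relation("dirichlet")
        )
        sizes = analysis.scc_sizes()
        assert max(sizes) > 1
        # the simultaneous pair couples the new-level voltage and the current
        big = max(analysis.dep.sccs, key=len)
        names = {analysis.instances[i].unknown[0] for i in big}
        assert names == {"V", "I"}

    def test_computation_order_respects_all_edges(self):
        analysis = analyze_system(
            membrane_model(), builtin_scheme("FTCS", 1), membrane_relation("neumann")
        )
        dep = analysis.dep
        pos = {}
        for rank, block in enumerate(dep.ordered_blocks()):
            for i in block:
                pos[i] = rank
        for a, b in dep.digraph.edges:
            assert pos[a] <= pos[b]

    def test_stimulus_before_current_before_voltage(self):
        analysis = analyze_system(
            membrane_model(), builtin_scheme("FTCS", 1), membrane_relation("neumann")
        )
        dep = analysis.dep
        rank = {}
        for r, block in enumerate(dep.ordered_blocks()):
            for i in block:
                rank[analysis.instances[i].unknown] = r
        for j in (1, 2, 3):
            assert rank[("J", 0, (j, 0, 0))] < rank[("I", 0, (j, 0, 0))]
            assert rank[("I", 0, (j, 0, 0))] < rank[("V", 1, (j, 0, 0))]
        # the left ghost value feeds the current at node 1
        assert rank[("V", 0, (0, 0, 0))] < rank[("I", 0, (1, 0, 0))]

    def test_dirichlet_arrow_reversal(self):
        """With fixed boundary values, the edge time-update equation is
        repurposed to compute the current, and the ghost value follows from
        the current equation — the arrows at the edge reverse direction."""
        analysis = analyze_system(
            membrane_model(), builtin_scheme("FTCS", 1), membrane_relation("dirichlet")
        )
        matched = {
            analysis.instances[i].label + "@" + str(inst.node[0]): inst.unknown
            for i, inst in enumerate(analysis.instances)
        }
        by_label = {}
        for inst in analysis.instances:
            by_label[(inst.label, inst.node[0], inst.kind)] = inst.unknown
        # time-update at the clamped edge no longer defines V[n+1,1]
        assert by_label[("eq_V", 1, "model")][0] == "I"
        # the current equation at node 1 defines the ghost value
        assert by_label[("eq_I", 1, "model")] == ("V", 0, (0, 0, 0))

    def test_unsolvable_system_lists_unmatched(self):
        from fdgen.relation import BoundaryDecl

        rel = membrane_relation("neumann")
        # remove the right-hand Neumann condition and cover the right ghost
        # with nothing: detection fails first; instead cover it with a decl
        # for a different variable so instantiation succeeds but the ghost
        # stays undefined
        rel.boundary[1] = BoundaryDecl("W", "neumann", rel.boundary[1].value,
                                       axis=0, side="+")
        rel.mapping["W"] = "diffvar"
        with pytest.raises(Exception):
            analyze_system(membrane_model(), builtin_scheme("FTCS", 1), rel)
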