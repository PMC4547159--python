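import random

import pytest

from conftest import make_pathway
from oracles import brute_force_crossings, elementary_cycles
from pathcausal import (
    IntegrityError,
    LayoutColumns,
    ReactionOrdering,
    UsageError,
    back_arcs,
    build_causality_graph,
    count_crossings,
    cyclic_toposort,
    generate_pathway,
    order_participants,
    varied_params,
)
from pathcausal.ordering_layout import _inversions, layout_edges


class TestCyclicToposort:
    def test_chain_is_plain_topological_order(self, chain3):
        g = build_causality_graph(chain3)
        assert cyclic_toposort(g).order == ["R1", "R2", "R3"]

    def test_hand_traced_cycle_breaking(self, cycle3_plus_tail):
        """No zero-in-degree node exists, so the node with maximum residual
        out-degree (R1, with successors R2 and R4) is eliminated first."""
        g = build_causality_graph(cycle3_plus_tail)
        assert g.simple_edges() == {("R1", "R2"), ("R2", "R3"),
                                    ("R3", "R1"), ("R1", "R4")}
        ordering = cyclic_toposort(g)
        assert ordering.order == ["R1", "R2", "R3", "R4"]
        assert back_arcs(g, ordering) == {("R3", "R1")}

    def test_empty_graph(self):
        from pathcausal import Pathway
        g = build_causality_graph(Pathway.build([], []))
        assert cyclic_toposort(g).order == []

    @pytest.mark.parametrize("seed", range(8))
    def test_dag_ordering_has_no_back_arcs(self, seed):
        from pathcausal import GeneratorParams
        pw, _ = generate_pathway(GeneratorParams(
            seed=seed, n_reactions=20, n_planted_cycles=0,
            cycle_lengths=(), extra_edge_probability=0.2))
        g = build_causality_graph(pw)
        assert back_arcs(g, cyclic_toposort(g)) == set()

    @pytest.mark.parametrize("seed", range(6))
    def test_every_cycle_crosses_a_back_arc(self, seed):
        pw, _ = generate_pathway(varied_params(seed, max_reactions=25))
        g = build_causality_graph(pw)
        ordering = cyclic_toposort(g)
        arcs = back_arcs(g, ordering)
        for cyc in elementary_cycles(g.simple_edges(), g.nodes):
            edges = {(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))}
            assert edges & arcs

    def test_is_deterministic_permutation(self):
        pw, _ = generate_pathway(varied_params(9, max_reactions=30))
        g = build_causality_graph(pw)
        o1, o2 = cyclic_toposort(g), cyclic_toposort(g)
        assert o1.order == o2.order
        assert sorted(o1.order) == sorted(g.nodes)

    def test_original_out_degree_variant_also_valid_on_dags(self, chain3):
        g = build_causality_graph(chain3)
        assert cyclic_toposort(g, use_original_out_degree=True).order == \
            ["R1", "R2", "R3"]

    def test_missing_node_is_integrity_error(self, chain3):
        g = build_causality_graph(chain3)
        with pytest.raises(IntegrityError):
            back_arcs(g, ReactionOrdering(order=["R1", "R2"]))


class TestParticipantOrdering:
    def test_one_reaction_proteins_adjacent_zero_crossings(self):
        pw = make_pathway({"R": (["A", "B"], ["Z"])})
        layout = order_participants(pw)
        ip = layout.input_proteins
        assert abs(ip.index("A") - ip.index("B")) == 1
        assert count_crossings(pw, layout) == 0

    def test_disjoint_reactions_stay_contiguous(self):
        pw = make_pathway({"R1": (["A", "B"], ["Y"]),
                           "R2": (["C", "D"], ["Z"])})
        layout = order_participants(pw)
        ip = layout.input_proteins
        assert {abs(ip.index("A") - ip.index("B")),
                abs(ip.index("C") - ip.index("D"))} == {1}
        assert count_crossings(pw, layout) == 0

    def test_start_must_be_protein(self):
        pw = make_pathway({"R": (["C"], ["Z"])}, complexes={"C": ["P"]})
        with pytest.raises(UsageError):
            order_participants(pw, start="C")

    def test_columns_are_dense_permutations(self):
        pw, _ = generate_pathway(varied_params(13, max_reactions=25))
        layout = order_participants(pw)
        for col in ("input_proteins", "input_complexes", "reactions",
                    "output_complexes", "output_proteins"):
            ids = getattr(layout, col)
            assert len(ids) == len(set(ids))
        assert sorted(layout.reactions) == sorted(pw.reaction_ids())

    def test_greedy_beats_random_orderings_on_average(self):
        """The chaining heuristic should reduce crossings versus shuffled
        columns on a typical generated pathway."""
        pw, _ = generate_pathway(varied_params(13, max_reactions=25))
        layout = order_participants(pw)
        greedy = count_crossings(pw, layout)
        rng = random.Random(13)
        randoms = []
        for _ in range(100):
            cols = {c: list(getattr(layout, c))
                    for c in ("input_proteins", "input_complexes", "reactions",
                              "output_complexes", "output_proteins")}
            for ids in cols.values():
                rng.shuffle(ids)
            randoms.append(count_crossings(pw, LayoutColumns(**cols)))
        randoms.sort()
        assert greedy < randoms[len(randoms) // 2]


class TestCrossingCount:
    def test_parallel_edges_do_not_cross(self):
        assert _inversions([(1, 1), (2, 2)]) == 0

    def test_inverted_edges_cross_once(self):
        assert _inversions([(1, 2), (2, 1)]) == 1

    def test_shared_endpoints_never_count(self):
        assert _inversions([(1, 1), (1, 2)]) == 0
        assert _inversions([(1, 2), (3, 2)]) == 0

    def test_matches_brute_force_on_random_bipartite(self):
        rng = random.Random(2)
        pairs = [(rng.randrange(8), rng.randrange(8)) for _ in range(20)]
        assert _inversions(pairs) == brute_force_crossings(pairs)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_metric_matches_per_gap_brute_force(self, seed):
        pw, _ = generate_pathway(varied_params(seed, max_reactions=15))
        layout = order_participants(pw)
        pos = layout.positions()
        total = 0
        for gap, (lcol, rcol) in {
            "protein_complex_in": ("input_proteins", "input_complexes"),
            "complex_reaction_in": ("input_complexes", "reactions"),
            "reaction_complex_out": ("reactions", "output_complexes"),
            "complex_protein_out": ("output_complexes", "output_proteins"),
        }.items():
            pairs = []
            for a, b in layout_edges(pw)[gap]:
                pa = pos[lcol].get(a, pos["input_proteins"].get(a))
                pb = pos[rcol].get(b, pos["output_proteins"].get(b))
                pairs.append((pa, pb))
            total += brute_force_crossings(pairs)
        assert count_crossings(pw, layout) == total

    def test_missing_position_is_integrity_error(self):
        pw = make_pathway({"R": (["A"], ["B"])})
        broken = LayoutColumns(input_proteins=[], input_complexes=[],
                               reactions=["R"], output_complexes=[],
                               output_proteins=["B"])
        with pytest.raises(IntegrityError):
            count_crossings(pw, broken)
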