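import pytest

from conftest import make_pathway
from oracles import (
    bfs_depths,
    brute_force_edges,
    brute_force_edges_expanded,
    exhaustive_hops,
    reachability_closure,
)
from pathcausal import (
    GraphOptions,
    UnknownIdError,
    UsageError,
    build_causality_graph,
    common_downstream,
    downstream_of,
    generate_pathway,
    seed_reactions,
    shortest_hops,
    varied_params,
)
from pathcausal.synthetic_fixtures import GeneratorParams


class TestGraphConstruction:
    def test_single_overlap_single_edge(self):
        pw = make_pathway({"R1": (["A"], ["B"]), "R2": (["B"], ["C"])})
        g = build_causality_graph(pw)
        [e] = g.edges
        assert (e.source, e.target, set(e.witness)) == ("R1", "R2", {"B"})

    def test_disjoint_reactions_no_edges(self):
        pw = make_pathway({"R1": (["A"], ["B"]), "R2": (["C"], ["D"])})
        assert build_causality_graph(pw).edges == []

    def test_empty_pathway_empty_graph(self):
        from pathcausal import Pathway
        g = build_causality_graph(Pathway.build([], []))
        assert g.nodes == [] and g.edges == []

    def test_self_loops_suppressed_by_default(self):
        pw = make_pathway({"R1": (["A"], ["A"])})
        assert build_causality_graph(pw).edges == []
        g = build_causality_graph(pw, GraphOptions(allow_self_loops=True))
        assert g.simple_edges() == {("R1", "R1")}

    def test_edge_set_matches_brute_force_scan(self):
        pw, _ = generate_pathway(varied_params(7, max_reactions=20))
        g = build_causality_graph(pw)
        assert g.simple_edges() == brute_force_edges(pw)

    def test_witness_is_output_input_intersection(self):
        pw, _ = generate_pathway(GeneratorParams(seed=5, n_reactions=15))
        rx = {r.id: r for r in pw.reactions}
        for e in build_causality_graph(pw).edges:
            assert e.witness
            assert e.witness <= (set(rx[e.source].outputs)
                                 & set(rx[e.target].inputs))

    def test_expansion_only_adds_edges(self):
        for seed in range(6):
            pw, _ = generate_pathway(varied_params(seed, max_reactions=20))
            exact = build_causality_graph(pw).simple_edges()
            expanded = build_causality_graph(
                pw, GraphOptions(expand_complex_components=True)).simple_edges()
            assert exact <= expanded
            assert expanded == brute_force_edges_expanded(pw)

    def test_expanded_edge_through_complex_membership(self):
        # R1 emits P; R2 consumes the complex C that contains P
        pw = make_pathway({"R1": (["A"], ["P"]), "R2": (["C"], ["Z"])},
                          complexes={"C": ["P", "Q"]})
        assert build_causality_graph(pw).edges == []
        g = build_causality_graph(pw, GraphOptions(expand_complex_components=True))
        [e] = g.edges
        assert (e.source, e.target) == ("R1", "R2") and "P" in e.witness

    def test_control_edges_on_separate_channel(self):
        pw = make_pathway({"R1": (["A"], ["K"]), "R2": (["S"], ["T"])},
                          controls=[("K", "R2", "catalysis")])
        assert build_causality_graph(pw).edges == []  # no shared participant
        g = build_causality_graph(pw, GraphOptions(include_control_edges=True))
        [e] = g.edges
        assert (e.source, e.target, e.channel) == ("R1", "R2", "control")


class TestSeedsAndDownstream:
    def test_seed_reactions_by_input(self):
        pw = make_pathway({"R1": (["A"], ["B"]), "R2": (["B"], ["C"])})
        g = build_causality_graph(pw)
        assert seed_reactions(pw, g, ["B"]) == {"R2"}
        assert seed_reactions(pw, g, ["C"]) == set()  # never an input
        with pytest.raises(UnknownIdError):
            seed_reactions(pw, g, ["nope"])

    def test_seed_protein_inside_input_complex_with_expansion(self):
        pw = make_pathway({"R3": (["C"], ["Z"])}, complexes={"C": ["P", "Q"]})
        g_exact = build_causality_graph(pw)
        g_exp = build_causality_graph(pw, GraphOptions(expand_complex_components=True))
        assert seed_reactions(pw, g_exact, ["P"]) == set()
        assert seed_reactions(pw, g_exp, ["P"]) == {"R3"}

    def test_chain_levels(self, chain3):
        g = build_causality_graph(chain3)
        res = downstream_of(g, {"R1"})
        assert res.levels == [["R1"], ["R2"], ["R3"]]
        assert res.visited == {"R1", "R2", "R3"}

    def test_cycle_visited_once(self):
        pw = make_pathway({"R1": (["b"], ["a"]), "R2": (["a"], ["b"])})
        g = build_causality_graph(pw)
        res = downstream_of(g, {"R1"})
        assert res.levels == [["R1"], ["R2"]]  # loop back, not revisited

    def test_unknown_seed_raises(self, chain3):
        g = build_causality_graph(chain3)
        with pytest.raises(UnknownIdError):
            downstream_of(g, {"R9"})

    def test_visited_equals_transitive_closure(self):
        pw, _ = generate_pathway(varied_params(11, max_reactions=30))
        g = build_causality_graph(pw)
        seeds = {g.nodes[0], g.nodes[len(g.nodes) // 2]}
        res = downstream_of(g, seeds)
        assert res.visited == reachability_closure(g.simple_edges(),
                                                   g.nodes, seeds)
        depths = bfs_depths(g.simple_edges(), g.nodes, seeds)
        for d, level in enumerate(res.levels):
            for rid in level:
                assert depths[rid] == d

    def test_levels_disjoint_and_ordered(self):
        pw, _ = generate_pathway(varied_params(4, max_reactions=25))
        g = build_causality_graph(pw)
        res = downstream_of(g, {g.nodes[0]})
        seen: set[str] = set()
        order = {n: i for i, n in enumerate(g.nodes)}
        for level in res.levels:
            assert not (set(level) & seen)
            assert level == sorted(level, key=order.__getitem__)
            seen |= set(level)


class TestCommonDownstream:
    def test_needs_two_seed_sets(self, chain3):
        g = build_causality_graph(chain3)
        with pytest.raises(UsageError):
            common_downstream(g, [{"R1"}])

    def test_disjoint_reachable_sets_empty(self):
        pw = make_pathway({"R1": (["A"], ["B"]), "R2": (["B"], ["C"]),
                           "R3": (["X"], ["Y"]), "R4": (["Y"], ["Z"])})
        g = build_causality_graph(pw)
        assert common_downstream(g, [{"R1"}, {"R3"}]) == set()

    def test_identical_seeds_reduce_to_downstream(self, chain3):
        g = build_causality_graph(chain3)
        full = downstream_of(g, {"R1"}).visited
        assert common_downstream(g, [{"R1"}, {"R1"}]) == full - {"R1"}
        assert common_downstream(g, [{"R1"}, {"R1"}], include_seeds=True) == full

    @pytest.mark.parametrize("seed", [3, 9, 15])
    def test_matches_independent_closure_intersection(self, seed):
        pw, _ = generate_pathway(varied_params(seed, max_reactions=30))
        g = build_causality_graph(pw)
        s1, s2 = {g.nodes[0]}, {g.nodes[-1]}
        expected = (reachability_closure(g.simple_edges(), g.nodes, s1)
                    & reachability_closure(g.simple_edges(), g.nodes, s2))
        assert common_downstream(g, [s1, s2], include_seeds=True) == expected


class TestShortestHops:
    def test_two_step_chain(self, chain3):
        g = build_causality_graph(chain3)
        t = shortest_hops(chain3, g, "A")
        assert t.distances == {"A": 0, "B": 1, "C": 2, "D": 3}

    def test_unreachable_entities_omitted(self, erk):
        g = build_causality_graph(erk)
        t = shortest_hops(erk, g, "ERK1")
        assert t.distances["PMEK1S"] == 3  # three reactions away
        for absent in ("MEK1", "PMEK1", "ATP"):
            assert absent not in t.distances

    def test_unknown_source_raises(self, chain3):
        g = build_causality_graph(chain3)
        with pytest.raises(UnknownIdError):
            shortest_hops(chain3, g, "nope")

    @pytest.mark.parametrize("seed", [5, 12])
    def test_matches_exhaustive_path_enumeration(self, seed):
        pw, _ = generate_pathway(GeneratorParams(
            seed=seed, n_reactions=10, n_proteins=8,
            extra_edge_probability=0.2))
        g = build_causality_graph(pw)
        source = pw.reactions[0].inputs[0]
        assert shortest_hops(pw, g, source).distances == exhaustive_hops(pw, source)

    def test_triangle_step_property(self):
        pw, _ = generate_pathway(varied_params(6, max_reactions=20))
        g = build_causality_graph(pw)
        source = pw.reactions[0].inputs[0]
        dist = shortest_hops(pw, g, source).distances
        for eid, d in dist.items():
            if d == 0:
                continue
            assert any(
                eid in r.outputs
                and any(dist.get(i) == d - 1 for i in r.inputs)
                for r in pw.reactions)
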