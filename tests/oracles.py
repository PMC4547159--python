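"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the library
(brute-force scans, networkx closures, exhaustive path enumeration) so that
agreement is meaningful.
"""

from __future__ import annotations

import networkx as nx

from pathcausal.pathway_model import Pathway


def brute_force_edges(pathway: Pathway) -> set[tuple[str, str]]:
    """All-ordered-pairs output/input intersection scan (exact matching)."""
    edges = set()
    for r1 in pathway.reactions:
        for r2 in pathway.reactions:
            if r1.id == r2.id:
                continue
            if set(r1.outputs) & set(r2.inputs):
                edges.add((r1.id, r2.id))
    return edges


def brute_force_edges_expanded(pathway: Pathway) -> set[tuple[str, str]]:
    """Same scan under complex-membership matching."""
    edges = set()
    for r1 in pathway.reactions:
        out_members = set()
        for o in r1.outputs:
            out_members |= pathway.members(o)
        for r2 in pathway.reactions:
            if r1.id == r2.id:
                continue
            in_members = set()
            for i in r2.inputs:
                in_members |= pathway.members(i)
            if out_members & in_members:
                edges.add((r1.id, r2.id))
    return edges


def nx_digraph(edges: set[tuple[str, str]], nodes: list[str]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def reachability_closure(edges: set[tuple[str, str]], nodes: list[str],
                         seeds: set[str]) -> set[str]:
    g = nx_digraph(edges, nodes)
    out = set(seeds)
    for s in seeds:
        out |= nx.descendants(g, s)
    return out


def bfs_depths(edges: set[tuple[str, str]], nodes: list[str],
               seeds: set[str]) -> dict[str, int]:
    g = nx_digraph(edges, nodes)
    g.add_node("__virtual_source__")
    for s in seeds:
        g.add_edge("__virtual_source__", s)
    lengths = nx.single_source_shortest_path_length(g, "__virtual_source__")
    return {n: d - 1 for n, d in lengths.items() if n != "__virtual_source__"}


def exhaustive_hops(pathway: Pathway, source: str) -> dict[str, int]:
    """Minimum reactions to each entity by exhaustive enumeration of
    reaction-simple alternating paths (each reaction used once per path)."""
    best: dict[str, int] = {source: 0}
    seen_states: dict[frozenset[str], int] = {}

    def extend(frontier_entities: frozenset[str], depth: int):
        if seen_states.get(frontier_entities, 1 << 30) <= depth:
            return  # this entity set was already reached at least as early
        seen_states[frontier_entities] = depth
        for r in pathway.reactions:
            if not (set(r.inputs) & frontier_entities):
                continue
            for out in r.outputs:
                if depth + 1 < best.get(out, 1 << 30):
                    best[out] = depth + 1
            grown = frontier_entities | set(r.outputs)
            if grown != frontier_entities:  # no new entities -> no new paths
                extend(grown, depth + 1)

    extend(frozenset({source}), 0)
    return best


def elementary_cycles(edges: set[tuple[str, str]],
                      nodes: list[str]) -> set[tuple[str, ...]]:
    """Elementary cycle set via networkx (Johnson's algorithm), normalized
    to start at the pathway-earliest member."""
    pos = {n: i for i, n in enumerate(nodes)}
    out = set()
    for cyc in nx.simple_cycles(nx_digraph(edges, nodes)):
        k = min(range(len(cyc)), key=lambda i: pos[cyc[i]])
        out.add(tuple(cyc[k:] + cyc[:k]))
    return out


def brute_force_crossings(pairs: list[tuple[int, int]]) -> int:
    """O(E^2) inversion scan over one column gap."""
    total = 0
    for i, (a1, b1) in enumerate(pairs):
        for a2, b2 in pairs[i + 1:]:
            if (a1 - a2) * (b1 - b2) < 0:
                total += 1
    return total
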