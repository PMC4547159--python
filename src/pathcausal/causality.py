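"""Reaction-to-reaction causality: graph construction, downstream closure,
hop distances, and common-downstream intersection.

A causal relationship r1 -> r2 holds when an output participant of reaction
r1 acts as an input participant of reaction r2; r2 is then *downstream* of
r1. By default participants match by exact id — in Reactome-style data
complex assembly and dissociation are themselves reactions, so exact
matching already propagates causality through complexes. Opt-in complex
expansion additionally matches an entity against any participant complex
that transitively contains it. Control links can optionally contribute
edges on a separate channel; the core causal relation is defined purely by
shared participants.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .errors import UnknownIdError, UsageError
from .pathway_model import Pathway, Reaction


@dataclass(frozen=True)
class GraphOptions:
    expand_complex_components: bool = False
    include_control_edges: bool = False
    allow_self_loops: bool = False


@dataclass(frozen=True)
class CausalEdge:
    source: str
    target: str
    witness: frozenset[str]
    channel: str = "participant"  # or "control"


@dataclass
class CausalGraph:
    """Directed graph on reaction ids; each edge carries the entity set that
    witnesses it."""

    nodes: list[str]
    edges: list[CausalEdge]
    options: GraphOptions = field(default_factory=GraphOptions)

    def successors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if (e.source, e.target) not in seen:
                seen.add((e.source, e.target))
                adj[e.source].append(e.target)
        return adj

    def simple_edges(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def to_networkx(self):
        """Projection onto a :mod:`networkx` DiGraph (witnesses joined as a
        sorted comma string; parallel channels collapsed, channel list kept)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if g.has_edge(e.source, e.target):
                g[e.source][e.target]["channels"].append(e.channel)
                wit = set(g[e.source][e.target]["witness"].split(",")) | set(e.witness)
                g[e.source][e.target]["witness"] = ",".join(sorted(wit))
            else:
                g.add_edge(e.source, e.target,
                           witness=",".join(sorted(e.witness)),
                           channels=[e.channel])
        return g


@dataclass
class DownstreamResult:
    """Breadth-first downstream closure; level 0 is the seed set and each
    reaction appears at the smallest depth at which it is reachable."""

    levels: list[list[str]]
    visited: set[str]
    witness_edges: list[CausalEdge]


@dataclass
class HopTable:
    """Minimum number of reactions needed to produce each entity from a
    source entity; unreachable entities are simply absent."""

    source: str
    distances: dict[str, int]


def _match_sets(pathway: Pathway, ids: tuple[str, ...],
                expand: bool) -> dict[str, frozenset[str]]:
    """id -> the set of entity ids it matches under the active mode."""
    if not expand:
        return {i: frozenset((i,)) for i in ids}
    return {i: pathway.members(i) for i in ids}


def build_causality_graph(pathway: Pathway,
                          options: GraphOptions | None = None) -> CausalGraph:
    """Emit a participant edge r1 -> r2 whenever some output of r1 matches
    some input of r2 under the active matching mode.

    The witness records the matched output entities of r1. With
    ``include_control_edges``, a control edge r1 -> r2 is added for every
    control link whose controller is an output of r1 and whose target is
    r2. Edges are deduplicated per (source, target, channel) and reported
    in pathway order.
    """
    opts = options or GraphOptions()
    nodes = pathway.reaction_ids()
    # producer index: entity-or-member id -> reactions producing it
    producers: dict[str, list[Reaction]] = {}
    out_match: dict[str, dict[str, frozenset[str]]] = {}
    in_match: dict[str, dict[str, frozenset[str]]] = {}
    for r in pathway.reactions:
        out_match[r.id] = _match_sets(pathway, r.outputs,
                                      opts.expand_complex_components)
        in_match[r.id] = _match_sets(pathway, r.inputs,
                                     opts.expand_complex_components)
        for out_id, members in out_match[r.id].items():
            for m in members:
                producers.setdefault(m, []).append(r)

    pos = pathway.reaction_position()
    edges: list[CausalEdge] = []
    for r2 in pathway.reactions:
        witness_by_source: dict[str, set[str]] = {}
        for in_id, in_members in in_match[r2.id].items():
            for m in in_members:
                for r1 in producers.get(m, ()):
                    if r1.id == r2.id and not opts.allow_self_loops:
                        continue
                    # witness = r1's output entities that matched
                    matched = {o for o, mem in out_match[r1.id].items()
                               if m in mem}
                    witness_by_source.setdefault(r1.id, set()).update(matched)
        for src in sorted(witness_by_source, key=pos.__getitem__):
            edges.append(CausalEdge(src, r2.id,
                                    frozenset(witness_by_source[src])))

    if opts.include_control_edges:
        produced_by: dict[str, list[str]] = {}
        for r in pathway.reactions:
            for o in r.outputs:
                produced_by.setdefault(o, []).append(r.id)
        seen: set[tuple[str, str]] = set()
        for c in pathway.controls:
            for src in produced_by.get(c.controller, ()):
                if src == c.controlled and not opts.allow_self_loops:
                    continue
                if (src, c.controlled) in seen:
                    continue
                seen.add((src, c.controlled))
                edges.append(CausalEdge(src, c.controlled,
                                        frozenset((c.controller,)),
                                        channel="control"))

    edges.sort(key=lambda e: (pos[e.source], pos[e.target], e.channel))
    return CausalGraph(nodes=nodes, edges=edges, options=opts)


def seed_reactions(pathway: Pathway, graph: CausalGraph,
                   entity_ids: list[str] | set[str]) -> set[str]:
    """Reactions having any of the given entities among their inputs, under
    the graph's matching mode."""
    for eid in entity_ids:
        pathway.entity(eid)  # raises UnknownIdError on a bad id
    expand = graph.options.expand_complex_components
    wanted = set(entity_ids)
    hits: set[str] = set()
    for r in pathway.reactions:
        for in_id in r.inputs:
            members = pathway.members(in_id) if expand else {in_id}
            if members & wanted:
                hits.add(r.id)
                break
    return hits


def downstream_of(graph: CausalGraph, seeds: set[str] | list[str]) -> DownstreamResult:
    """Breadth-first closure over causal edges; every reaction is visited at
    most once, so a branch looping back to an already-animated reaction
    terminates there."""
    node_set = set(graph.nodes)
    for s in seeds:
        if s not in node_set:
            raise UnknownIdError(f"seed reaction not in graph: {s!r}")
    order = {n: i for i, n in enumerate(graph.nodes)}
    adj = graph.successors()
    edge_lookup = {(e.source, e.target): e for e in graph.edges}

    level = sorted(set(seeds), key=order.__getitem__)
    visited: set[str] = set(level)
    levels: list[list[str]] = []
    witness_edges: list[CausalEdge] = []
    while level:
        levels.append(level)
        nxt: set[str] = set()
        for u in level:
            for v in adj[u]:
                if v not in visited:
                    nxt.add(v)
                    witness_edges.append(edge_lookup[(u, v)])
        visited.update(nxt)
        level = sorted(nxt, key=order.__getitem__)
    return DownstreamResult(levels=levels, visited=visited,
                            witness_edges=witness_edges)


def common_downstream(graph: CausalGraph, seed_sets: list[set[str]],
                      include_seeds: bool = False) -> set[str]:
    """Reactions downstream of every one of two or more seed sets."""
    if len(seed_sets) < 2:
        raise UsageError("common_downstream needs at least two seed sets")
    for s in seed_sets:
        if not s:
            raise UsageError("every seed set must be nonempty")
    closures = [downstream_of(graph, s).visited for s in seed_sets]
    common = set.intersection(*closures)
    if not include_seeds:
        common -= set.union(*[set(s) for s in seed_sets])
    return common


def shortest_hops(pathway: Pathway, graph: CausalGraph,
                  source: str) -> HopTable:
    """Minimum number of reactions on an alternating entity -> reaction ->
    entity path from the source entity to every reachable entity.

    Breadth-first search over the bipartite relation (entity feeds the
    reactions it is an input of; a reaction yields its outputs); the source
    has distance 0 and unreachable entities are omitted.
    """
    pathway.entity(source)
    expand = graph.options.expand_complex_components

    consumers: dict[str, list[Reaction]] = {}
    for r in pathway.reactions:
        for in_id in r.inputs:
            members = pathway.members(in_id) if expand else {in_id}
            for m in members:
                consumers.setdefault(m, []).append(r)

    dist: dict[str, int] = {source: 0}
    frontier = deque([source])
    while frontier:
        eid = frontier.popleft()
        d = dist[eid]
        reachable_from = pathway.members(eid) if expand else {eid}
        for m in sorted(reachable_from):
            for r in consumers.get(m, ()):
                for out in r.outputs:
                    if out not in dist:
                        dist[out] = d + 1
                        frontier.append(out)
    epos = pathway.entity_position()
    ordered = dict(sorted(dist.items(), key=lambda kv: (kv[1], epos[kv[0]])))
    return HopTable(source=source, distances=ordered)
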