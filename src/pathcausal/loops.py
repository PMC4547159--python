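"""Feedback-loop detection: enumeration of elementary directed cycles in
the reaction-level causality graph.

A feedback loop is an elementary cycle (no repeated reaction) of causal
edges. Cycle counts are worst-case exponential, so enumeration is
restricted to strongly connected components and truncated at a hard cap
with an explicit flag. Every cycle is rotation-normalized to start at its
member that comes first in pathway order, which makes output canonical.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .causality import CausalGraph
from .errors import UnknownIdError
from .ordering_layout import back_arcs, cyclic_toposort


@dataclass(frozen=True)
class FeedbackLoop:
    """One elementary cycle, as the ordered reaction-id tuple starting at
    the member earliest in pathway order."""

    cycle: tuple[str, ...]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.cycle

    def __len__(self) -> int:
        return len(self.cycle)

    def edges(self) -> list[tuple[str, str]]:
        c = self.cycle
        return [(c[i], c[(i + 1) % len(c)]) for i in range(len(c))]


class LoopSearchResult(list):
    """List of :class:`FeedbackLoop` with a ``truncated`` flag set when the
    enumeration hit its cap before exhausting all cycles."""

    def __init__(self, loops=(), truncated: bool = False):
        super().__init__(loops)
        self.truncated = truncated


def _tarjan_sccs(nodes: list[str], adj: dict[str, list[str]]) -> list[set[str]]:
    """Iterative Tarjan strongly-connected components."""
    index: dict[str, int] = {}
    low: dict[str, int] = {}
    on_stack: set[str] = set()
    stack: list[str] = []
    sccs: list[set[str]] = []
    counter = 0

    for root in nodes:
        if root in index:
            continue
        work: list[tuple[str, int]] = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                index[v] = low[v] = counter
                counter += 1
                stack.append(v)
                on_stack.add(v)
            recurse = False
            for i in range(pi, len(adj[v])):
                w = adj[v][i]
                if w not in index:
                    work[-1] = (v, i + 1)
                    work.append((w, 0))
                    recurse = True
                    break
                if w in on_stack:
                    low[v] = min(low[v], index[w])
            if recurse:
                continue
            work.pop()
            if low[v] == index[v]:
                comp: set[str] = set()
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.add(w)
                    if w == v:
                        break
                sccs.append(comp)
            if work:
                u, _ = work[-1]
                low[u] = min(low[u], low[v])
    return sccs


def find_feedback_loops(graph: CausalGraph, max_loops: int = 10_000,
                        max_len: int | None = None,
                        method: str = "elementary") -> LoopSearchResult:
    """Enumerate feedback loops of the causality graph.

    ``method="elementary"`` (default) enumerates every elementary cycle,
    component by component, emitting each cycle anchored at its
    pathway-earliest member; ``method="backarc"`` reports one shortest loop
    per back arc of the cycle-tolerant topological ordering — cheaper, and
    mirrors reading loops off the left-hand arcs of the ordered view.
    Enumeration stops after ``max_loops`` cycles (``truncated`` flag set);
    ``max_len`` bounds cycle length.
    """
    pos = {n: i for i, n in enumerate(graph.nodes)}
    self_loops = sorted({(s,) for s, t in graph.simple_edges() if s == t})
    adj_full: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for s, t in sorted(graph.simple_edges(), key=lambda e: (pos[e[0]], pos[e[1]])):
        if s != t:
            adj_full[s].append(t)

    if method == "backarc":
        return _backarc_loops(graph, adj_full, pos, max_loops)
    if method != "elementary":
        raise ValueError(f"unknown loop-search method: {method!r}")

    loops: list[FeedbackLoop] = [FeedbackLoop(c) for c in self_loops]
    truncated = False
    limit = max_len if max_len is not None else len(graph.nodes)

    # anchored search: cycles whose pathway-earliest node is `s` are found
    # by DFS from s over nodes ordered after s, inside s's residual SCC
    for s in graph.nodes:
        if truncated:
            break
        allowed = {n for n in graph.nodes if pos[n] >= pos[s]}
        scc_of: dict[str, int] = {}
        sub_nodes = [n for n in graph.nodes if n in allowed]
        sub_adj = {n: [t for t in adj_full[n] if t in allowed] for n in sub_nodes}
        for i, comp in enumerate(_tarjan_sccs(sub_nodes, sub_adj)):
            for n in comp:
                scc_of[n] = i
        if not any(scc_of[t] == scc_of[s] for t in sub_adj[s]):
            continue
        comp_adj = {n: [t for t in sub_adj[n] if scc_of[t] == scc_of[s]]
                    for n in sub_nodes if scc_of[n] == scc_of[s]}
        path: list[str] = [s]
        on_path = {s}

        def dfs(v: str) -> bool:
            nonlocal truncated
            for w in comp_adj[v]:
                if len(loops) >= max_loops:
                    truncated = True
                    return False
                if w == s and len(path) >= 2:
                    loops.append(FeedbackLoop(tuple(path)))
                elif w not in on_path and len(path) < limit:
                    path.append(w)
                    on_path.add(w)
                    if not dfs(w):
                        return False
                    path.pop()
                    on_path.discard(w)
            return True

        dfs(s)

    return LoopSearchResult(loops, truncated)


def _backarc_loops(graph: CausalGraph, adj: dict[str, list[str]],
                   pos: dict[str, int], max_loops: int) -> LoopSearchResult:
    ordering = cyclic_toposort(graph)
    arcs = sorted(back_arcs(graph, ordering),
                  key=lambda e: (pos[e[0]], pos[e[1]]))
    found: list[FeedbackLoop] = []
    seen: set[tuple[str, ...]] = set()
    truncated = False
    for u, v in arcs:  # close u -> v with a shortest v -> u path
        if len(found) >= max_loops:
            truncated = True
            break
        parent: dict[str, str] = {v: v}
        q = deque([v])
        while q and u not in parent:
            x = q.popleft()
            for y in adj[x]:
                if y not in parent:
                    parent[y] = x
                    q.append(y)
        if u not in parent:
            continue  # the arc is a self-loop handled elsewhere or dead
        chain = [u]
        while chain[-1] != v:
            chain.append(parent[chain[-1]])
        cycle = tuple(reversed(chain))  # v .. u
        k = min(range(len(cycle)), key=lambda i: pos[cycle[i]])
        norm = cycle[k:] + cycle[:k]
        if norm not in seen:
            seen.add(norm)
            found.append(FeedbackLoop(norm))
    return LoopSearchResult(found, truncated)


def loops_containing(loops: list[FeedbackLoop], reaction_id: str,
                     graph: CausalGraph | None = None) -> list[FeedbackLoop]:
    """The subset of loops passing through a reaction; empty if none.

    When the originating graph is supplied, an id outside it raises
    :class:`UnknownIdError`.
    """
    if graph is not None and reaction_id not in set(graph.nodes):
        raise UnknownIdError(f"unknown reaction id: {reaction_id!r}")
    return [lp for lp in loops if reaction_id in lp]
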