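"""Cycle-tolerant topological ordering, back-arc identification, the greedy
participant-ordering heuristic, and the edge-crossing metric.

Pathway causality graphs are rarely acyclic, so a plain topological sort is
undefined. The ordering used here is a Kahn-style elimination that, when no
zero-in-degree node remains, removes the node with maximum *residual*
out-degree — greedily cutting as many remaining cycles as possible. Edges
pointing right-to-left under the resulting order ("back arcs") are exactly
the arcs that can close feedback loops.

The layout half arranges the pathway in five columns (input proteins,
input complexes, reactions, output complexes, output proteins), chains
proteins that share reactions or complexes next to each other, places
complexes and reactions at the barycenter of their placed members, and
counts edge crossings between adjacent columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .causality import CausalGraph
from .errors import IntegrityError, UsageError
from .pathway_model import EntityKind, Pathway


@dataclass
class ReactionOrdering:
    order: list[str]
    position: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.position:
            self.position = {r: i for i, r in enumerate(self.order)}


def cyclic_toposort(graph: CausalGraph,
                    use_original_out_degree: bool = False) -> ReactionOrdering:
    """Modified Kahn elimination tolerating directed cycles.

    Repeatedly: if some node has residual in-degree 0, remove the earliest
    such node in pathway order; otherwise remove the node with maximum
    residual out-degree (ties broken by pathway order). On an acyclic graph
    this reduces to an ordinary topological sort.

    ``use_original_out_degree`` switches the cycle-breaking score to the
    out-degree in the *original* graph, for comparison.
    """
    nodes = list(graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    succ: dict[str, set[str]] = {n: set() for n in nodes}
    pred: dict[str, set[str]] = {n: set() for n in nodes}
    for s, t in graph.simple_edges():
        if s != t:
            succ[s].add(t)
            pred[t].add(s)
    original_out = {n: len(succ[n]) for n in nodes}

    remaining = set(nodes)
    order: list[str] = []
    while remaining:
        ready = [n for n in nodes if n in remaining and not pred[n]]
        if ready:
            chosen = ready[0]  # earliest in pathway order
        else:
            score = (original_out if use_original_out_degree
                     else {n: len(succ[n]) for n in remaining})
            chosen = min(remaining, key=lambda n: (-score[n], pos[n]))
        order.append(chosen)
        remaining.discard(chosen)
        for t in succ.pop(chosen, ()):  # drop outgoing edges
            pred[t].discard(chosen)
        for p in pred.pop(chosen, ()):  # drop incoming edges
            succ[p].discard(chosen)
    return ReactionOrdering(order=order)


def back_arcs(graph: CausalGraph,
              ordering: ReactionOrdering) -> set[tuple[str, str]]:
    """Edges whose target precedes their source under the ordering; every
    directed cycle contributes at least one."""
    for n in graph.nodes:
        if n not in ordering.position:
            raise IntegrityError(f"node missing from ordering: {n!r}")
    return {(s, t) for s, t in graph.simple_edges()
            if ordering.position[t] < ordering.position[s]}


# -- five-column participant layout ---------------------------------------


@dataclass
class LayoutColumns:
    """Five ordered columns of the reaction-centric view. An entity
    participating on both sides appears in both its input and output
    columns; positions are 0-based and dense within each column."""

    input_proteins: list[str]
    input_complexes: list[str]
    reactions: list[str]
    output_complexes: list[str]
    output_proteins: list[str]

    def positions(self) -> dict[str, dict[str, int]]:
        return {
            "input_proteins": {x: i for i, x in enumerate(self.input_proteins)},
            "input_complexes": {x: i for i, x in enumerate(self.input_complexes)},
            "reactions": {x: i for i, x in enumerate(self.reactions)},
            "output_complexes": {x: i for i, x in enumerate(self.output_complexes)},
            "output_proteins": {x: i for i, x in enumerate(self.output_proteins)},
        }


def _column_membership(pathway: Pathway):
    """Assign ids to columns. Complexes that are direct reaction
    participants form the complex columns; their transitive non-complex
    components join the adjacent protein column. Non-complex entities that
    participate directly also join the protein columns."""
    in_prot: list[str] = []
    in_cplx: list[str] = []
    out_cplx: list[str] = []
    out_prot: list[str] = []
    seen: dict[str, set[str]] = {k: set() for k in ("ip", "ic", "oc", "op")}

    def flat_proteins(eid: str) -> list[str]:
        out = []
        for m in sorted(pathway.members(eid),
                        key=pathway.entity_position().__getitem__):
            if pathway.entity(m).kind is not EntityKind.COMPLEX:
                out.append(m)
        return out

    for r in pathway.reactions:
        for eid in r.inputs:
            if pathway.entity(eid).kind is EntityKind.COMPLEX:
                if eid not in seen["ic"]:
                    seen["ic"].add(eid)
                    in_cplx.append(eid)
                for p in flat_proteins(eid):
                    if p not in seen["ip"]:
                        seen["ip"].add(p)
                        in_prot.append(p)
            elif eid not in seen["ip"]:
                seen["ip"].add(eid)
                in_prot.append(eid)
        for eid in r.outputs:
            if pathway.entity(eid).kind is EntityKind.COMPLEX:
                if eid not in seen["oc"]:
                    seen["oc"].add(eid)
                    out_cplx.append(eid)
                for p in flat_proteins(eid):
                    if p not in seen["op"]:
                        seen["op"].add(p)
                        out_prot.append(p)
            elif eid not in seen["op"]:
                seen["op"].add(eid)
                out_prot.append(eid)
    return in_prot, in_cplx, out_cplx, out_prot


def layout_edges(pathway: Pathway) -> dict[str, list[tuple[str, str]]]:
    """Drawn links per adjacent column gap.

    ``protein_complex_in``: input protein -> input complex it belongs to;
    ``complex_reaction_in``: left participant (complex, or protein for a
    direct participant) -> reaction; symmetric on the output side. Direct
    protein participants span the middle gap with their protein-column
    position as ordinate.
    """
    gaps: dict[str, list[tuple[str, str]]] = {
        "protein_complex_in": [], "complex_reaction_in": [],
        "reaction_complex_out": [], "complex_protein_out": [],
    }
    is_cplx = {e.id: e.kind is EntityKind.COMPLEX
               for e in pathway.entities.values()}
    epos = pathway.entity_position()

    def flat_proteins(eid: str) -> list[str]:
        return [m for m in sorted(pathway.members(eid), key=epos.__getitem__)
                if not is_cplx[m]]

    seen_pc: set[tuple[str, str]] = set()
    for r in pathway.reactions:
        for eid in r.inputs:
            gaps["complex_reaction_in"].append((eid, r.id))
            if is_cplx[eid]:
                for p in flat_proteins(eid):
                    if (p, eid) not in seen_pc:
                        seen_pc.add((p, eid))
                        gaps["protein_complex_in"].append((p, eid))
        for eid in r.outputs:
            gaps["reaction_complex_out"].append((r.id, eid))
            if is_cplx[eid]:
                for p in flat_proteins(eid):
                    if (eid, p) not in seen_pc:
                        seen_pc.add((eid, p))
                        gaps["complex_protein_out"].append((eid, p))
    return gaps


def order_participants(pathway: Pathway,
                       start: str | None = None) -> LayoutColumns:
    """Greedy protein chaining to keep interacting participants adjacent.

    Starting from ``start`` (default: the first protein in pathway order),
    repeatedly append the unplaced protein sharing the greatest number of
    reactions or complexes with the most recently placed one (ties broken
    by pathway order); when nothing is shared, jump to the next unplaced
    protein in pathway order. Complexes and reactions are then placed at
    the barycenter (mean position) of their already-placed members and
    participants.
    """
    in_prot, in_cplx, out_cplx, out_prot = _column_membership(pathway)
    epos = pathway.entity_position()
    rpos = pathway.reaction_position()
    is_cplx = {e.id: e.kind is EntityKind.COMPLEX
               for e in pathway.entities.values()}
    proteins = sorted(set(in_prot) | set(out_prot), key=epos.__getitem__)

    if start is not None:
        if pathway.entity(start).kind is EntityKind.COMPLEX:
            raise UsageError(f"start id must not be a complex: {start!r}")
        if start not in proteins:
            raise UsageError(f"start id is not a participating protein: {start!r}")

    # shared-participation counts between protein pairs
    groups: list[set[str]] = []
    for r in pathway.reactions:
        members: set[str] = set()
        for eid in pathway.iter_participants(r):
            members.update(m for m in pathway.members(eid) if not is_cplx[m])
        groups.append(members)
    for e in pathway.entities.values():
        if is_cplx[e.id]:
            groups.append({m for m in pathway.members(e.id) if not is_cplx[m]})

    shared: dict[str, dict[str, int]] = {p: {} for p in proteins}
    for g in groups:
        g = sorted(g & set(proteins), key=epos.__getitem__)
        for i, a in enumerate(g):
            for b in g[i + 1:]:
                shared[a][b] = shared[a].get(b, 0) + 1
                shared[b][a] = shared[b].get(a, 0) + 1

    unplaced = set(proteins)
    chain: list[str] = []
    current = start if start is not None else (proteins[0] if proteins else None)
    while unplaced:
        if current is None or current not in unplaced:
            current = min(unplaced, key=epos.__getitem__)
        chain.append(current)
        unplaced.discard(current)
        best, best_count = None, 0
        for q in sorted(unplaced, key=epos.__getitem__):
            c = shared[current].get(q, 0)
            if c > best_count:
                best, best_count = q, c
        current = best  # None -> jump to next in pathway order

    chain_pos = {p: i for i, p in enumerate(chain)}

    def barycenter(ids: list[str], member_pos_of) -> list[str]:
        def key(x: str) -> tuple:
            ps = member_pos_of(x)
            mean = sum(ps) / len(ps) if ps else float("inf")
            return (mean, epos.get(x, rpos.get(x, 0)))
        return sorted(ids, key=key)

    def complex_members_pos(cid: str) -> list[int]:
        return [chain_pos[m] for m in pathway.members(cid)
                if m in chain_pos and m != cid]

    in_cplx_o = barycenter(in_cplx, complex_members_pos)
    out_cplx_o = barycenter(out_cplx, complex_members_pos)
    in_cplx_pos = {c: i for i, c in enumerate(in_cplx_o)}
    out_cplx_pos = {c: i for i, c in enumerate(out_cplx_o)}

    def reaction_members_pos(rid: str) -> list[int]:
        r = pathway.reaction(rid)
        ps: list[int] = []
        for eid in r.inputs:
            if eid in in_cplx_pos:
                ps.append(in_cplx_pos[eid])
            elif eid in chain_pos:
                ps.append(chain_pos[eid])
        for eid in r.outputs:
            if eid in out_cplx_pos:
                ps.append(out_cplx_pos[eid])
            elif eid in chain_pos:
                ps.append(chain_pos[eid])
        return ps

    def rbary(rid: str) -> tuple:
        ps = reaction_members_pos(rid)
        mean = sum(ps) / len(ps) if ps else float("inf")
        return (mean, rpos[rid])

    reactions_o = sorted(pathway.reaction_ids(), key=rbary)

    restrict = lambda col: sorted(col, key=chain_pos.__getitem__)
    return LayoutColumns(
        input_proteins=restrict(in_prot),
        input_complexes=in_cplx_o,
        reactions=reactions_o,
        output_complexes=out_cplx_o,
        output_proteins=restrict(out_prot),
    )


_GAP_COLUMNS = {
    "protein_complex_in": ("input_proteins", "input_complexes"),
    "complex_reaction_in": ("input_complexes", "reactions"),
    "reaction_complex_out": ("reactions", "output_complexes"),
    "complex_protein_out": ("output_complexes", "output_proteins"),
}


def _inversions(pairs: list[tuple[int, int]]) -> int:
    """Count strictly inverted pairs ((a-a')(b-b') < 0) by merge counting.

    Sorting by (a, b) makes pairs with equal a contribute nothing, and
    equal b values are never counted as inversions, so links sharing an
    endpoint are automatically excluded.
    """
    seq = [b for _, b in sorted(pairs)]

    def count(lo: int, hi: int) -> int:
        if hi - lo < 2:
            return 0
        mid = (lo + hi) // 2
        inv = count(lo, mid) + count(mid, hi)
        merged = []
        i, j = lo, mid
        while i < mid and j < hi:
            if seq[i] <= seq[j]:
                merged.append(seq[i])
                i += 1
            else:
                inv += mid - i
                merged.append(seq[j])
                j += 1
        merged.extend(seq[i:mid])
        merged.extend(seq[j:hi])
        seq[lo:hi] = merged
        return inv

    return count(0, len(seq))


def count_crossings(pathway: Pathway, layout: LayoutColumns) -> int:
    """Total crossings over the four adjacent column gaps: unordered link
    pairs whose endpoint positions invert; links sharing an endpoint never
    count."""
    pos = layout.positions()
    gaps = layout_edges(pathway)
    total = 0
    for gap, (left_col, right_col) in _GAP_COLUMNS.items():
        lp, rp = pos[left_col], pos[right_col]
        # direct (non-complex) participants in the middle gaps take their
        # ordinate from the protein column
        alt_l = pos["input_proteins"] if gap == "complex_reaction_in" else {}
        alt_r = pos["output_proteins"] if gap == "reaction_complex_out" else {}
        pairs: list[tuple[int, int]] = []
        for a, b in gaps[gap]:
            try:
                pa = lp[a] if a in lp else alt_l[a]
                pb = rp[b] if b in rp else alt_r[b]
            except KeyError as exc:
                raise IntegrityError(
                    f"layout assigns no position to endpoint {exc.args[0]!r}"
                ) from None
            pairs.append((pa, pb))
        total += _inversions(pairs)
    return total
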