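"""Graph-format export (GraphML, DOT) and deterministic static SVG figures
of the reaction-centric five-column view.

The figure mirrors the tool's layout: input proteins on the far left,
output proteins on the far right, complexes beside them (triangles when a
complex is only ever an input or only ever an output, diamonds when it acts
as both, scaled with component count), reactions as circles in the center
scaled with participant count, and causal arcs between reactions drawn
with a yellow-to-black gradient running source to target. Forward arcs bow
to the right of the reaction column and back arcs to the left, so under a
topological ordering every left-hand arc flags a potential feedback loop.
Animation is replaced by a sequence of cumulative highlight frames, one per
breadth-first level of the downstream closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from xml.sax.saxutils import escape, quoteattr

import networkx as nx

from .causality import CausalGraph, downstream_of
from .errors import IntegrityError
from .ordering_layout import LayoutColumns, layout_edges, order_participants
from .pathway_model import ComplexRole, Pathway, complex_roles, reaction_size

# fixed geometry; the source data carries none
_COL_X = {"input_proteins": 60.0, "input_complexes": 220.0, "reactions": 400.0,
          "output_complexes": 580.0, "output_proteins": 740.0}
_ROW_DY = 28.0
_TOP_Y = 40.0
_GLYPH_UNIT = 3.0  # px of radius per participant/component
_FADE_OPACITY = 0.15

_HIGHLIGHT_COLOR = {"seed": "#d62728", "downstream": "#ff7f0e",
                    "common": "#1f77b4", "loop": "#9467bd"}


@dataclass
class RenderSpec:
    """What to draw: a five-column layout, optional highlights (id -> role
    tag), an optional animation frame index, and per-link-class fade
    flags."""

    layout: LayoutColumns
    highlights: dict[str, str] = field(default_factory=dict)
    frame_index: int | None = None
    fade: frozenset[str] = frozenset()  # of {"reaction_links", "complex_links", "causal_arcs"}


# -- graph formats ---------------------------------------------------------


def graph_to_networkx(graph: CausalGraph) -> "nx.DiGraph":
    return graph.to_networkx()


def export_graphml(graph: CausalGraph) -> str:
    """GraphML with witness and channel edge attributes, deterministic
    element order."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for e in graph.edges:
        if g.has_edge(e.source, e.target):
            data = g[e.source][e.target]
            data["channel"] = ",".join(sorted(
                set(data["channel"].split(",")) | {e.channel}))
            data["witness"] = ",".join(sorted(
                set(data["witness"].split(",")) | set(e.witness)))
        else:
            g.add_edge(e.source, e.target,
                       witness=",".join(sorted(e.witness)), channel=e.channel)
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"


def export_dot(graph: CausalGraph) -> str:
    """Graphviz DOT; witness and channel become edge attributes."""
    lines = ["digraph causality {"]
    for n in graph.nodes:
        lines.append(f"  {quoteattr(n)};")
    for e in graph.edges:
        wit = ",".join(sorted(e.witness))
        lines.append(
            f"  {quoteattr(e.source)} -> {quoteattr(e.target)} "
            f"[witness={quoteattr(wit)}, channel={quoteattr(e.channel)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def parse_dot_edges(document: str) -> set[tuple[str, str]]:
    """Minimal reader for the DOT emitted above (used for round-trip
    checks without a Graphviz dependency)."""
    edges: set[tuple[str, str]] = set()
    for line in document.splitlines():
        line = line.strip()
        if "->" in line:
            left, right = line.split("->", 1)
            src = left.strip().strip('"')
            tgt = right.split("[", 1)[0].strip().rstrip(";").strip().strip('"')
            edges.add((src, tgt))
    return edges


# -- static SVG ------------------------------------------------------------


def _y(idx: int) -> float:
    return _TOP_Y + idx * _ROW_DY


def _fmt(x: float) -> str:
    return f"{x:.1f}"


def render_static(pathway: Pathway, spec: RenderSpec,
                  graph: CausalGraph | None = None) -> str:
    """Emit the five-column figure as a standalone SVG document.

    Causal arcs require ``graph``; omit it to draw participants only.
    Output is byte-deterministic for a fixed input. Raises
    :class:`IntegrityError` when the spec highlights an id absent from the
    layout and the pathway.
    """
    layout = spec.layout
    pos = layout.positions()
    known = set(pathway.entities) | {r.id for r in pathway.reactions}
    for hid in spec.highlights:
        if hid not in known:
            raise IntegrityError(f"highlight references unknown id: {hid!r}")

    roles = complex_roles(pathway)
    n_rows = max((len(getattr(layout, c)) for c in _COL_X), default=0)
    height = _TOP_Y + max(n_rows, 1) * _ROW_DY + 40
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(f'<svg xmlns="http://www.w3.org/2000/svg" width="800" '
               f'height="{_fmt(height)}" viewBox="0 0 800 {_fmt(height)}">')

    # gradient defs, one per causal arc, oriented source -> target
    arcs: list[tuple[str, str, bool]] = []
    if graph is not None:
        rpos = pos["reactions"]
        for e in graph.edges:
            if e.source in rpos and e.target in rpos:
                arcs.append((e.source, e.target,
                             rpos[e.target] < rpos[e.source]))
    out.append("<defs>")
    for i, (src, tgt, _) in enumerate(arcs):
        y1, y2 = _y(pos["reactions"][src]), _y(pos["reactions"][tgt])
        out.append(
            f'<linearGradient id="arc{i}" gradientUnits="userSpaceOnUse" '
            f'x1="{_fmt(_COL_X["reactions"])}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(_COL_X["reactions"])}" y2="{_fmt(y2)}">'
            '<stop offset="0" stop-color="#ffd700"/>'
            '<stop offset="1" stop-color="#000000"/></linearGradient>')
    out.append("</defs>")

    # column captions
    for col, x in _COL_X.items():
        out.append(f'<text class="caption" x="{_fmt(x)}" y="20" '
                   f'text-anchor="middle" font-size="11">'
                   f'{escape(col.replace("_", " "))}</text>')

    # participant links
    gaps = layout_edges(pathway)
    link_class = {
        "protein_complex_in": "complex_links", "complex_protein_out": "complex_links",
        "complex_reaction_in": "reaction_links", "reaction_complex_out": "reaction_links",
    }
    gap_cols = {
        "protein_complex_in": ("input_proteins", "input_complexes"),
        "complex_reaction_in": ("input_complexes", "reactions"),
        "reaction_complex_out": ("reactions", "output_complexes"),
        "complex_protein_out": ("output_complexes", "output_proteins"),
    }
    for gap, pairs in gaps.items():
        lcol, rcol = gap_cols[gap]
        cls = link_class[gap]
        opacity = _FADE_OPACITY if cls in spec.fade else 0.8
        color = "#2ca02c" if cls == "complex_links" else "#d62728"
        for a, b in pairs:
            la = pos[lcol].get(a, pos["input_proteins"].get(a)
                               if gap == "complex_reaction_in" else None)
            lb = pos[rcol].get(b, pos["output_proteins"].get(b)
                               if gap == "reaction_complex_out" else None)
            if la is None or lb is None:
                raise IntegrityError(f"layout omits endpoint of {a!r}->{b!r}")
            xa = _COL_X[lcol] if a in pos[lcol] else _COL_X[
                "input_proteins" if gap == "complex_reaction_in" else lcol]
            xb = _COL_X[rcol] if b in pos[rcol] else _COL_X[
                "output_proteins" if gap == "reaction_complex_out" else rcol]
            out.append(
                f'<line class="{cls}" x1="{_fmt(xa)}" y1="{_fmt(_y(la))}" '
                f'x2="{_fmt(xb)}" y2="{_fmt(_y(lb))}" stroke="{color}" '
                f'stroke-opacity="{opacity}" stroke-width="1"/>')

    # causal arcs: semicircles right of the column for forward edges, left
    # for back arcs
    arc_opacity = _FADE_OPACITY if "causal_arcs" in spec.fade else 0.9
    for i, (src, tgt, back) in enumerate(arcs):
        y1, y2 = _y(pos["reactions"][src]), _y(pos["reactions"][tgt])
        x = _COL_X["reactions"]
        r = abs(y2 - y1) / 2.0
        sweep = 0 if back else 1
        out.append(
            f'<path class="causal_arc" d="M {_fmt(x)} {_fmt(y1)} '
            f'A {_fmt(r)} {_fmt(r)} 0 0 {sweep} {_fmt(x)} {_fmt(y2)}" '
            f'fill="none" stroke="url(#arc{i})" '
            f'stroke-opacity="{arc_opacity}" stroke-width="2"/>')

    # glyphs
    for col in ("input_proteins", "output_proteins"):
        for eid in getattr(layout, col):
            y = _y(pos[col][eid])
            hl = spec.highlights.get(eid)
            fill = _HIGHLIGHT_COLOR.get(hl, "#444444")
            out.append(f'<circle class="participant" cx="{_fmt(_COL_X[col])}" '
                       f'cy="{_fmt(y)}" r="3.0" fill="{fill}"/>')
            anchor = "end" if col == "input_proteins" else "start"
            dx = -6 if col == "input_proteins" else 6
            out.append(f'<text x="{_fmt(_COL_X[col] + dx)}" y="{_fmt(y + 3)}" '
                       f'text-anchor="{anchor}" font-size="9">'
                       f'{escape(pathway.entity(eid).name)}</text>')
    for col in ("input_complexes", "output_complexes"):
        for cid in getattr(layout, col):
            y = _y(pos[col][cid])
            size = 4.0 + _GLYPH_UNIT * len(pathway.members(cid) - {cid})
            x = _COL_X[col]
            hl = spec.highlights.get(cid)
            fill = _HIGHLIGHT_COLOR.get(hl, "#1f77b4")
            if roles.get(cid) is ComplexRole.BOTH:  # diamond
                pts = (f"{_fmt(x)},{_fmt(y - size)} {_fmt(x + size)},{_fmt(y)} "
                       f"{_fmt(x)},{_fmt(y + size)} {_fmt(x - size)},{_fmt(y)}")
            else:  # triangle for single-role (and unused) complexes
                pts = (f"{_fmt(x)},{_fmt(y - size)} "
                       f"{_fmt(x + size)},{_fmt(y + size)} "
                       f"{_fmt(x - size)},{_fmt(y + size)}")
            out.append(f'<polygon class="complex" points="{pts}" fill="{fill}"/>')
    for rid in layout.reactions:
        y = _y(pos["reactions"][rid])
        radius = 3.0 + _GLYPH_UNIT * reaction_size(pathway, rid) / 2.0
        hl = spec.highlights.get(rid)
        fill = _HIGHLIGHT_COLOR.get(hl, "#ffffff")
        out.append(f'<circle class="reaction" cx="{_fmt(_COL_X["reactions"])}" '
                   f'cy="{_fmt(y)}" r="{_fmt(radius)}" fill="{fill}" '
                   f'stroke="#333333" stroke-width="1.2"/>')

    out.append("</svg>")
    return "\n".join(out) + "\n"


def animation_frames(graph: CausalGraph, seeds: set[str] | list[str],
                     pathway: Pathway,
                     layout: LayoutColumns | None = None) -> list[RenderSpec]:
    """One cumulative highlight frame per breadth-first level of the
    downstream closure; rendering the frames in order reproduces the
    step-by-step animation, and a branch looping back to an
    already-highlighted reaction adds no further frames."""
    layout = layout if layout is not None else order_participants(pathway)
    result = downstream_of(graph, seeds)
    frames: list[RenderSpec] = []
    highlights: dict[str, str] = {}
    for i, level in enumerate(result.levels):
        for rid in level:
            highlights[rid] = "seed" if i == 0 else "downstream"
        frames.append(RenderSpec(layout=layout, highlights=dict(highlights),
                                 frame_index=i))
    return frames
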