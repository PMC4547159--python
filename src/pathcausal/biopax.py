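"""BioPAX Level-3 OWL (RDF/XML) reader and a writer for the subset we model.

The reader maps BiochemicalReaction left/right onto reaction inputs/outputs,
Complex component lists recursively, and Catalysis/Control onto control
links. Entity identity is the RDF resource URI fragment, so differently
modified forms of a protein (e.g. a phosphorylated form) are distinct
entities. Classes outside the modelled subset are skipped and counted in a
log record. BioPAX ``left`` is always treated as the input side;
``conversionDirection`` is logged when present and contrary, never obeyed.
"""

from __future__ import annotations

import logging
from collections import Counter

import rdflib
from lxml import etree
from rdflib.namespace import RDF

from .errors import FormatError, IntegrityError
from .pathway_model import (
    ControlEffect,
    ControlLink,
    EntityKind,
    Pathway,
    PhysicalEntity,
    Reaction,
)

log = logging.getLogger(__name__)

BP = rdflib.Namespace("http://www.biopax.org/release/biopax-level3.owl#")
_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

#: BioPAX class local-name -> modelled entity kind. Anything else that is
#: referenced as a participant but typed with a different physical-entity
#: class falls back to kind=other.
_KIND_BY_CLASS = {
    "Protein": EntityKind.PROTEIN,
    "SmallMolecule": EntityKind.SMALL_MOLECULE,
    "Complex": EntityKind.COMPLEX,
}
_OTHER_ENTITY_CLASSES = {
    "PhysicalEntity", "SimplePhysicalEntity", "Dna", "Rna",
    "DnaRegion", "RnaRegion", "Gene",
}
_CONTROL_CLASSES = {"Catalysis", "Control", "Modulation", "TemplateReactionRegulation"}


def _frag(uri: str) -> str:
    """Stable identifier: URI fragment, else last path segment."""
    if "#" in uri:
        return uri.rsplit("#", 1)[1]
    return uri.rstrip("/").rsplit("/", 1)[-1]


def _document_reaction_order(document: str) -> list[str]:
    """Document order of BiochemicalReaction elements via a streaming XML
    scan; RDF graphs are unordered so this is recovered from the raw text."""
    try:
        root = etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML at line {exc.lineno}, "
                          f"column {exc.position[1]}: {exc.msg}") from exc
    order: list[str] = []
    tag = f"{{{BP}}}BiochemicalReaction"
    for el in root.iter(tag):
        rid = (el.get(f"{{{_RDF_NS}}}ID")
               or el.get(f"{{{_RDF_NS}}}about"))
        if rid is not None:
            order.append(_frag(rid))
    return order


def _display_name(g: rdflib.Graph, node: rdflib.term.Node, default: str) -> str:
    for pred in (BP.displayName, BP.standardName):
        val = g.value(node, pred)
        if val is not None:
            return str(val)
    names = sorted(str(v) for v in g.objects(node, BP.name))
    return names[0] if names else default


def _comments(g: rdflib.Graph, node: rdflib.term.Node) -> str:
    return " ".join(sorted(str(v) for v in g.objects(node, BP.comment)))


def parse_biopax(document: str) -> Pathway:
    """Parse a BioPAX Level-3 OWL document into a :class:`Pathway`.

    Raises :class:`FormatError` (naming the position) on malformed XML and
    :class:`IntegrityError` (naming the dangling id) when a participant or
    component reference resolves to no declared physical entity.
    """
    doc_order = _document_reaction_order(document)
    g = rdflib.Graph()
    g.parse(data=document, format="xml")

    kind_of: dict[str, EntityKind] = {}
    node_of: dict[str, rdflib.term.Node] = {}
    reactions_nodes: dict[str, rdflib.term.Node] = {}
    control_nodes: list[tuple[str, rdflib.term.Node]] = []
    skipped: Counter[str] = Counter()

    for s, _, cls in g.triples((None, RDF.type, None)):
        cls_uri = str(cls)
        if not cls_uri.startswith(str(BP)):
            continue
        local = cls_uri[len(str(BP)):]
        sid = _frag(str(s))
        if local in _KIND_BY_CLASS:
            kind_of[sid] = _KIND_BY_CLASS[local]
            node_of[sid] = s
        elif local in _OTHER_ENTITY_CLASSES:
            kind_of[sid] = EntityKind.OTHER
            node_of[sid] = s
        elif local == "BiochemicalReaction":
            reactions_nodes[sid] = s
        elif local in _CONTROL_CLASSES:
            control_nodes.append((local, s))
        else:
            skipped[local] += 1
    if skipped:
        log.info("ignored %d individuals of %d unmodelled BioPAX classes: %s",
                 sum(skipped.values()), len(skipped),
                 ", ".join(sorted(skipped)))

    entities: list[PhysicalEntity] = []
    for sid in sorted(kind_of):
        node = node_of[sid]
        comps: tuple[str, ...] = ()
        if kind_of[sid] is EntityKind.COMPLEX:
            comp_ids = sorted(_frag(str(o)) for o in g.objects(node, BP.component))
            for cid in comp_ids:
                if cid not in kind_of:
                    raise IntegrityError(
                        f"complex {sid!r} references undeclared component {cid!r}")
            comps = tuple(comp_ids)
        entities.append(PhysicalEntity(
            id=sid, name=_display_name(g, node, sid), kind=kind_of[sid],
            components=comps, description=_comments(g, node)))

    def participants(node: rdflib.term.Node, pred: rdflib.term.Node,
                     rid: str) -> list[str]:
        ids = sorted(_frag(str(o)) for o in g.objects(node, pred))
        for eid in ids:
            if eid not in kind_of:
                raise IntegrityError(
                    f"reaction {rid!r} references undeclared entity {eid!r}")
        return ids

    # reactions in document order; any stragglers (order recovery failed for
    # them) go last, sorted by id
    ordered = [r for r in doc_order if r in reactions_nodes]
    ordered += sorted(set(reactions_nodes) - set(ordered))
    reactions: list[Reaction] = []
    for rid in ordered:
        node = reactions_nodes[rid]
        direction = g.value(node, BP.conversionDirection)
        if direction is not None and "LEFT" not in str(direction).split("-")[0]:
            log.warning("reaction %s declares conversionDirection=%s; "
                        "left is still read as the input side", rid, direction)
        reactions.append(Reaction(
            id=rid,
            name=_display_name(g, node, rid),
            inputs=tuple(participants(node, BP.left, rid)),
            outputs=tuple(participants(node, BP.right, rid)),
            description=_comments(g, node)))

    controls: list[ControlLink] = []
    n_skipped_controls = 0
    for local, node in sorted(control_nodes, key=lambda t: _frag(str(t[1]))):
        controller = g.value(node, BP.controller)
        controlled = g.value(node, BP.controlled)
        if controller is None or controlled is None:
            n_skipped_controls += 1
            continue
        cid, tid = _frag(str(controller)), _frag(str(controlled))
        if cid not in kind_of or tid not in reactions_nodes:
            # e.g. a control whose target is a whole pathway
            n_skipped_controls += 1
            continue
        ctype = str(g.value(node, BP.controlType) or "")
        if "INHIBITION" in ctype.upper():
            effect = ControlEffect.INHIBITION
        elif "ACTIVATION" in ctype.upper():
            effect = ControlEffect.ACTIVATION
        else:
            effect = ControlEffect.CATALYSIS
        controls.append(ControlLink(cid, tid, effect))
    if n_skipped_controls:
        log.info("skipped %d control links outside the entity->reaction model",
                 n_skipped_controls)

    pw_node = g.value(None, RDF.type, BP.Pathway, any=True)
    pw_id = _frag(str(pw_node)) if pw_node is not None else "pathway"
    pw_name = _display_name(g, pw_node, "") if pw_node is not None else ""
    return Pathway.build(entities, reactions, controls, id=pw_id, name=pw_name)


# -- writer ----------------------------------------------------------------

_CLASS_BY_KIND = {
    EntityKind.PROTEIN: "Protein",
    EntityKind.SMALL_MOLECULE: "SmallMolecule",
    EntityKind.COMPLEX: "Complex",
    EntityKind.OTHER: "PhysicalEntity",
}
_CONTROL_TYPE = {
    ControlEffect.ACTIVATION: "ACTIVATION",
    ControlEffect.INHIBITION: "INHIBITION",
}


def write_biopax(pathway: Pathway) -> str:
    """Emit the BioPAX Level-3 subset read by :func:`parse_biopax`.

    Reactions appear in pathway order so that a round trip preserves the
    document-order tie-break; output is byte-deterministic.
    """
    nsmap = {
        "rdf": _RDF_NS,
        "bp": str(BP),
        "owl": "http://www.w3.org/2002/07/owl#",
    }
    rdf = f"{{{_RDF_NS}}}"
    bp = f"{{{BP}}}"
    owl = "{http://www.w3.org/2002/07/owl#}"
    root = etree.Element(f"{rdf}RDF", nsmap=nsmap)
    onto = etree.SubElement(root, f"{owl}Ontology", {f"{rdf}about": ""})
    etree.SubElement(onto, f"{owl}imports",
                     {f"{rdf}resource": str(BP).rstrip("#")})

    def string_prop(parent: etree._Element, tag: str, value: str) -> None:
        el = etree.SubElement(parent, tag, {
            f"{rdf}datatype": "http://www.w3.org/2001/XMLSchema#string"})
        el.text = value

    for e in sorted(pathway.entities.values(), key=lambda e: e.id):
        el = etree.SubElement(root, f"{bp}{_CLASS_BY_KIND[e.kind]}",
                              {f"{rdf}ID": e.id})
        string_prop(el, f"{bp}displayName", e.name)
        if e.description:
            string_prop(el, f"{bp}comment", e.description)
        for cid in e.components:
            etree.SubElement(el, f"{bp}component", {f"{rdf}resource": f"#{cid}"})

    for r in pathway.reactions:
        el = etree.SubElement(root, f"{bp}BiochemicalReaction",
                              {f"{rdf}ID": r.id})
        string_prop(el, f"{bp}displayName", r.name)
        if r.description:
            string_prop(el, f"{bp}comment", r.description)
        for eid in r.inputs:
            etree.SubElement(el, f"{bp}left", {f"{rdf}resource": f"#{eid}"})
        for eid in r.outputs:
            etree.SubElement(el, f"{bp}right", {f"{rdf}resource": f"#{eid}"})

    for i, c in enumerate(pathway.controls):
        cls = "Catalysis" if c.effect is ControlEffect.CATALYSIS else "Control"
        el = etree.SubElement(root, f"{bp}{cls}", {f"{rdf}ID": f"control_{i:04d}"})
        etree.SubElement(el, f"{bp}controller",
                         {f"{rdf}resource": f"#{c.controller}"})
        etree.SubElement(el, f"{bp}controlled",
                         {f"{rdf}resource": f"#{c.controlled}"})
        if c.effect in _CONTROL_TYPE:
            string_prop(el, f"{bp}controlType", _CONTROL_TYPE[c.effect])

    pw = etree.SubElement(root, f"{bp}Pathway", {f"{rdf}ID": pathway.id})
    string_prop(pw, f"{bp}displayName", pathway.name)
    for r in pathway.reactions:
        etree.SubElement(pw, f"{bp}pathwayComponent",
                         {f"{rdf}resource": f"#{r.id}"})

    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")
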