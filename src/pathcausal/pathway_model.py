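"""Reaction-centric pathway data model and the simple JSON dialect.

A pathway is modelled as a set of physical entities (proteins, small
molecules, and possibly nested complexes) plus an ordered list of
biochemical reactions, each a state transition from a set of input
participants to a set of output participants. Control links record
activation / inhibition / catalysis relationships between an entity and a
reaction. Reaction order follows the source document and is used everywhere
as the deterministic tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

from .errors import FormatError, IntegrityError, UnknownIdError


class EntityKind(str, Enum):
    PROTEIN = "protein"
    SMALL_MOLECULE = "small_molecule"
    COMPLEX = "complex"
    OTHER = "other"


class ComplexRole(str, Enum):
    INPUT_ONLY = "input_only"
    OUTPUT_ONLY = "output_only"
    BOTH = "both"
    UNUSED = "unused"


class ControlEffect(str, Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    CATALYSIS = "catalysis"


def _dedup(ids: Iterable[str]) -> list[str]:
    """Collapse duplicates preserving first-occurrence order."""
    seen: set[str] = set()
    out: list[str] = []
    for i in ids:
        if i not in seen:
            seen.add(i)
            out.append(i)
    return out


@dataclass(frozen=True)
class PhysicalEntity:
    """A protein, small molecule, complex, or other physical entity.

    ``components`` is nonempty exactly when ``kind`` is complex; component
    ids refer to other entities of the same pathway and the composition
    relation must be acyclic. Post-translationally modified forms are
    distinct entities with distinct ids.
    """

    id: str
    name: str
    kind: EntityKind = EntityKind.PROTEIN
    components: tuple[str, ...] = ()
    description: str = ""


@dataclass(frozen=True)
class Reaction:
    """A biochemical state transition.

    ``inputs`` and ``outputs`` are duplicate-free ordered id lists
    (stoichiometry is deliberately ignored; the model is set-based). An
    entity may appear on both sides.
    """

    id: str
    name: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(_dedup(self.inputs)))
        object.__setattr__(self, "outputs", tuple(_dedup(self.outputs)))


@dataclass(frozen=True)
class ControlLink:
    """An entity controlling a reaction (activation, inhibition, catalysis)."""

    controller: str
    controlled: str
    effect: ControlEffect = ControlEffect.CATALYSIS


@dataclass
class Pathway:
    """Container with referential integrity over all id references."""

    id: str = "pathway"
    name: str = ""
    entities: dict[str, PhysicalEntity] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    controls: list[ControlLink] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        entities: Iterable[PhysicalEntity],
        reactions: Iterable[Reaction],
        controls: Iterable[ControlLink] = (),
        *,
        id: str = "pathway",
        name: str = "",
    ) -> "Pathway":
        """Assemble and validate a pathway; raises IntegrityError on
        duplicate or dangling ids or cyclic complex composition."""
        emap: dict[str, PhysicalEntity] = {}
        for e in entities:
            if e.id in emap:
                raise IntegrityError(f"duplicate entity id: {e.id!r}")
            emap[e.id] = e
        pw = cls(id=id, name=name, entities=emap,
                 reactions=list(reactions), controls=list(controls))
        pw.validate()
        return pw

    def validate(self) -> None:
        rids = set()
        for r in self.reactions:
            if r.id in rids:
                raise IntegrityError(f"duplicate reaction id: {r.id!r}")
            if r.id in self.entities:
                raise IntegrityError(
                    f"id used for both an entity and a reaction: {r.id!r}")
            rids.add(r.id)
            for eid in (*r.inputs, *r.outputs):
                if eid not in self.entities:
                    raise IntegrityError(
                        f"reaction {r.id!r} references undeclared entity {eid!r}")
        for e in self.entities.values():
            if e.kind is EntityKind.COMPLEX and not e.components:
                raise IntegrityError(f"complex {e.id!r} has no components")
            if e.kind is not EntityKind.COMPLEX and e.components:
                raise IntegrityError(
                    f"non-complex {e.id!r} declares components")
            for cid in e.components:
                if cid not in self.entities:
                    raise IntegrityError(
                        f"complex {e.id!r} references undeclared component {cid!r}")
        self._check_component_acyclic()
        for c in self.controls:
            if c.controller not in self.entities:
                raise IntegrityError(
                    f"control references undeclared entity {c.controller!r}")
            if c.controlled not in rids:
                raise IntegrityError(
                    f"control references undeclared reaction {c.controlled!r}")

    def _check_component_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color: dict[str, int] = {}

        def visit(eid: str) -> None:
            state = color.get(eid, 0)
            if state == GREY:
                raise IntegrityError(
                    f"cyclic complex composition involving {eid!r}")
            if state == BLACK:
                return
            color[eid] = GREY
            for cid in self.entities[eid].components:
                visit(cid)
            color[eid] = BLACK

        for eid in self.entities:
            visit(eid)

    # -- lookups ----------------------------------------------------------

    def entity(self, eid: str) -> PhysicalEntity:
        try:
            return self.entities[eid]
        except KeyError:
            raise UnknownIdError(f"unknown entity id: {eid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise UnknownIdError(f"unknown reaction id: {rid!r}")

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction_position(self) -> dict[str, int]:
        """Document-order index of each reaction; the global tie-break key."""
        return {r.id: i for i, r in enumerate(self.reactions)}

    def entity_position(self) -> dict[str, int]:
        return {eid: i for i, eid in enumerate(self.entities)}

    def members(self, eid: str) -> frozenset[str]:
        """The entity itself plus its transitive complex components."""
        out: set[str] = set()
        stack = [eid]
        while stack:
            x = stack.pop()
            if x in out:
                continue
            out.add(x)
            stack.extend(self.entity(x).components)
        return frozenset(out)

    def iter_participants(self, r: Reaction) -> Iterator[str]:
        yield from r.inputs
        yield from r.outputs


# -- derived descriptors ---------------------------------------------------


def complex_roles(pathway: Pathway) -> dict[str, ComplexRole]:
    """Classify every complex by which reaction sides reference it.

    Complexes appearing only as inputs (or only as outputs) are rendered as
    triangles; complexes acting as both input and output across the pathway
    are rendered as diamonds; unreferenced complexes are unused.
    """
    as_input: set[str] = set()
    as_output: set[str] = set()
    for r in pathway.reactions:
        as_input.update(r.inputs)
        as_output.update(r.outputs)
    roles: dict[str, ComplexRole] = {}
    for e in pathway.entities.values():
        if e.kind is not EntityKind.COMPLEX:
            continue
        i, o = e.id in as_input, e.id in as_output
        if i and o:
            roles[e.id] = ComplexRole.BOTH
        elif i:
            roles[e.id] = ComplexRole.INPUT_ONLY
        elif o:
            roles[e.id] = ComplexRole.OUTPUT_ONLY
        else:
            roles[e.id] = ComplexRole.UNUSED
    return roles


def reaction_size(pathway: Pathway, reaction_id: str) -> int:
    """Participant count |inputs| + |outputs| after duplicate collapse;
    drives the rendered circle radius."""
    r = pathway.reaction(reaction_id)
    return len(r.inputs) + len(r.outputs)


# -- simple JSON dialect ---------------------------------------------------

_KINDS = {k.value for k in EntityKind}
_EFFECTS = {e.value for e in ControlEffect}


def parse_simple(document: str) -> Pathway:
    """Parse the simple JSON pathway dialect (see docs/methods.md).

    Top-level keys: ``id``, ``name``, ``entities``, ``reactions``,
    ``controls``. Enforces the same integrity invariants as the BioPAX
    reader.
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise FormatError("top level must be a JSON object")
    entities = []
    for rec in doc.get("entities", []):
        kind = rec.get("kind", "protein")
        if kind not in _KINDS:
            raise FormatError(f"unknown entity kind: {kind!r}")
        entities.append(PhysicalEntity(
            id=str(rec["id"]),
            name=str(rec.get("name", rec["id"])),
            kind=EntityKind(kind),
            components=tuple(rec.get("components", ())),
            description=str(rec.get("description", "")),
        ))
    reactions = []
    for rec in doc.get("reactions", []):
        reactions.append(Reaction(
            id=str(rec["id"]),
            name=str(rec.get("name", rec["id"])),
            inputs=tuple(rec.get("inputs", ())),
            outputs=tuple(rec.get("outputs", ())),
            description=str(rec.get("description", "")),
        ))
    controls = []
    for rec in doc.get("controls", []):
        effect = rec.get("effect", "catalysis")
        if effect not in _EFFECTS:
            raise FormatError(f"unknown control effect: {effect!r}")
        controls.append(ControlLink(
            controller=str(rec["controller"]),
            controlled=str(rec["controlled"]),
            effect=ControlEffect(effect),
        ))
    return Pathway.build(entities, reactions, controls,
                         id=str(doc.get("id", "pathway")),
                         name=str(doc.get("name", "")))


def write_simple(pathway: Pathway) -> str:
    """Serialize to the simple dialect: entities sorted by id, reactions in
    stored order; byte-deterministic, inverted by :func:`parse_simple`."""
    doc = {
        "id": pathway.id,
        "name": pathway.name,
        "entities": [
            {
                "id": e.id,
                "name": e.name,
                "kind": e.kind.value,
                "components": list(e.components),
                "description": e.description,
            }
            for e in sorted(pathway.entities.values(), key=lambda e: e.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "inputs": list(r.inputs),
                "outputs": list(r.outputs),
                "description": r.description,
            }
            for r in pathway.reactions
        ],
        "controls": [
            {
                "controller": c.controller,
                "controlled": c.controlled,
                "effect": c.effect.value,
            }
            for c in pathway.controls
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=False) + "\n"
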