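import pytest
from hypothesis import settings

from pathcausal import (
    ControlLink,
    EntityKind,
    Pathway,
    PhysicalEntity,
    Reaction,
    erk1_activation_synthetic,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_pathway(reactions, complexes=None, controls=(), kinds=None):
    """Terse pathway builder: ``reactions`` maps id -> (inputs, outputs);
    every referenced id becomes a protein unless listed in ``complexes``
    (id -> components) or ``kinds``."""
    complexes = complexes or {}
    kinds = kinds or {}
    ids: set[str] = set(complexes)
    for ins, outs in reactions.values():
        ids.update(ins, outs)
    for comps in complexes.values():
        ids.update(comps)
    entities = []
    for eid in sorted(ids):
        if eid in complexes:
            entities.append(PhysicalEntity(eid, eid, EntityKind.COMPLEX,
                                           tuple(complexes[eid])))
        else:
            entities.append(PhysicalEntity(eid, eid,
                                           kinds.get(eid, EntityKind.PROTEIN)))
    rxns = [Reaction(rid, rid, tuple(ins), tuple(outs))
            for rid, (ins, outs) in reactions.items()]
    return Pathway.build(entities, rxns, [ControlLink(*c) for c in controls])


@pytest.fixture
def erk():
    return erk1_activation_synthetic()


@pytest.fixture
def chain3():
    """R1: A->B, R2: B->C, R3: C->D — a causal chain."""
    return make_pathway({
        "R1": (["A"], ["B"]),
        "R2": (["B"], ["C"]),
        "R3": (["C"], ["D"]),
    })


@pytest.fixture
def cycle3_plus_tail():
    """R1->R2->R3->R1 plus R1->R4: the hand-traced cycle-breaking fixture."""
    return make_pathway({
        "R1": (["c"], ["a", "d"]),
        "R2": (["a"], ["b"]),
        "R3": (["b"], ["c"]),
        "R4": (["d"], ["e"]),
    })
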