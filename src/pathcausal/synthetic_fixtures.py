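"""Seeded generator of random pathways with planted causal structure.

Fixtures are structural, not biological: they emulate the shape of curated
pathway exports — multi-input/multi-output reactions, shared participants,
nested complexes, directed feedback cycles — without matching any empirical
degree distribution. Planted feedback cycles and planted causal edges are
returned alongside the pathway so recovery can be asserted exactly.

Construction keeps the causal structure fully under control: input-pool
entities are only ever consumed and output-pool entities only ever
produced, so the only causal edges are the dedicated chain/link entities
planted on purpose, plus the edges of explicit complex-binding reactions.
Complex assembly is emitted as a binding reaction (components in, complex
out), mirroring how curated databases model assembly, so the default
exact-match causality mode propagates through complexes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .biopax import write_biopax
from .errors import UsageError
from .pathway_model import (
    ControlEffect,
    ControlLink,
    EntityKind,
    Pathway,
    PhysicalEntity,
    Reaction,
)

_VERBS = ["phosphorylates", "binds", "dissociates", "activates",
          "translocates", "ubiquitinates", "cleaves", "inhibits"]
_NOUNS = ["kinase", "substrate", "receptor", "ligand", "dimer",
          "membrane", "nucleus", "cytosol", "signal", "cascade"]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the pathway generator; all randomness flows from ``seed``."""

    n_proteins: int = 16
    n_reactions: int = 15
    complex_probability: float = 0.3
    max_complex_size: int = 3
    n_planted_cycles: int = 1
    cycle_lengths: tuple[int, ...] = (3,)
    extra_edge_probability: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_proteins, self.n_reactions, self.max_complex_size,
               self.n_planted_cycles) < 0:
            raise UsageError("counts must be nonnegative")
        if not (0.0 <= self.complex_probability <= 1.0
                and 0.0 <= self.extra_edge_probability <= 1.0):
            raise UsageError("probabilities must lie in [0, 1]")
        if len(self.cycle_lengths) != self.n_planted_cycles:
            raise UsageError("cycle_lengths must list one length per planted cycle")
        if any(l < 2 for l in self.cycle_lengths):
            raise UsageError("planted cycle lengths must be >= 2")
        if sum(self.cycle_lengths) > self.n_reactions:
            raise UsageError("cycle lengths exceed the reaction count")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator: feedback cycles (reaction-id
    tuples anchored at their first reaction) and individual causal edges."""

    cycles: list[tuple[str, ...]] = field(default_factory=list)
    edges: set[tuple[str, str]] = field(default_factory=set)


def generate_pathway(params: GeneratorParams) -> tuple[Pathway, PlantedTruth]:
    """Build a random pathway whose exact-match causality graph contains
    precisely the planted cycles plus forward (acyclic) extra edges."""
    params.validate()
    rng = random.Random(params.seed)
    truth = PlantedTruth()

    entities: dict[str, PhysicalEntity] = {}

    def add_entity(eid: str, name: str, kind: EntityKind,
                   components: tuple[str, ...] = ()) -> str:
        entities[eid] = PhysicalEntity(
            id=eid, name=name, kind=kind, components=components,
            description=(f"{rng.choice(_NOUNS)} {rng.choice(_VERBS)} "
                         f"{rng.choice(_NOUNS)}"))
        return eid

    n_in = max(1, (params.n_proteins + 1) // 2)
    n_out = max(1, params.n_proteins - n_in)
    in_pool = [add_entity(f"IN{i:02d}", f"IN{i:02d}",
                          EntityKind.SMALL_MOLECULE if i % 5 == 4
                          else EntityKind.PROTEIN)
               for i in range(n_in)]
    out_pool = [add_entity(f"OUT{i:02d}", f"OUT{i:02d}",
                           EntityKind.SMALL_MOLECULE if i % 7 == 6
                           else EntityKind.PROTEIN)
                for i in range(n_out)]

    rids = [f"R{i:03d}" for i in range(params.n_reactions)]
    inputs: dict[str, list[str]] = {r: [] for r in rids}
    outputs: dict[str, list[str]] = {r: [] for r in rids}

    # planted cycles occupy contiguous blocks at the front
    cursor = 0
    cycle_block: dict[str, int] = {}
    for ci, length in enumerate(params.cycle_lengths):
        block = rids[cursor:cursor + length]
        cursor += length
        for r in block:
            cycle_block[r] = ci
        for i, r in enumerate(block):
            nxt = block[(i + 1) % length]
            chain = add_entity(f"CYC{ci}_{i}", f"CYC{ci}_{i}",
                               EntityKind.PROTEIN)
            outputs[r].append(chain)
            inputs[nxt].append(chain)
            truth.edges.add((r, nxt))
        truth.cycles.append(tuple(block))

    # random forward edges between reactions not sharing a planted cycle
    for i in range(params.n_reactions):
        for j in range(i + 1, params.n_reactions):
            ri, rj = rids[i], rids[j]
            if cycle_block.get(ri, -1) == cycle_block.get(rj, -2):
                continue
            if rng.random() < params.extra_edge_probability:
                link = add_entity(f"LNK_{i:03d}_{j:03d}", f"LNK_{i:03d}_{j:03d}",
                                  EntityKind.PROTEIN)
                outputs[ri].append(link)
                inputs[rj].append(link)
                truth.edges.add((ri, rj))

    # private participants from the role-segregated pools
    for r in rids:
        for e in rng.sample(in_pool, k=min(len(in_pool), rng.randint(1, 2))):
            if e not in inputs[r]:
                inputs[r].append(e)
        for e in rng.sample(out_pool, k=min(len(out_pool), rng.randint(1, 2))):
            if e not in outputs[r]:
                outputs[r].append(e)

    # complex wrapping: replace a pool input with a complex assembled by an
    # explicit binding reaction (inputs = components, output = complex)
    binding: list[Reaction] = []
    complexes: list[str] = []
    n_cplx = 0
    for r in rids:
        if rng.random() >= params.complex_probability:
            continue
        pool_ins = [e for e in inputs[r] if e in set(in_pool)]
        if not pool_ins:
            continue
        wrapped = rng.choice(pool_ins)
        size = rng.randint(2, max(2, params.max_complex_size))
        comps = [wrapped]
        candidates = [e for e in in_pool if e != wrapped] + [
            c for c in complexes if rng.random() < 0.3]
        for c in rng.sample(candidates, k=min(size - 1, len(candidates))):
            if c not in comps:
                comps.append(c)
        cid = add_entity(f"CPX{n_cplx:02d}", f"CPX{n_cplx:02d}",
                         EntityKind.COMPLEX, components=tuple(sorted(comps)))
        complexes.append(cid)
        bid = f"B{n_cplx:03d}"
        n_cplx += 1
        binding.append(Reaction(
            id=bid, name=f"Binding of {cid}",
            inputs=tuple(comps), outputs=(cid,),
            description=f"binding forms the complex {cid}"))
        inputs[r] = [cid if e == wrapped else e for e in inputs[r]]
        truth.edges.add((bid, r))
        for c in comps:
            if c in complexes:  # nested complex consumed here too
                producer = f"B{complexes.index(c):03d}"
                truth.edges.add((producer, bid))

    # single-role complexes for glyph variety: an unproduced input complex
    # and an unconsumed output complex (fresh sink/source components)
    n_solo = 0
    for r in rids:
        if rng.random() < params.complex_probability / 2:
            comps = tuple(add_entity(f"SOLO{n_solo}_{k}", f"SOLO{n_solo}_{k}",
                                     EntityKind.PROTEIN)
                          for k in range(2))
            cid = add_entity(f"SCPX{n_solo:02d}", f"SCPX{n_solo:02d}",
                             EntityKind.COMPLEX, components=comps)
            n_solo += 1
            if rng.random() < 0.5:
                inputs[r].append(cid)
            else:
                outputs[r].append(cid)

    reactions = []
    for i, r in enumerate(rids):
        verb = rng.choice(_VERBS)
        subj = inputs[r][0] if inputs[r] else "nothing"
        obj = outputs[r][0] if outputs[r] else "nothing"
        reactions.append(Reaction(
            id=r, name=f"{subj} {verb} {obj}",
            inputs=tuple(inputs[r]), outputs=tuple(outputs[r]),
            description=(f"{subj} {verb} {obj} in the "
                         f"{rng.choice(_NOUNS)} {rng.choice(_NOUNS)}")))
    reactions.extend(binding)

    controls = []
    for r in reactions:
        if r.inputs and rng.random() < 0.2:
            controls.append(ControlLink(
                controller=rng.choice(in_pool), controlled=r.id,
                effect=rng.choice(list(ControlEffect))))

    pathway = Pathway.build(entities.values(), reactions, controls,
                            id=f"synthetic_{params.seed}",
                            name=f"synthetic pathway (seed {params.seed})")
    return pathway, truth


def generate_biopax_doc(pathway: Pathway) -> str:
    """BioPAX Level-3 serialization of a pathway (see
    :func:`pathcausal.biopax.write_biopax`)."""
    return write_biopax(pathway)


def varied_params(seed: int, max_reactions: int = 50) -> GeneratorParams:
    """Deterministically varied generator settings for sweep-style tests:
    size, cycle count, and edge density all derive from the seed."""
    rng = random.Random(seed * 7919 + 13)
    n_reactions = rng.randint(6, max_reactions)
    n_cycles = rng.randint(0, min(3, n_reactions // 3))
    lengths = []
    budget = n_reactions
    for _ in range(n_cycles):
        if budget < 2:
            break
        l = rng.randint(2, min(5, budget))
        lengths.append(l)
        budget -= l
    return GeneratorParams(
        n_proteins=rng.randint(6, 20),
        n_reactions=n_reactions,
        complex_probability=rng.uniform(0.1, 0.4),
        max_complex_size=3,
        n_planted_cycles=len(lengths),
        cycle_lengths=tuple(lengths),
        extra_edge_probability=rng.uniform(0.05, 0.25),
        seed=seed,
    )
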