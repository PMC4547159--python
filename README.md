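# pathcausal

Reaction-centric causality analysis for biological pathways.

Curated pathway databases describe a pathway as a set of biochemical
reactions — state transitions with multiple input and output participants
(proteins, small molecules, and possibly nested complexes) — exchanged as
BioPAX Level-3 OWL. For a systems or molecular biologist the interesting
questions are *causal*: what lies downstream of a perturbed protein, how
many reactions separate two proteins, where are the feedback loops, and
which reactions are common downstream targets of several inputs.
`pathcausal` answers these questions on the reaction graph rather than on a
node-link drawing: it parses BioPAX (or a simple JSON dialect) into a
validated pathway model and computes the causal structure directly.

## The model

Let a pathway be a set of reactions, each with participant sets
`in(r)` and `out(r)`. A **causal relationship** `r₁ → r₂` holds iff

```
out(r₁) ∩ in(r₂) ≠ ∅        (r₁ ≠ r₂)
```

with the shared entities recorded as the edge's *witness*. `r₂` is then
*downstream* of `r₁`. On this directed graph the package computes:

- **Downstream closure** — breadth-first levels from seed reactions, each
  reaction visited once (a branch looping back to an already-visited
  reaction terminates, so cyclic pathways animate finitely).
- **Hop distances** — the minimum number of reactions on an alternating
  entity → reaction → entity path from a source entity; unreachable
  entities carry no number.
- **Feedback loops** — elementary directed cycles, enumerated inside
  strongly connected components with a truncation cap.
- **Common downstream** — the intersection of the closures of two or more
  seed sets.
- **Cycle-tolerant topological ordering** — Kahn elimination modified so
  that when no zero-in-degree node remains, the node with maximum residual
  out-degree is removed (greedily cutting remaining cycles). Edges pointing
  backwards under the order ("back arcs") are exactly the arcs that can
  close feedback loops.
- **Crossing-reducing layout** — a five-column arrangement (input proteins,
  input complexes, reactions, output complexes, output proteins); proteins
  are chained greedily so that proteins sharing reactions or complexes sit
  adjacent, complexes and reactions sit at the barycenter of their placed
  members, and an inversion count measures edge crossings per column gap.

Matching is by exact participant id by default (curated data models
assembly and dissociation as reactions, so causality propagates through
complexes on its own); an opt-in mode also matches an entity against any
participant complex that transitively contains it. Control links
(activation / inhibition / catalysis) can contribute edges on a separate
channel.

## Worked example

The package bundles a small synthetic reconstruction of an ERK1-activation
module (kinase binding, phosphorylation, dissociation, dimerisation,
nuclear translocation, plus an unconnected MEK1 phosphorylation step):

```python
import pathcausal as pc

pw = pc.erk1_activation_synthetic()
g = pc.build_causality_graph(pw)
print(len(pw.reactions), len(g.edges))
for e in g.edges:
    print(f"  {e.source} -> {e.target}   via {sorted(e.witness)}")
print([l.cycle for l in pc.find_feedback_loops(g)])
print(pc.cyclic_toposort(g).order)
print(pc.shortest_hops(pw, g, "ERK1").distances)
```

prints

```
6 5
  R1 -> R2   via ['CPX_ERK1_PMEK1']
  R2 -> R3   via ['CPX_PERK1_PMEK1']
  R3 -> R1   via ['PMEK1S']
  R3 -> R4   via ['PERK1']
  R4 -> R5   via ['CPX_PERK1_DIMER']
[('R1', 'R2', 'R3')]
['R6', 'R3', 'R1', 'R2', 'R4', 'R5']
{'ERK1': 0, 'CPX_ERK1_PMEK1': 1, 'ADP': 2, 'CPX_PERK1_PMEK1': 2,
 'PMEK1S': 3, 'PERK1': 3, 'CPX_PERK1_DIMER': 4, 'CPX_PERK1_DIMER_NUC': 5}
```

Six reactions are linked by five causal relationships; binding,
phosphorylation and dissociation form one feedback loop (the dissociation
step regenerates phospho-MEK1, an input of the binding step); the
phosphorylated MEK1 form sits three reaction hops downstream of ERK-1,
while unmodified MEK1 is not downstream at all and so carries no distance.
The topological ordering removes the disconnected reaction R6 first, then
breaks the cycle at R3 (the maximum-residual-out-degree node).

The same analyses are available from the shell:

```
pathcausal synth --seed 7 --reactions 30 --cycles 2x3 -o fixture.json
pathcausal loops fixture.json
pathcausal downstream fixture.json --seed R000 --report-format tsv
pathcausal hops fixture.json --from IN00
pathcausal render fixture.json -o figure.svg
pathcausal convert fixture.json --to biopax -o fixture.owl
```

`render` writes a deterministic SVG of the five-column view with
yellow-to-black gradient arcs marking causal direction (forward arcs bow
right of the reaction column, back arcs left).

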