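# Methods

This note records the model, the conventions the implementation commits
to, and what the synthetic fixtures do and do not establish.

## Pathway model

A pathway is a container of physical entities, an ordered list of
reactions, and control links, with referential integrity enforced on load:
ids are unique, every participant/component/controller reference resolves,
and complex composition is acyclic. Reactions keep their source-document
order; that order is the global tie-break for every deterministic output
(orderings, level sorting, edge sorting), with lexicographic id as the
final key. Duplicate participants within one side of a reaction are
collapsed on load — the model is set-based and stoichiometry is ignored.
An entity may appear on both sides of the same reaction.

Post-translationally modified forms are distinct entities: identity is the
BioPAX resource URI fragment (falling back to the display name only when
no fragment exists), so a phosphorylated kinase and its unmodified form
never alias.

### BioPAX subset

The reader consumes `BiochemicalReaction` (`left` → inputs, `right` →
outputs), `Protein`, `SmallMolecule`, `Complex` (`component`, recursive),
and `Catalysis`/`Control`/`Modulation` (`controller`, `controlled`,
`controlType`). Other physical-entity classes (`Dna`, `Rna`, `Gene`,
generic `PhysicalEntity`) map to kind `other`; all remaining classes are
skipped with a logged count. `conversionDirection` is never obeyed — left
is always the input side — but a contrary declaration is logged. Control
links whose endpoints fall outside the entity→reaction model (e.g. a
control targeting a whole pathway) are skipped with a logged count;
dangling *participant* or *component* references are hard integrity
errors naming the offending id. Document order of reactions is recovered
by a separate streaming XML pass, since RDF graphs are unordered.

### Simple dialect

A UTF-8 JSON object with keys `id`, `name`, `entities`, `reactions`,
`controls`:

```json
{"entities":  [{"id": "...", "name": "...", "kind": "protein|small_molecule|complex|other",
                "components": ["..."], "description": "..."}],
 "reactions": [{"id": "...", "name": "...", "inputs": ["..."],
                "outputs": ["..."], "description": "..."}],
 "controls":  [{"controller": "...", "controlled": "...",
                "effect": "activation|inhibition|catalysis"}]}
```

The writer sorts entities by id, keeps reactions in stored order, and is
byte-deterministic; `parse_simple` inverts it exactly.

## Causality graph

`r₁ → r₂` iff an output of `r₁` matches an input of `r₂` (`r₁ ≠ r₂`),
witness = the matched output entities. Matching modes:

- **exact** (default): participant-id equality. In curated data complex
  assembly/dissociation are explicit reactions, so exact matching already
  propagates causality through complexes.
- **expand_complex_components** (opt-in): an entity additionally matches
  any participant complex that transitively contains it, in either
  direction. Expansion can only add edges (tested monotonicity).

Self-loop edges (a reaction regenerating its own input) are suppressed
unless explicitly enabled — downstream animation would otherwise never
terminate on them. Control-mediated edges (controller produced by `r₁`,
controlling `r₂`) are opt-in and carried on a separate `control` channel,
because the core causal relation is defined by shared participants only.

Downstream closure is plain BFS with single visitation; level `d` holds
exactly the reactions first reachable in `d` steps. Common downstream of
k ≥ 2 seed sets is the intersection of their closures, with the seeds
themselves excluded unless requested. Hop distances run BFS on the
bipartite relation (entity feeds reactions consuming it; a reaction yields
its outputs); the source has distance 0 and unreachable entities are
omitted rather than given a sentinel.

## Cycle-tolerant ordering

Modified Kahn elimination on a working copy: remove the earliest (pathway
order) zero-residual-in-degree node when one exists, otherwise the node
with maximum **residual** out-degree, ties by pathway order. Residual
rather than original out-degree is the default because the elimination
operates on the remaining graph; the original-out-degree variant is
available behind a flag for comparison. On a DAG the result is a valid
topological order (tested on generated DAG sweeps). Back arcs are the
edges whose target precedes their source; every directed cycle contributes
at least one, which is what makes left-hand arcs a visual feedback-loop
cue. The tendency of the ordering to cluster interrelated reactions is
treated as emergent behavior, not an asserted invariant.

## Feedback loops

Elementary cycles are enumerated by an anchored DFS: for each node `s` in
pathway order, cycles whose earliest member is `s` are found by searching
only nodes ordered after `s` within `s`'s residual strongly connected
component (components via an iterative Tarjan). Starting at the anchor
makes rotation normalization automatic and output canonical. Because cycle
counts are worst-case exponential, enumeration truncates at a cap
(default 10 000) with an explicit `truncated` flag — truncation is
signaled, never raised. A cheaper `backarc` method closes each back arc of
the cycle-tolerant ordering with a shortest forward path, yielding one
representative loop per back arc.

## Layout and crossings

Columns: complexes that are direct reaction participants form the complex
columns; their transitive non-complex components, plus direct non-complex
participants, form the protein columns (small molecules and `other`
entities are treated like proteins for layout). An entity on both sides
appears in both its columns.

Protein order is one global greedy chain: start at the given protein (or
the first in pathway order), repeatedly append the unplaced protein
sharing the most reactions-or-complexes with the last placed one (ties by
pathway order), jumping to the next unplaced protein when nothing is
shared. Complexes and reactions are placed at the barycenter (mean
position) of their already-placed members/participants — the chaining rule
is the specified heuristic; barycenter placement for the other columns is
this package's choice.

Crossings are counted per adjacent column gap as strict inversions
`(a_e − a_f)(b_e − b_f) < 0` (merge-count, O(E log E)); links sharing an
endpoint yield a zero product and never count. A protein participating in
a reaction directly spans two gaps; its link is counted once, in the
complexes↔reactions gap, with the protein-column position as ordinate — a
documented convention, since column positions are ordinal, not geometric.
Causal arcs within the reaction column are excluded from the metric (they
are drawn as arcs, not straight links). Optimal crossing minimization is
NP-hard and out of scope; the greedy order is only asserted to beat the
median of random shuffles on most generated pathways (a statistical
property, fixed seeds).

## Text analytics

Tokenization: lowercase, split on non-alphanumeric characters, drop tokens
shorter than 3 characters and tokens on the bundled ~100-word stop list
(`data/stopwords.txt`, shipped as a data file so it is auditable). Term
rank is by total occurrence count (ties lexicographic); per-description
presence counting is available behind a flag. Co-occurrence of a term pair
is the number of descriptions containing both (presence, not
multiplicity), reported unthresholded — any display cutoff is a rendering
option. Search is case-insensitive substring match over names and
descriptions; the empty phrase matches nothing. No stemming, TF-IDF, or
multilingual support.

## Rendering

The SVG figure uses fixed geometry (column x-positions, 28 px row pitch)
because the source data carries none. Reactions are circles with radius
3 + 1.5·(participant count) px; complexes are triangles (single-role) or
diamonds (dual-role) with linear size in component count; causal arcs are
semicircles — right of the reaction column for forward edges, left for
back arcs — each filled by a per-arc linear gradient from yellow
(`#ffd700`) at the source to black at the target. Faded link classes
render at opacity 0.15. Output is byte-deterministic. Animation is a list
of cumulative highlight frames, one per BFS level. No GUI, brushing, or
video encoding.

## Synthetic fixtures

The generator emulates the *shape* of curated pathway exports, not their
biology: role-segregated protein pools (input-pool entities are only ever
consumed, output-pool only ever produced), dedicated chain entities that
realize planted feedback cycles verbatim, forward-only extra edges between
reactions of different cycles, and complex assembly emitted as explicit
binding reactions (components in, complex out) so exact matching
propagates through complexes. Binding reactions have no incoming causal
edges by construction, so with `extra_edge_probability = 0` the elementary
cycles of the generated graph are exactly the planted ones — this is what
the recovery tests assert. Defaults (16 proteins, 15 reactions, complex
probability 0.3, one planted 3-cycle, extra-edge probability 0.15) are
desk-scale values chosen to resemble the small-to-medium curated modules
the analyses target; `varied_params(seed)` derives sizes up to 50
reactions for sweep tests. All randomness flows from a single seeded
generator; identical parameters give byte-identical serializations.

What passing tests therefore show: the algorithms are exact on graphs with
known ground truth and agree with independent oracles across seeded
sweeps. What they do not show: behavior on empirical degree distributions,
very large pathways (hundreds of reactions are generated in timing tests,
but no empirical scaling claim is made), or database-specific modeling
quirks beyond the BioPAX subset described above.

## Problem sizes and numerical choices

Sweep tests use 50 generated pathways of up to 50 reactions for edge and
reachability checks, 20 fixtures for loop recovery/hop tables/common
downstream/crossing comparisons (hop fixtures at ≤ 12 reactions so the
exhaustive path oracle stays exact), and 100 random shuffles per fixture
for the crossing Monte-Carlo — sizes chosen so each check completes in
seconds on one core while exercising non-trivial structure. There are no
floating-point tolerances anywhere: every computation is combinatorial and
compared exactly; barycenter means are the only real-valued intermediate
and affect ordering only through exact comparisons with deterministic
tie-breaks.

## Known limitations

- No SBML/SBGN/KGML input, no BioPAX writing beyond the modelled subset,
  no stoichiometry, compartments, or kinetics.
- Knockout semantics are reachability-only: perturbing an entity
  highlights its downstream cone; entities are not removed and
  reachability of others is not recomputed.
- Feedback loops are defined on the reaction-level graph only;
  entity-level cycles are not separately enumerated, and loops spanning
  multiple pathways are out of scope.
- The crossing metric is ordinal per column gap and is not a geometric
  crossing count of the rendered figure.
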