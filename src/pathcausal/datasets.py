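"""Bundled example pathways.

The ERK1 activation example is a *synthetic reconstruction*: a small
hand-written pathway shaped like the curated ERK1 activation module of the
MAPK/ERK cascade (kinase binding, phosphorylation, dissociation,
dimerisation, nuclear translocation, plus an unconnected MEK1
phosphorylation step). It is not a database export; it exists so the
worked examples and tests run offline.
"""

from importlib import resources

from .pathway_model import Pathway, parse_simple


def erk1_activation_synthetic() -> Pathway:
    """The bundled synthetic ERK1-activation-like pathway: 6 reactions
    linked by 5 causal relationships, one three-reaction feedback loop, and
    a phosphorylated MEK1 form three reaction hops downstream of ERK-1."""
    text = (resources.files("pathcausal") / "data"
            / "erk1_activation_synthetic.json").read_text()
    return parse_simple(text)
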