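"""Description-text analytics: search filtering, top-k term ranking, and
term co-occurrence counts for the arc diagrams over term lists.

Tokenization is deliberately simple and auditable: lowercase, split on
non-alphanumeric characters, drop tokens shorter than three characters and
tokens on the bundled English stop list (``data/stopwords.txt``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .pathway_model import Pathway

_TOKEN_RE = re.compile(r"[^0-9a-z]+")
_MIN_TOKEN_LEN = 3


@lru_cache(maxsize=1)
def stop_words() -> frozenset[str]:
    text = (resources.files("pathcausal") / "data" / "stopwords.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#"))


def tokenize(text: str) -> list[str]:
    """Retained tokens of one description, in order of occurrence."""
    stops = stop_words()
    return [t for t in _TOKEN_RE.split(text.lower())
            if len(t) >= _MIN_TOKEN_LEN and t not in stops]


@dataclass
class TermStats:
    ranked: list[tuple[str, int]]
    cooccurrence: dict[frozenset[str], int]


def term_frequencies(texts: list[str], per_document: bool = False) -> dict[str, int]:
    """Raw term table. ``per_document`` counts each term at most once per
    description instead of per occurrence."""
    freq: dict[str, int] = {}
    for text in texts:
        toks = tokenize(text)
        if per_document:
            toks = sorted(set(toks))
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    return freq


def top_terms(texts: list[str], k: int = 20,
              per_document: bool = False) -> list[tuple[str, int]]:
    """The k most common description terms, ties broken lexicographically.

    The default of 20 matches the term lists shown next to the pathway
    view.
    """
    freq = term_frequencies(texts, per_document=per_document)
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def term_cooccurrence(texts: list[str],
                      terms: list[str] | set[str]) -> dict[frozenset[str], int]:
    """For each unordered pair of the supplied terms, the number of
    descriptions containing both (presence, not multiplicity)."""
    term_list = sorted(set(terms))
    counts: dict[frozenset[str], int] = {}
    for i, a in enumerate(term_list):
        for b in term_list[i + 1:]:
            counts[frozenset((a, b))] = 0
    for text in texts:
        present = set(tokenize(text))
        hit = [t for t in term_list if t in present]
        for i, a in enumerate(hit):
            for b in hit[i + 1:]:
                counts[frozenset((a, b))] += 1
    return counts


def term_stats(texts: list[str], k: int = 20) -> TermStats:
    ranked = top_terms(texts, k)
    return TermStats(ranked=ranked,
                     cooccurrence=term_cooccurrence(texts,
                                                    [t for t, _ in ranked]))


def search_filter(pathway: Pathway, phrase: str) -> tuple[set[str], set[str]]:
    """Reactions and entities whose name or description contains the phrase
    (case-insensitive substring); an empty phrase matches nothing."""
    if phrase == "":
        return set(), set()
    needle = phrase.lower()
    rids = {r.id for r in pathway.reactions
            if needle in r.name.lower() or needle in r.description.lower()}
    eids = {e.id for e in pathway.entities.values()
            if needle in e.name.lower() or needle in e.description.lower()}
    return rids, eids
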