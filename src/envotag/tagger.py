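"""Dictionary-based named entity recognition over isolation-source text.

The tagger matches ontology term names and EXACT synonyms against free
text such as ``"fresh water from a boreal lake"``.  Matching is token
based (so "watershed" never matches "water"), case-insensitive, and
leftmost-longest: at each position the longest token n-gram present in
the lexicon wins and consumes its span, so "fresh water" suppresses a
separate "water" hit.  A stop-list removes ambiguous surface forms from
the lexicon before any matching happens.

No stemming or plural handling is applied by default; optional
``strip_plural_s`` adds a conservative trailing-"s" fallback.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .ontology import OntologyGraph

# min characters for a surface form; suppresses spurious acronym matches
MIN_SURFACE_CHARS = 3

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def normalize_form(text: str) -> str:
    """Lowercase and collapse all non-alphanumeric runs to single spaces."""
    return " ".join(_TOKEN_RE.findall(text.lower()))


@dataclass
class TagHit:
    """One match of a lexicon surface form in a source text.

    ``start``/``end`` are 0-based half-open character offsets such that
    ``text[start:end]`` case-insensitively normalizes to a surface form
    mapped to ``term_id``.
    """

    term_id: str
    surface: str
    start: int
    end: int


@dataclass
class Lexicon:
    """Normalized surface form -> set of term ids, plus the longest form length."""

    entries: dict[str, set[str]] = field(default_factory=dict)
    max_tokens: int = 0


def load_stoplist(path=None) -> set[str]:
    """Read a stop-list: one lowercase form per line, '#' comments allowed.

    Without a path, the packaged default list of ambiguous words is used.
    """
    if path is None:
        text = resources.files("envotag.data").joinpath("stoplist.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    forms = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            forms.add(normalize_form(line))
    return forms


def build_lexicon(graph: OntologyGraph, stoplist: Iterable[str] = ()) -> Lexicon:
    """Build the tagging dictionary from term names and synonyms.

    One entry per distinct normalized name/synonym that is not in the
    stop-list and is at least ``MIN_SURFACE_CHARS`` long; a form naming
    several terms maps to all of them.
    """
    stop = set(stoplist)
    entries: dict[str, set[str]] = {}
    for term in graph.terms.values():
        for surface in [term.name, *term.synonyms]:
            form = normalize_form(surface)
            if not form or len(form) < MIN_SURFACE_CHARS or form in stop:
                continue
            entries.setdefault(form, set()).add(term.term_id)
    max_tokens = max((form.count(" ") + 1 for form in entries), default=0)
    return Lexicon(entries=entries, max_tokens=max_tokens)


def tag_text(lexicon: Lexicon, text: str, strip_plural_s: bool = False) -> list[TagHit]:
    """Tag free text with ontology terms, leftmost-longest, non-overlapping.

    Returns hits in text order; an ambiguous surface form mapped to several
    terms produces one :class:`TagHit` per term (identical spans, term ids
    sorted).  Empty text yields an empty list.
    """
    tokens = [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    hits: list[TagHit] = []
    i = 0
    while i < len(tokens):
        matched = 0
        for n in range(min(lexicon.max_tokens, len(tokens) - i), 0, -1):
            form = " ".join(tok for tok, _, _ in tokens[i : i + n])
            term_ids = lexicon.entries.get(form)
            if term_ids is None and strip_plural_s and form.endswith("s"):
                term_ids = lexicon.entries.get(form[:-1])
            if term_ids:
                start, end = tokens[i][1], tokens[i + n - 1][2]
                for term_id in sorted(term_ids):
                    hits.append(TagHit(term_id, text[start:end], start, end))
                matched = n
                break
        i += matched or 1
    return hits


def count_terms(hits: Iterable[TagHit]) -> dict[str, int]:
    """Frequency of occurrence of each term over a list of hits."""
    return dict(Counter(hit.term_id for hit in hits))
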