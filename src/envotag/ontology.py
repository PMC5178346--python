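"""Environment Ontology (EnvO) handling.

EnvO distributes as an OBO flat file whose ``[Term]`` stanzas define a
hierarchy of environment descriptors linked by ``is_a`` relations.  The
hierarchy is an acyclic directed graph (a term may have several parents),
and two operations on it drive the pipeline's post-processing:

* *backtracking* propagates a term's frequency count to every ancestor,
* *restriction* keeps only the descendants of one chosen term.

Only ``is_a`` edges are traversed; ``part_of`` and other relationships are
ignored.  Obsolete terms are dropped at parse time.  By default only EXACT
synonyms enter the tagging lexicon downstream (precision-first tagging);
pass ``synonym_scopes`` to widen this.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import OboParseError, OntologyCycleError, UnknownTermError

# '"surface water" EXACT [MIGS:0001]' -> text + scope
_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z]+)?')


@dataclass
class OntologyTerm:
    """One ontology term: identifier, label, synonyms and is_a parents."""

    term_id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    obsolete: bool = False


class OntologyGraph:
    """An acyclic directed graph of ontology terms.

    Edges point child -> parent along ``is_a``.  ``terms`` maps every
    non-obsolete term id to its :class:`OntologyTerm`.
    """

    def __init__(self, terms: dict[str, OntologyTerm]):
        self.terms = terms
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(terms)
        for term in terms.values():
            for parent in term.parents:
                if parent in terms:
                    self.graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyCycleError(f"is_a relation contains a cycle: {path}")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id].name if term_id in self.terms else term_id

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown ontology term: {term_id!r}")

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable upward via is_a, excluding ``term_id`` itself."""
        self._require(term_id)
        # edges run child -> parent, so upward reachability is nx.descendants
        return nx.descendants(self.graph, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All terms from which ``term_id`` is reachable via is_a."""
        self._require(term_id)
        return nx.ancestors(self.graph, term_id)

    def restrict_to(self, root: str, term_ids: Iterable[str]) -> set[str]:
        """Subset of ``term_ids`` lying at or below ``root``.

        A term survives iff it equals ``root`` or has ``root`` among its
        ancestors; everything not reachable through ``root`` is removed.
        """
        self._require(root)
        allowed = self.descendants(root) | {root}
        return set(term_ids) & allowed


def _parse_synonym(value: str, line_no: int) -> tuple[str, str]:
    m = _SYNONYM_RE.match(value.strip())
    if not m:
        raise OboParseError(f"line {line_no}: malformed synonym line: {value!r}")
    text = m.group("text").replace('\\"', '"')
    return text, m.group("scope") or "RELATED"


def parse_obo(
    path, synonym_scopes: tuple[str, ...] = ("EXACT",)
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Keeps every non-obsolete ``[Term]`` stanza; synonyms are restricted to
    the given scopes (default EXACT only).  ``is_a`` targets pointing at
    obsolete or undefined terms are dropped silently, matching how released
    ontologies handle dangling references.

    Raises
    ------
    OboParseError
        On a malformed stanza, naming the offending line.
    OntologyCycleError
        If the is_a relation is cyclic.
    """
    terms: dict[str, OntologyTerm] = {}
    current: OntologyTerm | None = None
    in_term_stanza = False

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip() if not raw.lstrip().startswith("!") else ""
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(f"line {line_no}: malformed stanza header: {line!r}")
                if current is not None:
                    _finish_term(terms, current, line_no)
                    current = None
                in_term_stanza = line == "[Term]"
                if in_term_stanza:
                    current = OntologyTerm(term_id="")
                continue
            if not in_term_stanza:
                continue  # header lines and non-Term stanzas (e.g. [Typedef])
            if ":" not in line:
                raise OboParseError(f"line {line_no}: expected 'tag: value', got {line!r}")
            tag, _, value = line.partition(":")
            tag, value = tag.strip(), value.strip()
            assert current is not None
            if tag == "id":
                if not value:
                    raise OboParseError(f"line {line_no}: empty term id")
                current.term_id = value
            elif tag == "name":
                current.name = value
            elif tag == "is_a":
                current.parents.append(value.split()[0] if value else "")
            elif tag == "synonym":
                text, scope = _parse_synonym(value, line_no)
                if scope in synonym_scopes:
                    current.synonyms.append(text)
            elif tag == "is_obsolete":
                current.obsolete = value.lower() == "true"

    if current is not None:
        _finish_term(terms, current, line_no)
    if not terms:
        raise OboParseError(f"no [Term] stanzas found in {path}")

    # drop dangling is_a targets (obsolete/undefined parents)
    for term in terms.values():
        term.parents = [p for p in term.parents if p in terms]
    return OntologyGraph(terms)


def _finish_term(terms: dict[str, OntologyTerm], term: OntologyTerm, line_no: int) -> None:
    if term.obsolete:
        return
    if not term.term_id:
        raise OboParseError(f"line {line_no}: [Term] stanza without an id")
    if term.term_id in terms:
        raise OboParseError(f"line {line_no}: duplicate term id {term.term_id!r}")
    terms[term.term_id] = term
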