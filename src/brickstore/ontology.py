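"""Controlled vocabularies: terms, hierarchies, and label resolution.

An :class:`Ontology` is a set of :class:`Term` nodes arranged in a
multi-parent DAG (real-world vocabularies such as ENVO or ChEBI are DAGs,
not trees).  Terms ground every name, unit, and categorical value in the
data model, so that synonymous concepts collapse onto one identifier and
a search for a general concept ("carbohydrate") can be expanded to all of
its descendants ("glucose", ...).

Documents use a minimal OBO-like stanza dialect::

    [Term]
    id: EX:0000001
    name: carbohydrate
    synonym: "saccharide"
    is_a: EX:0000000 ! chemical entity

Recognised keys are ``id``, ``name``, ``synonym`` (quoted string, optional
trailing scope/xref markers ignored), and ``is_a`` (CURIE, optional
``! label`` comment).  Anything else is a parse error.  Duplicate ids,
dangling ``is_a`` targets, and cycles are integrity errors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    AmbiguousTermError,
    OntologyIntegrityError,
    OntologyParseError,
    TermNotFoundError,
)

CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*:[A-Za-z0-9_.\-/]+$")

__all__ = [
    "Term",
    "Ontology",
    "TermIndex",
    "load_ontology",
    "parse_ontology_text",
    "resolve_term",
    "expand_term",
    "normalize_label",
]


def normalize_label(label: str) -> str:
    """Case-fold and collapse internal whitespace for label matching."""
    return " ".join(label.split()).casefold()


def is_curie(text: str) -> bool:
    return bool(CURIE_RE.match(text))


@dataclass(frozen=True)
class Term:
    """A controlled-vocabulary node.

    ``id`` is a CURIE (``PREFIX:LOCALID``); ``parent_ids`` point to broader
    terms within the same ontology.
    """

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()
    ontology_id: str = ""

    def __post_init__(self):
        if not is_curie(self.id):
            raise OntologyParseError(f"not a CURIE: {self.id!r}")

    @property
    def prefix(self) -> str:
        return self.id.split(":", 1)[0]


class Ontology:
    """An immutable, indexed term set with hierarchy queries."""

    def __init__(self, ontology_id: str, terms: Iterable[Term]):
        self.id = ontology_id
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyIntegrityError(f"duplicate term id {t.id}")
            self.terms[t.id] = t

        for t in self.terms.values():
            for p in t.parent_ids:
                if p not in self.terms:
                    raise OntologyIntegrityError(
                        f"term {t.id} has dangling parent {p}"
                    )

        # child relation as a DiGraph: edge parent -> child
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parent_ids:
                self._graph.add_edge(p, t.id)
        if not nx.is_directed_acyclic_graph(self._graph):
            cyc = nx.find_cycle(self._graph)
            raise OntologyIntegrityError(f"cycle in parent relation: {cyc}")

        # normalized label/synonym -> set of CURIEs
        self.label_index: dict[str, set[str]] = {}
        for t in self.terms.values():
            for name in (t.label, *t.synonyms):
                self.label_index.setdefault(normalize_label(name), set()).add(t.id)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise TermNotFoundError(f"{term_id} not in ontology {self.id}") from None

    def resolve(self, query: str) -> Term:
        return resolve_term(self, query)

    def expand(self, term: Term | str) -> set[Term]:
        return expand_term(self, term)

    def roots(self) -> list[Term]:
        return [t for t in self.terms.values() if not t.parent_ids]

    def children(self, term_id: str) -> list[Term]:
        self[term_id]
        return [self.terms[c] for c in self._graph.successors(term_id)]

    def is_ancestor(self, ancestor_id: str, descendant_id: str) -> bool:
        """True iff ``descendant_id`` is ``ancestor_id`` or below it."""
        if ancestor_id == descendant_id:
            return ancestor_id in self.terms
        return (
            ancestor_id in self.terms
            and descendant_id in self.terms
            and nx.has_path(self._graph, ancestor_id, descendant_id)
        )


_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _parse_stanza(lines: list[tuple[int, str]], ontology_id: str) -> Term:
    term_id = None
    name = None
    synonyms: list[str] = []
    parents: list[str] = []
    for lineno, line in lines:
        if ":" not in line:
            raise OntologyParseError(f"line {lineno}: expected 'key: value'")
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key == "id":
            if term_id is not None:
                raise OntologyParseError(f"line {lineno}: repeated id")
            if not is_curie(value):
                raise OntologyParseError(f"line {lineno}: id {value!r} is not a CURIE")
            term_id = value
        elif key == "name":
            name = value
        elif key == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OntologyParseError(
                    f"line {lineno}: synonym must be a quoted string"
                )
            synonyms.append(m.group("text").replace('\\"', '"'))
        elif key == "is_a":
            target = value.split("!", 1)[0].strip()
            if not is_curie(target):
                raise OntologyParseError(
                    f"line {lineno}: is_a target {target!r} is not a CURIE"
                )
            parents.append(target)
        else:
            raise OntologyParseError(f"line {lineno}: unknown key {key!r}")
    if term_id is None:
        raise OntologyParseError("stanza without an id")
    if name is None:
        raise OntologyParseError(f"term {term_id} has no name")
    return Term(
        id=term_id,
        label=name,
        synonyms=tuple(synonyms),
        parent_ids=tuple(parents),
        ontology_id=ontology_id,
    )


def parse_ontology_text(text: str, ontology_id: str) -> Ontology:
    """Parse an ontology document from a string.  See module docstring."""
    stanzas: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line == "[Term]":
            current = []
            stanzas.append(current)
            continue
        if line.startswith("[") and line.endswith("]"):
            current = None  # unknown stanza types are skipped whole
            continue
        if current is None:
            # header lines (e.g. format-version:) before the first stanza
            if ":" in line:
                continue
            raise OntologyParseError(f"line {lineno}: text outside a [Term] stanza")
        current.append((lineno, line))
    return Ontology(ontology_id, [_parse_stanza(s, ontology_id) for s in stanzas])


def load_ontology(source, ontology_id: str | None = None) -> Ontology:
    """Load an ontology from a path or file object.

    ``ontology_id`` defaults to the file stem.
    """
    import pathlib

    if hasattr(source, "read"):
        text = source.read()
        oid = ontology_id or "ontology"
    else:
        p = pathlib.Path(source)
        text = p.read_text(encoding="utf-8")
        oid = ontology_id or p.stem
    return parse_ontology_text(text, oid)


def resolve_term(ontology: Ontology, query: str) -> Term:
    """Resolve a CURIE (exact) or a label/synonym (case-insensitive).

    Raises :class:`TermNotFoundError` / :class:`AmbiguousTermError`.
    """
    if is_curie(query) and query in ontology.terms:
        return ontology.terms[query]
    hits = ontology.label_index.get(normalize_label(query), set())
    if not hits:
        raise TermNotFoundError(f"{query!r} not found in ontology {ontology.id}")
    if len(hits) > 1:
        raise AmbiguousTermError(
            f"{query!r} matches several terms in {ontology.id}: {sorted(hits)}; "
            "use a CURIE"
        )
    return ontology.terms[next(iter(hits))]


def expand_term(ontology: Ontology, term: Term | str) -> set[Term]:
    """The term plus all of its descendants (transitive child closure)."""
    term_id = term.id if isinstance(term, Term) else term
    if term_id not in ontology.terms:
        raise TermNotFoundError(f"{term_id} not in ontology {ontology.id}")
    ids = {term_id} | nx.descendants(ontology._graph, term_id)
    return {ontology.terms[i] for i in ids}


class TermIndex:
    """Resolution across all ontologies loaded into one instance.

    CURIEs resolve by prefix lookup; labels/synonyms are searched in every
    ontology, and a collision across ontologies is an ambiguity error (the
    caller disambiguates with a CURIE).
    """

    def __init__(self, ontologies: Mapping[str, Ontology] | Iterable[Ontology] = ()):
        self.ontologies: dict[str, Ontology] = {}
        items = ontologies.values() if isinstance(ontologies, Mapping) else ontologies
        for o in items:
            self.add(o)

    def add(self, ontology: Ontology) -> None:
        if ontology.id in self.ontologies:
            raise OntologyIntegrityError(f"ontology {ontology.id} already loaded")
        self.ontologies[ontology.id] = ontology

    def ontology_of(self, term: Term | str) -> Ontology:
        term_id = term.id if isinstance(term, Term) else term
        for o in self.ontologies.values():
            if term_id in o:
                return o
        raise TermNotFoundError(f"{term_id} not in any loaded ontology")

    def get(self, term_id: str) -> Term:
        return self.ontology_of(term_id)[term_id]

    def resolve(self, query: str) -> Term:
        if is_curie(query):
            for o in self.ontologies.values():
                if query in o:
                    return o[query]
        hits: list[Term] = []
        for o in self.ontologies.values():
            try:
                hits.append(resolve_term(o, query))
            except TermNotFoundError:
                continue
            # AmbiguousTermError within one ontology propagates
        if not hits:
            raise TermNotFoundError(f"{query!r} not found in any loaded ontology")
        if len(hits) > 1:
            raise AmbiguousTermError(
                f"{query!r} matches terms in several ontologies: "
                f"{sorted(t.id for t in hits)}; use a CURIE"
            )
        return hits[0]

    def expand(self, term: Term | str) -> set[Term]:
        return expand_term(self.ontology_of(term), term)

    def is_ancestor(self, ancestor_id: str, descendant_id: str) -> bool:
        try:
            o = self.ontology_of(ancestor_id)
        except TermNotFoundError:
            return False
        return o.is_ancestor(ancestor_id, descendant_id)
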