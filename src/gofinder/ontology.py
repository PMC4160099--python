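"""OBO ontology parsing and ancestor closures.

An :class:`Ontology` is an acyclic is_a DAG over :class:`OntologyTerm`
records.  Only ``is_a`` edges define ancestry; ``part_of`` and other
relationship types are ignored, matching the hierarchical-evaluation
convention in which predicted and gold term sets are expanded with their
is_a ancestors.  Ancestor closures are reflexive (a term is its own
ancestor) so that expansion reduces to the identity on a flat ontology.

Obsolete terms are parsed and kept for reference but excluded from the
retrieval vocabulary and from expansion.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set, Union

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = ["OntologyTerm", "Ontology", "OboParseError", "parse_obo", "ancestors", "expand_set"]


class OboParseError(ValueError):
    """Raised for structurally invalid OBO input (cycles, duplicate ids)."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology concept."""

    id: str
    name: str
    synonyms: tuple = ()
    definition: str = ""
    parents: tuple = ()
    obsolete: bool = False


@dataclass
class Ontology:
    """An is_a DAG of terms, with roots = terms having no parents."""

    terms: Dict[str, OntologyTerm]
    root_ids: List[str]
    _parent_graph: nx.DiGraph = field(repr=False, default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        if self._parent_graph.number_of_nodes() == 0:
            g = nx.DiGraph()
            g.add_nodes_from(self.terms)
            for t in self.terms.values():
                for p in t.parents:
                    g.add_edge(t.id, p)  # edge child -> parent
            self._parent_graph = g

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def retrieval_ids(self) -> List[str]:
        """Non-obsolete accessions, sorted — the retrieval vocabulary."""
        return sorted(t for t, term in self.terms.items() if not term.obsolete)


_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _unquote(raw: str) -> str:
    m = _QUOTED.match(raw.strip())
    return m.group(1).replace('\\"', '"') if m else raw.strip()


def _scan_term_ids(text: str) -> Set[str]:
    """Ids of declared [Term] stanzas; rejects duplicates."""
    seen: Set[str] = set()
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term and line.startswith("id:"):
            tid = line[3:].split("!", 1)[0].strip()
            if tid in seen:
                raise OboParseError(f"duplicate term id {tid!r}")
            seen.add(tid)
    return seen


def parse_obo(stream: Union[str, io.TextIOBase]) -> Ontology:
    """Parse OBO 1.2 text into an :class:`Ontology`.

    Only ``id``, ``name``, ``def``, ``synonym``, ``is_a`` and
    ``is_obsolete`` tags are interpreted; everything else is skipped.
    Raises :class:`OboParseError` on duplicate ids or a cyclic is_a graph.
    """
    text = stream if isinstance(stream, str) else stream.read()
    declared = _scan_term_ids(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    terms: Dict[str, OntologyTerm] = {}
    for tid, data in graph.nodes(data=True):
        if tid not in declared:
            # node auto-created by an is_a reference with no stanza
            child = next((c for c, p in graph.edges() if p == tid), "?")
            raise OboParseError(f"term {child} has unknown parent {tid!r}")
        unknown = set(data) - {"name", "def", "synonym", "is_a", "is_obsolete",
                               "namespace", "alt_id", "subset", "xref", "comment"}
        if unknown:
            logger.debug("term %s: skipping OBO tags %s", tid, sorted(unknown))
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        parents = tuple(sorted(data.get("is_a", [])))
        terms[tid] = OntologyTerm(
            id=tid,
            name=data.get("name", ""),
            synonyms=tuple(_unquote(s) for s in data.get("synonym", [])),
            definition=_unquote(data.get("def", "")),
            parents=parents,
            obsolete=obsolete,
        )

    for t in terms.values():
        for p in t.parents:
            if p not in terms:
                raise OboParseError(f"term {t.id} has unknown parent {p!r}")

    parent_graph = nx.DiGraph()
    parent_graph.add_nodes_from(terms)
    for t in terms.values():
        for p in t.parents:
            parent_graph.add_edge(t.id, p)
    try:
        cycle = nx.find_cycle(parent_graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise OboParseError(f"cyclic is_a graph involving term {cycle[0][0]!r}")

    roots = sorted(t.id for t in terms.values() if not t.parents and not t.obsolete)
    return Ontology(terms=terms, root_ids=roots, _parent_graph=parent_graph)


def ancestors(ontology: Ontology, term_id: str) -> FrozenSet[str]:
    """Reflexive-transitive is_a closure of *term_id* (includes itself)."""
    if term_id not in ontology.terms:
        raise KeyError(f"unknown term id {term_id!r}")
    return frozenset({term_id} | nx.descendants(ontology._parent_graph, term_id))


def expand_set(ontology: Ontology, term_ids: Iterable[str]) -> FrozenSet[str]:
    """Union of reflexive ancestor closures over *term_ids*. Idempotent."""
    out: Set[str] = set()
    for tid in term_ids:
        out |= ancestors(ontology, tid)
    return frozenset(out)
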