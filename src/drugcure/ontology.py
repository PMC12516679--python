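"""A minimal disease-ontology store with information-content similarity.

Holds a DAG of disease terms (an EFO-like ontology read from an OBO file),
answers descendant queries, and scores pairwise semantic similarity with
the Lin measure over a descendant-count information-content corpus:

    IC(t)   = -ln((|descendants(t)| + 1) / N)
    sim(a,b) = 2 * IC(MICA) / (IC(a) + IC(b))

where N is the number of non-obsolete terms and MICA the common ancestor
with maximal IC.  The measure is pluggable; Lin is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import obonet


class OntologyStructureError(ValueError):
    """Cycle or dangling reference in the term graph."""


class MissingTermError(KeyError):
    pass


@dataclass
class Term:
    term_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    parent_ids: list[str] = field(default_factory=list)
    obsolete: bool = False
    replaced_by: Optional[str] = None


class Ontology:
    """Terms indexed by id over a child->parent is_a DAG."""

    def __init__(self, terms: dict[str, Term]):
        self.terms = terms
        self.graph = nx.DiGraph()  # edge child -> parent
        active = {t.term_id for t in terms.values() if not t.obsolete}
        for term in terms.values():
            if term.obsolete:
                if not term.replaced_by:
                    raise OntologyStructureError(
                        f"obsolete term {term.term_id} has no replaced_by"
                    )
                continue
            self.graph.add_node(term.term_id)
            for parent in term.parent_ids:
                if parent not in active:
                    raise OntologyStructureError(
                        f"dangling is_a: {term.term_id} -> {parent}"
                    )
                self.graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyStructureError(f"cycle in is_a graph: {cycle}")
        #: term universe size for the IC corpus
        self.n_terms = self.graph.number_of_nodes()
        self._desc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.n_terms

    def _check(self, term_id: str) -> None:
        if term_id not in self.graph:
            raise MissingTermError(term_id)

    def resolve(self, term_id: str) -> Optional[str]:
        """Follow replaced_by pointers to the current id (None if removed)."""
        seen = set()
        while term_id in self.terms and self.terms[term_id].obsolete:
            if term_id in seen:
                return None
            seen.add(term_id)
            term_id = self.terms[term_id].replaced_by  # type: ignore[assignment]
        return term_id if term_id in self.graph else None

    def descendants(self, term_id: str) -> frozenset[str]:
        """Transitive is_a descendants, excluding the term itself."""
        self._check(term_id)
        if term_id not in self._desc_cache:
            self._desc_cache[term_id] = frozenset(nx.ancestors(self.graph, term_id))
        return self._desc_cache[term_id]

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive is_a ancestors, excluding the term itself."""
        self._check(term_id)
        return frozenset(nx.descendants(self.graph, term_id))

    def is_descendant(self, a: str, b: str) -> bool:
        """True iff ``a`` is a (strict) transitive descendant of ``b``."""
        return a in self.descendants(b)

    def information_content(self, term_id: str) -> float:
        """IC from the descendant-count corpus; 0 for a root covering all."""
        self._check(term_id)
        return -math.log((len(self.descendants(term_id)) + 1) / self.n_terms)

    def mica(self, a: str, b: str) -> Optional[str]:
        """Most informative common ancestor (self-inclusive)."""
        common = (self.ancestors(a) | {a}) & (self.ancestors(b) | {b})
        if not common:
            return None
        return max(sorted(common), key=self.information_content)

    def similarity(self, a: str, b: str) -> float:
        """Lin similarity in [0, 1]; 1 for identical terms, 0 when the only
        shared information is a zero-IC root (or nothing at all)."""
        self._check(a)
        self._check(b)
        if a == b:
            return 1.0
        ic_a = self.information_content(a)
        ic_b = self.information_content(b)
        anc = self.mica(a, b)
        if anc is None or ic_a + ic_b == 0:
            return 0.0
        return 2.0 * self.information_content(anc) / (ic_a + ic_b)


def descendants(ontology: Ontology, term_id: str) -> frozenset[str]:
    return ontology.descendants(term_id)


def similarity(ontology: Ontology, a: str, b: str) -> float:
    return ontology.similarity(a, b)


def load_ontology(path_or_file) -> Ontology:
    """Load an OBO-format ontology (subset: [Term] stanzas with id, name,
    synonym, is_a, is_obsolete, replaced_by).

    Parsing is delegated to :mod:`obonet`; structural validation (cycles,
    dangling is_a references, obsolete terms lacking a replacement) happens
    on construction and raises :class:`OntologyStructureError`.
    """
    graph = obonet.read_obo(path_or_file, ignore_obsolete=False)
    terms: dict[str, Term] = {}
    for node, data in graph.nodes(data=True):
        syns = []
        for raw in data.get("synonym", []):
            # synonym lines look like: "name" EXACT []
            if raw.startswith('"') and '"' in raw[1:]:
                syns.append(raw[1 : raw.index('"', 1)])
            else:
                syns.append(raw)
        replaced = data.get("replaced_by", [])
        terms[node] = Term(
            term_id=node,
            name=data.get("name", node),
            synonyms=syns,
            parent_ids=list(data.get("is_a", [])),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
            replaced_by=replaced[0] if replaced else None,
        )
    return Ontology(terms)
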