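"""Ontology graph and annotation-set containers.

The ontology is a DAG over GO-style terms with typed ``is_a`` / ``part_of``
edges.  Ancestry and depth queries traverse both edge types; other
relationship kinds are not stored.  Depth is the shortest path, in edges, from
a term to the root of its namespace — the convention used by the GAQ
annotation-quality score.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import networkx as nx

TRAVERSED_RELATIONS = ("is_a", "part_of")


class OntologyGraph:
    """GO-style term DAG supporting ancestor, descendant and depth queries.

    Edges are stored child -> parent in a :class:`networkx.DiGraph` with a
    ``rel`` attribute.  Obsolete terms stay in the node set (so annotation
    files referencing them can be diagnosed) but never participate in
    ancestry.
    """

    def __init__(self) -> None:
        self._graph = nx.DiGraph()

    # -- construction -------------------------------------------------------

    def add_term(
        self,
        term_id: str,
        name: str = "",
        namespace: str = "biological_process",
        obsolete: bool = False,
    ) -> None:
        self._graph.add_node(
            term_id, name=name or term_id, namespace=namespace, obsolete=obsolete
        )

    def add_edge(self, child: str, parent: str, rel: str = "is_a") -> None:
        if rel not in TRAVERSED_RELATIONS:
            raise ValueError(f"unsupported relationship type: {rel}")
        for term in (child, parent):
            if term not in self._graph:
                raise KeyError(f"unknown term: {term}")
        self._graph.add_edge(child, parent, rel=rel)
        if not nx.is_directed_acyclic_graph(self._graph):
            self._graph.remove_edge(child, parent)
            raise ValueError(f"edge {child} -> {parent} would create a cycle")

    # -- queries ------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def terms(self) -> list[str]:
        return list(self._graph.nodes)

    def name(self, term_id: str) -> str:
        return self._graph.nodes[term_id]["name"]

    def namespace(self, term_id: str) -> str:
        return self._graph.nodes[term_id]["namespace"]

    def is_obsolete(self, term_id: str) -> bool:
        return self._graph.nodes[term_id]["obsolete"]

    def edges(self) -> list[tuple[str, str, str]]:
        return [(c, p, d["rel"]) for c, p, d in self._graph.edges(data=True)]

    def parents(self, term_id: str) -> set[str]:
        return set(self._graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self._graph.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable upward from ``term_id`` (excluding itself)."""
        if term_id not in self._graph:
            raise KeyError(f"unknown term: {term_id}")
        return set(nx.descendants(self._graph, term_id))

    def descendants(self, term_id: str) -> set[str]:
        """All terms that reach ``term_id`` upward (excluding itself)."""
        if term_id not in self._graph:
            raise KeyError(f"unknown term: {term_id}")
        return set(nx.ancestors(self._graph, term_id))

    def roots(self, namespace: str | None = None) -> set[str]:
        """Terms with no parents (optionally restricted to one namespace)."""
        roots = {
            n
            for n in self._graph.nodes
            if self._graph.out_degree(n) == 0 and not self.is_obsolete(n)
        }
        if namespace is not None:
            roots = {n for n in roots if self.namespace(n) == namespace}
        return roots

    def depth(self, term_id: str) -> int:
        """Shortest path, in edges, from ``term_id`` to its namespace root."""
        if term_id not in self._graph:
            raise KeyError(f"unknown term: {term_id}")
        roots = self.roots(self.namespace(term_id))
        if term_id in roots:
            return 0
        lengths = nx.single_source_shortest_path_length(self._graph, term_id)
        reachable = [lengths[r] for r in roots if r in lengths]
        if not reachable:
            raise ValueError(f"term {term_id} does not reach a namespace root")
        return min(reachable)

    def validate(self) -> None:
        """Check acyclicity and that every non-root, non-obsolete term reaches a root."""
        if not nx.is_directed_acyclic_graph(self._graph):
            raise ValueError("ontology graph contains a cycle")
        for term in self._graph.nodes:
            if not self.is_obsolete(term):
                self.depth(term)


@dataclasses.dataclass
class AnnotationSet:
    """Positive protein -> GO annotations, as (term, evidence code) pairs.

    NOT-qualified GAF rows are excluded upstream, so membership here always
    means a positive assertion.  ``aspects`` records the GAF aspect letter
    (P/F/C) per (protein, term) pair when known.
    """

    annotations: dict[str, set[tuple[str, str]]]
    aspects: dict[tuple[str, str], str] = dataclasses.field(default_factory=dict)

    def proteins(self) -> set[str]:
        return set(self.annotations)

    def terms_for(self, protein: str) -> set[str]:
        return {term for term, _ in self.annotations.get(protein, set())}

    def pairs_for(self, protein: str) -> set[tuple[str, str]]:
        return set(self.annotations.get(protein, set()))

    def subset(self, proteins: Iterable[str]) -> "AnnotationSet":
        keep = set(proteins)
        return AnnotationSet(
            annotations={p: set(v) for p, v in self.annotations.items() if p in keep},
            aspects={k: v for k, v in self.aspects.items() if k[0] in keep},
        )

    def by_namespace(self, ontology: OntologyGraph, namespace: str) -> "AnnotationSet":
        filtered: dict[str, set[tuple[str, str]]] = {}
        for protein, pairs in self.annotations.items():
            kept = {
                (t, e)
                for t, e in pairs
                if t in ontology and ontology.namespace(t) == namespace
            }
            if kept:
                filtered[protein] = kept
        return AnnotationSet(
            annotations=filtered,
            aspects={k: v for k, v in self.aspects.items() if k[0] in filtered},
        )

    def dangling_terms(self, ontology: OntologyGraph) -> set[str]:
        """Annotation terms absent from the ontology (reported, never dropped)."""
        return {
            term
            for pairs in self.annotations.values()
            for term, _ in pairs
            if term not in ontology
        }
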