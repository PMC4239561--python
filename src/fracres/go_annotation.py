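"""Gene Ontology DAG handling and annotation propagation.

GO terms form a directed acyclic graph in three namespaces (biological
process, cellular component, molecular function).  Annotation follows the
true-path rule: a gene annotated with a term implicitly hits every ancestor
of that term.  At the homology-set level, a set inherits the union of its
member genes' (propagated) annotations, and each member gene in turn
inherits the set-level annotation for gene-level analyses.

Only ``is_a`` and ``part_of`` edges participate in propagation; regulatory
relations are ignored, and a parent link crossing namespaces is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .homology import HomologySet

log = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")
PROPAGATION_RELATIONS = ("is_a", "part_of")

__all__ = [
    "NAMESPACES",
    "GoTerm",
    "GoDag",
    "AnnotationMap",
    "load_obo",
    "write_obo",
    "read_gene_annotations",
    "write_gene_annotations",
    "ancestors",
    "annotate_sets",
    "top_level_categories",
]


@dataclass(frozen=True)
class GoTerm:
    """A single ontology term with its propagation-relevant parent links."""

    term_id: str
    name: str
    namespace: str
    relations: tuple[tuple[str, str], ...] = ()  # (relation, parent_id)

    @property
    def parents(self) -> frozenset[str]:
        return frozenset(p for _, p in self.relations)


class GoDag:
    """An ontology restricted to is_a/part_of edges, validated on build.

    Guarantees: known namespaces only, no self-parents, parents stay within
    a term's namespace, the graph is acyclic, and each namespace present has
    exactly one root (parentless term).
    """

    def __init__(self, terms: Mapping[str, GoTerm]):
        self.terms: dict[str, GoTerm] = dict(terms)
        self._parents: dict[str, frozenset[str]] = {}
        self._anc_cache: dict[str, frozenset[str]] = {}
        for tid, term in self.terms.items():
            if term.namespace not in NAMESPACES:
                raise ValueError(f"{tid}: unknown namespace {term.namespace!r}")
            parents = term.parents
            if tid in parents:
                raise ValueError(f"{tid} lists itself as a parent")
            for p in parents:
                if p not in self.terms:
                    raise ValueError(f"{tid}: unknown parent {p}")
                if self.terms[p].namespace != term.namespace:
                    raise ValueError(f"{tid}: parent {p} crosses namespaces")
            self._parents[tid] = parents

        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        graph.add_edges_from(
            (t, p) for t, parents in self._parents.items() for p in parents
        )
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")

        self.roots: dict[str, str] = {}
        for tid, term in self.terms.items():
            if not self._parents[tid]:
                if term.namespace in self.roots:
                    raise ValueError(
                        f"namespace {term.namespace} has multiple roots: "
                        f"{self.roots[term.namespace]}, {tid}"
                    )
                self.roots[term.namespace] = tid

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents(self, term_id: str) -> frozenset[str]:
        return self._parents[term_id]

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive parent closure of a term (memoized BFS)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id}")
        cached = self._anc_cache.get(term_id)
        if cached is not None:
            return cached
        closure = {term_id}
        frontier = list(self._parents[term_id])
        while frontier:
            t = frontier.pop()
            if t not in closure:
                closure.add(t)
                frontier.extend(self._parents[t])
        result = frozenset(closure)
        self._anc_cache[term_id] = result
        return result

    def top_level_categories(self, namespace: str) -> list[str]:
        """Direct children of the namespace root, sorted by term id.

        These are the mutually exclusive top-level classes ("metabolic
        process", "response to stimulus", ...) used for enrichment.
        """
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        root = self.roots.get(namespace)
        if root is None:
            return []
        return sorted(
            tid for tid, parents in self._parents.items() if root in parents
        )


def ancestors(dag: GoDag, term_id: str) -> frozenset[str]:
    """Reflexive transitive closure over parent links (true-path rule)."""
    return dag.ancestors(term_id)


def top_level_categories(dag: GoDag, namespace: str) -> list[str]:
    return dag.top_level_categories(namespace)


def load_obo(path: str | Path) -> GoDag:
    """Load an OBO 1.2 flat file into a validated :class:`GoDag`.

    Obsolete terms are dropped (obonet's default), only is_a/part_of edges
    are kept, and parent links crossing namespaces or pointing at missing
    terms are discarded with a debug log line.
    """
    graph = obonet.read_obo(str(path))
    namespaces: dict[str, str] = {}
    names: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns not in NAMESPACES:
            raise ValueError(f"term {node}: unknown or missing namespace {ns!r}")
        namespaces[node] = ns
        names[node] = data.get("name", node)

    relations: dict[str, list[tuple[str, str]]] = {n: [] for n in namespaces}
    for child, parent, rel in graph.edges(keys=True):
        if rel not in PROPAGATION_RELATIONS:
            continue
        if parent not in namespaces:
            log.debug("dropping %s edge %s -> missing %s", rel, child, parent)
            continue
        if namespaces[parent] != namespaces[child]:
            log.debug("dropping cross-namespace %s edge %s -> %s", rel, child, parent)
            continue
        relations[child].append((rel, parent))

    terms = {
        tid: GoTerm(
            term_id=tid,
            name=names[tid],
            namespace=namespaces[tid],
            relations=tuple(sorted(relations[tid])),
        )
        for tid in namespaces
    }
    return GoDag(terms)


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialize a DAG back to OBO 1.2 (round-trips through load_obo)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for tid in sorted(dag.terms):
            term = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {term.name}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for rel, parent in term.relations:
                pname = dag.terms[parent].name
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {pname}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {pname}\n")
        fh.write("\n[Typedef]\nid: part_of\nname: part of\n")


def read_gene_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``gene_id<TAB>term_id`` table (no header)."""
    hits: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            gene_id, term_id = parts
            hits.setdefault(gene_id, set()).add(term_id)
    return hits


def write_gene_annotations(hits: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id in sorted(hits):
            for term_id in sorted(hits[gene_id]):
                fh.write(f"{gene_id}\t{term_id}\n")


@dataclass
class AnnotationMap:
    """Direct gene-level hits plus fully propagated set-level annotation.

    ``by_set`` is closed both upward (ancestor closure) and across the set
    (union over member genes); applying :func:`annotate_sets` to its own
    output is a no-op.  Genes inherit the set-level terms of their set via
    :meth:`gene_terms`.
    """

    direct: dict[str, frozenset[str]] = field(default_factory=dict)
    by_set: dict[str, frozenset[str]] = field(default_factory=dict)
    _gene_to_set: dict[str, str] = field(default_factory=dict)

    def set_terms(self, set_id: str) -> frozenset[str]:
        return self.by_set.get(set_id, frozenset())

    def gene_terms(self, gene_id: str) -> frozenset[str]:
        """Terms a gene inherits from its homology set (back-propagation)."""
        set_id = self._gene_to_set.get(gene_id)
        return self.by_set.get(set_id, frozenset()) if set_id else frozenset()

    def is_annotated(self, set_id: str, dag: GoDag, namespace: str) -> bool:
        """Whether a set carries any term of the namespace.

        Propagation reaches the namespace root whenever any term in the
        namespace is hit, so the root is a sufficient witness.
        """
        root = dag.roots.get(namespace)
        return root is not None and root in self.by_set.get(set_id, ())


def annotate_sets(
    sets: Iterable[HomologySet],
    gene_hits: Mapping[str, Iterable[str]],
    dag: GoDag,
) -> AnnotationMap:
    """Propagate gene-level GO hits to homology sets.

    A set retains every term hit by any member gene together with all its
    ancestors.  Gene ids in ``gene_hits`` absent from the sets are skipped
    with a logged warning.  Sets with no annotated member get an empty term
    set (and are excluded from category analyses downstream).
    """
    sets = list(sets)
    gene_to_set = {g: hs.set_id for hs in sets for _, g in hs.genes()}
    unknown = [g for g in gene_hits if g not in gene_to_set]
    if unknown:
        log.warning(
            "%d annotated gene id(s) not found in any homology set "
            "(e.g. %s); ignoring them",
            len(unknown),
            unknown[0],
        )

    direct: dict[str, frozenset[str]] = {}
    by_set: dict[str, frozenset[str]] = {}
    for hs in sets:
        terms: set[str] = set()
        for _, gene_id in hs.genes():
            hit_terms = gene_hits.get(gene_id)
            if not hit_terms:
                continue
            direct[gene_id] = frozenset(hit_terms)
            for t in hit_terms:
                terms |= dag.ancestors(t)
        by_set[hs.set_id] = frozenset(terms)
    return AnnotationMap(direct=direct, by_set=by_set, _gene_to_set=gene_to_set)
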