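"""Gene Ontology DAG: OBO parsing and reachability queries.

The ontology is held as a directed graph with child -> parent edges typed by
relation (``is_a`` or ``part_of`` by default, matching the relations used to
compute similarities).  Ancestor and descendant sets are *reflexive* — a term
is its own ancestor — so that self-similarity is well defined for every
measure.  Queries that mix namespaces raise :class:`NamespaceError`: term
similarity is only defined within one GO category.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(Exception):
    """Base class for ontology failures."""


class OboParseError(OntologyError):
    """Malformed OBO input; carries the offending line number."""


class CycleError(OntologyError):
    """The relation graph is not acyclic; message lists one cycle."""


class UnknownTermError(OntologyError, KeyError):
    """Query for a term absent from the DAG."""


class NamespaceError(OntologyError):
    """Query pairing terms from different GO namespaces."""


@dataclass
class OntologyDAG:
    """A parsed ontology restricted to the configured relations.

    ``graph`` stores child -> parent edges with a ``relation`` attribute.
    ``alt_ids`` maps secondary accessions onto their primary term.
    """

    graph: nx.DiGraph
    namespace: dict[str, str]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- basic access -----------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_ids

    def resolve(self, term: str) -> str:
        """Map an alt_id alias onto its primary accession."""
        if term in self.graph:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(f"unknown term: {term!r}")

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(self.resolve(term)))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(self.resolve(term)))

    def root_of(self, term: str) -> str:
        return self.roots[self.namespace[self.resolve(term)]]

    # -- reachability -----------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive closure over parent edges."""
        t = self.resolve(term)
        hit = self._anc_cache.get(t)
        if hit is None:
            hit = frozenset(nx.descendants(self.graph, t) | {t})
            self._anc_cache[t] = hit
        return hit

    def descendants(self, term: str) -> frozenset[str]:
        """Reflexive-transitive closure over child edges."""
        t = self.resolve(term)
        hit = self._desc_cache.get(t)
        if hit is None:
            hit = frozenset(nx.ancestors(self.graph, t) | {t})
            self._desc_cache[t] = hit
        return hit

    def common_ancestors(self, t_a: str, t_b: str) -> frozenset[str]:
        """Shared (reflexive) ancestors; always contains the namespace root."""
        a, b = self.resolve(t_a), self.resolve(t_b)
        if self.namespace[a] != self.namespace[b]:
            raise NamespaceError(
                f"{a} ({self.namespace[a]}) and {b} ({self.namespace[b]}) "
                "are in different namespaces"
            )
        return self.ancestors(a) & self.ancestors(b)

    def path_terms(self, t_a: str, t_b: str, p: str) -> frozenset[str]:
        """Terms on any directed path from ``t_a`` or ``t_b`` up to ``p``,
        plus all (reflexive) descendants of ``t_a`` and ``t_b``.

        A term x lies on a path t -> ... -> p exactly when x is an ancestor
        of t and a descendant of p, so the path sets are closure
        intersections rather than explicit path enumerations.
        """
        a, b, pp = self.resolve(t_a), self.resolve(t_b), self.resolve(p)
        if pp not in self.common_ancestors(a, b):
            raise ValueError(f"{pp} is not a common ancestor of {a} and {b}")
        desc_p = self.descendants(pp)
        return (
            (self.ancestors(a) & desc_p)
            | (self.ancestors(b) & desc_p)
            | self.descendants(a)
            | self.descendants(b)
        )


# -- construction ---------------------------------------------------------


def build_dag(
    term_namespaces: dict[str, str],
    edges: Iterable[tuple[str, str, str]],
    alt_ids: dict[str, str] | None = None,
    names: dict[str, str] | None = None,
) -> OntologyDAG:
    """Assemble an :class:`OntologyDAG` from in-memory pieces.

    ``edges`` are (child, parent, relation) triples.  Cross-namespace edges
    are dropped; cycles and multi-root namespaces are rejected.
    """
    g = nx.DiGraph()
    g.add_nodes_from(term_namespaces)
    for child, parent, rel in edges:
        if child not in term_namespaces or parent not in term_namespaces:
            raise UnknownTermError(f"edge {child}->{parent} references unknown term")
        if term_namespaces[child] != term_namespaces[parent]:
            continue  # cross-namespace relations are not loaded
        g.add_edge(child, parent, relation=rel)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError(f"ontology contains a cycle: {cycle}")
    parentless: dict[str, list[str]] = {}
    for term, ns in term_namespaces.items():
        if g.out_degree(term) == 0:
            parentless.setdefault(ns, []).append(term)
    roots: dict[str, str] = {}
    for ns, cands in parentless.items():
        if len(cands) > 1:
            # can happen when relation filtering disconnects components;
            # keep the term covering the most of the namespace as the root
            warnings.warn(
                f"namespace {ns!r} has {len(cands)} parentless terms; "
                "using the most-covering one as root"
            )
            roots[ns] = max(
                sorted(cands), key=lambda t: len(nx.ancestors(g, t))
            )
        else:
            roots[ns] = cands[0]
    return OntologyDAG(
        graph=g,
        namespace=dict(term_namespaces),
        roots=roots,
        alt_ids=dict(alt_ids or {}),
        names=dict(names or {}),
    )


def _prevalidate_obo(path: str) -> None:
    # obonet's errors carry no position, so do a cheap line-level check first.
    with open(path, encoding="utf-8") as fh:
        in_stanza = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            if stripped.startswith("[") and stripped.endswith("]"):
                in_stanza = True
                continue
            if stripped.startswith("["):
                raise OboParseError(f"line {lineno}: unterminated stanza header")
            if in_stanza and ":" not in stripped:
                raise OboParseError(f"line {lineno}: expected 'tag: value', got {stripped!r}")


def parse_obo(
    path: str,
    relations: frozenset[str] = DEFAULT_RELATIONS,
    default_namespace: str = "biological_process",
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Only the requested ``relations`` are loaded (default: ``is_a`` and
    ``part_of``); ``regulates`` and other relationships are ignored.
    Obsolete terms are absent, alt_id aliases resolve to their primary
    accession, and cross-namespace edges are dropped.
    """
    unknown = set(relations) - {"is_a", "part_of"}
    if unknown:
        raise ValueError(f"unsupported relations: {sorted(unknown)}")
    _prevalidate_obo(path)
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise OboParseError(f"failed to parse {path}: {exc}") from exc

    term_ns: dict[str, str] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        term_ns[term] = data.get("namespace", default_namespace)
        if "name" in data:
            names[term] = data["name"]
        for alias in data.get("alt_id", []):
            alt_ids[alias] = term
    edges = [
        (child, parent, rel)
        for child, parent, rel in multigraph.edges(keys=True)
        if rel in relations
    ]
    return build_dag(term_ns, edges, alt_ids=alt_ids, names=names)


def write_obo(dag: OntologyDAG, path: str, ontology_name: str = "fixture") -> None:
    """Serialize the DAG back to OBO (round-trip support for fixtures)."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\n")
    buf.write(f"ontology: {ontology_name}\n")
    for term in sorted(dag.graph.nodes):
        buf.write("\n[Term]\n")
        buf.write(f"id: {term}\n")
        buf.write(f"name: {dag.names.get(term, term)}\n")
        buf.write(f"namespace: {dag.namespace[term]}\n")
        for alias, primary in sorted(dag.alt_ids.items()):
            if primary == term:
                buf.write(f"alt_id: {alias}\n")
        for parent in sorted(dag.graph.successors(term)):
            rel = dag.graph.edges[term, parent]["relation"]
            if rel == "is_a":
                buf.write(f"is_a: {parent}\n")
            else:
                buf.write(f"relationship: {rel} {parent}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
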