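"""Gene -> GO annotations: GAF parsing, filtering, and true-path propagation.

The central container is :class:`AnnotationSet`.  ``direct[t]`` holds the
genes annotated straight to term t; ``propagated[t]`` (the gene set G_t)
additionally contains every gene annotated to a descendant of t, following
the true-path rule.  ``universe`` is G — the genes annotated anywhere in the
namespace, i.e. the propagated set of the root.  Information-content
quantities divide by |G|, so leave-one-out removal shrinks the universe too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .ontology import OntologyDAG, UnknownTermError

# GAF column indices (0-based): db, db_object_id, symbol, qualifier, go_id,
# reference, evidence, with/from, aspect, ...
_GAF_MIN_COLUMNS = 15
_ASPECT_TO_NS = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class GafFormatError(Exception):
    """Malformed GAF row; message carries the row number."""


@dataclass
class AnnotationSet:
    """Direct and propagated gene sets per term.

    ``gene_terms`` maps each gene to its *directly* annotated terms (the
    per-gene term sets T_i used by gene-level aggregation).  ``propagated``
    is None until :func:`propagate` has been run against a DAG.
    """

    direct: dict[str, set[str]]
    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] | None = None
    universe: set[str] = field(default_factory=set)
    namespace: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_terms:
            gt: dict[str, set[str]] = {}
            for term, genes in self.direct.items():
                for g in genes:
                    gt.setdefault(g, set()).add(term)
            self.gene_terms = gt

    @property
    def genes(self) -> set[str]:
        return set(self.gene_terms)

    def term_genes(self, term: str) -> set[str]:
        """Propagated gene set G_t (empty set for unannotated terms)."""
        if self.propagated is None:
            raise ValueError("annotations have not been propagated; call propagate()")
        return self.propagated.get(term, set())

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(
            direct={t: set(gs) for t, gs in self.direct.items()},
            gene_terms={g: set(ts) for g, ts in self.gene_terms.items()},
            propagated=None
            if self.propagated is None
            else {t: set(gs) for t, gs in self.propagated.items()},
            universe=set(self.universe),
            namespace=self.namespace,
        )


def parse_gaf(
    path: str,
    exclude_evidence: frozenset[str] | set[str] = frozenset({"IEA"}),
    aspect: str | None = None,
    exclude_not: bool = True,
) -> AnnotationSet:
    """Read a GAF 2.x file into a direct-only :class:`AnnotationSet`.

    Rows whose evidence code is in ``exclude_evidence`` are dropped (pass an
    empty set to keep electronically inferred annotations).  Rows with a NOT
    qualifier are dropped by default.  ``aspect`` restricts to one namespace
    ('P', 'F', 'C' or the long namespace name); duplicates collapse to one
    annotation.
    """
    if aspect in _ASPECT_TO_NS.values():
        aspect = {v: k for k, v in _ASPECT_TO_NS.items()}[aspect]
    if aspect is not None and aspect not in _ASPECT_TO_NS:
        raise ValueError(f"unknown aspect {aspect!r}")
    exclude_evidence = frozenset(exclude_evidence)

    direct: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for rowno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < _GAF_MIN_COLUMNS:
                raise GafFormatError(
                    f"row {rowno}: expected >= {_GAF_MIN_COLUMNS} columns, "
                    f"found {len(fields)}"
                )
            gene = fields[1]
            qualifier = fields[3]
            term = fields[4]
            evidence = fields[6]
            row_aspect = fields[8]
            if evidence in exclude_evidence:
                continue
            if exclude_not and "NOT" in qualifier.split("|"):
                continue
            if aspect is not None and row_aspect != aspect:
                continue
            direct.setdefault(term, set()).add(gene)
    return AnnotationSet(
        direct=direct,
        namespace=_ASPECT_TO_NS.get(aspect) if aspect else None,
    )


def propagate(
    annots: AnnotationSet,
    dag: OntologyDAG,
    unknown_term_policy: str = "error",
) -> AnnotationSet:
    """Fill propagated gene sets: G_t = union of direct sets over the
    reflexive descendants of t.

    Terms absent from the DAG (e.g. obsoleted between releases) follow
    ``unknown_term_policy``: ``"error"`` raises, ``"skip"`` drops the
    annotation with a warning.  If ``annots.namespace`` is set, only terms of
    that namespace are kept.
    """
    if unknown_term_policy not in ("error", "skip"):
        raise ValueError(f"unknown policy {unknown_term_policy!r}")
    direct: dict[str, set[str]] = {}
    for term, genes in annots.direct.items():
        try:
            primary = dag.resolve(term)
        except UnknownTermError:
            if unknown_term_policy == "error":
                raise
            warnings.warn(f"skipping annotations to unknown term {term!r}")
            continue
        if annots.namespace is not None and dag.namespace[primary] != annots.namespace:
            continue
        direct.setdefault(primary, set()).update(genes)

    namespaces = (
        {annots.namespace}
        if annots.namespace is not None
        else {dag.namespace[t] for t in direct}
    )
    propagated: dict[str, set[str]] = {}
    # children-before-parents order: accumulate child sets into parents
    for term in nx.topological_sort(dag.graph):
        if dag.namespace[term] not in namespaces:
            continue
        acc = set(direct.get(term, ()))
        for child in dag.graph.predecessors(term):
            acc |= propagated.get(child, set())
        propagated[term] = acc
    universe = set()
    for ns in namespaces:
        universe |= propagated.get(dag.roots[ns], set())
    return AnnotationSet(
        direct=direct,
        propagated=propagated,
        universe=universe,
        namespace=annots.namespace,
    )


def remove_genes(annots: AnnotationSet, genes: Iterable[str]) -> AnnotationSet:
    """A copy with ``genes`` removed from every set, including the universe.

    Removing absent genes is a no-op; the input is left unchanged.  This is
    the leave-one-out primitive: the evaluated gene pair is excluded from the
    whole annotation model, universe included, before similarities are
    computed.
    """
    drop = set(genes)
    out = annots.copy()
    if not drop:
        return out
    for term in list(out.direct):
        out.direct[term] -= drop
        if not out.direct[term]:
            del out.direct[term]
    for g in drop:
        out.gene_terms.pop(g, None)
    if out.propagated is not None:
        for term in out.propagated:
            out.propagated[term] -= drop
    out.universe -= drop
    return out


def write_gaf(annots: AnnotationSet, path: str, db: str = "FIXTURE") -> None:
    """Serialize direct annotations as a minimal valid GAF 2.2 file."""
    aspect = {v: k for k, v in _ASPECT_TO_NS.items()}.get(
        annots.namespace or "biological_process", "P"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term in sorted(annots.direct):
            for gene in sorted(annots.direct[term]):
                fields = [
                    db, gene, gene, "involved_in", term, "FIX:0000001",
                    "IDA", "", aspect, gene, "", "gene", "taxon:0000",
                    "20150214", db, "", "",
                ]
                fh.write("\t".join(fields) + "\n")
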