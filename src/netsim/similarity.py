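"""Term-to-term similarity: the network-aware measure, its ablation
variants, and the Resnik / Schlicker / Wang baselines.

The network-aware score for two terms t_a, t_b and a common ancestor p is

    S(t_a, t_b, p) = (2 ln|G| - 2 ln f) / (2 ln|G| - (ln|G_a| + ln|G_b|))
                     * (1 - h/|G| * |G_p|/|G|)

with the gene-set distance D (a modified Czekanovski-Dice distance over the
co-function network), the path-constrained annotation U, and

    f = D^2 |U| + (1 - D^2) sqrt(|G_a| |G_b|)
    h = D^2 |G| + (1 - D^2) max(|G_a|, |G_b|).

When the two gene sets are tightly co-functional (D -> 0), f collapses to
sqrt(|G_a||G_b|) and the first factor approaches 1; when they are unrelated
(D -> 1), f counts the path-constrained annotation and h pushes the
specificity weight toward its floor.  Two limits anchor the measure to the
classical information-content family: with no usable network and disjoint
gene sets it reduces to the Schlicker score evaluated at p, and for a term
against itself it equals 1 - (|G_t|/|G|)^2, proportional to the Resnik
information content of the term.

Logs are natural throughout; the first factor is a log ratio, so the base
cancels — fixing it keeps results bit-reproducible.

Ablation variants: ``netsim_v1`` replaces the product-form D with the mean
pairwise edge distance; ``netsim_v2`` drops path constraining (U = G_p);
``netsim_v3`` replaces the specificity weight with Schlicker's
(1 - |G_p|/|G|).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .cofunction import CoFunctionNetwork, gene_to_set_distance, pair_distance
from .ontology import OntologyDAG

NETSIM_MEASURES = ("netsim", "netsim_v1", "netsim_v2", "netsim_v3")
ALL_MEASURES = NETSIM_MEASURES + ("resnik", "schlicker", "wang")


@dataclass(frozen=True)
class MeasureConfig:
    """Which measure to run and its knobs.

    Wang edge weights are the semantic contribution factors per relation;
    the 0.8 / 0.6 defaults are the conventional is_a / part_of choices.
    """

    measure: str = "netsim"
    wang_is_a: float = 0.8
    wang_part_of: float = 0.6

    def __post_init__(self) -> None:
        if self.measure not in ALL_MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not (0.0 < self.wang_is_a < 1.0 and 0.0 < self.wang_part_of < 1.0):
            raise ValueError("Wang edge weights must lie in (0,1)")

    @property
    def wang_weights(self) -> dict[str, float]:
        return {"is_a": self.wang_is_a, "part_of": self.wang_part_of}


@dataclass
class SimilarityResult:
    """A scored term pair with its intermediates."""

    term_a: str
    term_b: str
    ancestor: str
    D: float
    U: frozenset[str]
    f: float
    h: float
    S: float


# -- gene-set distances (step 1) ------------------------------------------


def gene_set_distance(net: CoFunctionNetwork, G_a: set[str], G_b: set[str]) -> float:
    """Modified Czekanovski-Dice distance between two gene sets.

    D = (sum_a + sum_b) / (2|G_a u G_b| - sum_a - sum_b), where sum_a is the
    sum over g in G_a of the product-form distance from g to G_b (and
    symmetrically for sum_b).  A shared gene zeroes its product, so
    identical sets give D = 0; disjoint, fully unconnected sets give D = 1.
    """
    if not G_a or not G_b:
        raise ValueError("gene sets must be nonempty")
    sum_a = sum(gene_to_set_distance(net, g, G_b) for g in G_a)
    sum_b = sum(gene_to_set_distance(net, g, G_a) for g in G_b)
    denom = 2.0 * len(G_a | G_b) - sum_a - sum_b
    return (sum_a + sum_b) / denom


def gene_set_distance_v1(net: CoFunctionNetwork, G_a: set[str], G_b: set[str]) -> float:
    """Ablation distance: mean pairwise edge distance between the sets."""
    if not G_a or not G_b:
        raise ValueError("gene sets must be nonempty")
    total = sum(pair_distance(net, gi, gj) for gi in G_a for gj in G_b)
    return total / (len(G_a) * len(G_b))


# -- path-constrained annotation (step 2) ---------------------------------


def path_constrained_annotation(
    dag: OntologyDAG, annots: AnnotationSet, t_a: str, t_b: str, p: str
) -> frozenset[str]:
    """U(t_a, t_b, p): the propagated gene sets of the two compared terms
    plus the *direct* annotations of every term on the constrained paths.

    Interior path terms contribute only their direct annotations —
    propagating them would re-include exactly the off-path descendants the
    constraint is meant to exclude.
    """
    terms = dag.path_terms(t_a, t_b, p)
    genes: set[str] = set(annots.term_genes(t_a)) | set(annots.term_genes(t_b))
    for t in terms:
        genes |= annots.direct.get(t, set())
    return frozenset(genes)


# -- information content --------------------------------------------------


def information_content(annots: AnnotationSet, term: str) -> float:
    """IC(t) = -ln(|G_t| / |G|)."""
    g_t = annots.term_genes(term)
    if not g_t or not annots.universe:
        raise ValueError(f"term {term!r} has an empty propagated gene set")
    return -math.log(len(g_t) / len(annots.universe))


def _lca(annots: AnnotationSet, dag: OntologyDAG, t_a: str, t_b: str) -> str:
    """Common ancestor with maximal IC (smallest propagated set); ties
    break to the lexicographically smallest accession."""
    candidates = [
        p for p in dag.common_ancestors(t_a, t_b) if annots.term_genes(p)
    ]
    if not candidates:
        raise ValueError(f"no annotated common ancestor for {t_a}, {t_b}")
    return min(candidates, key=lambda p: (len(annots.term_genes(p)), p))


# -- the core score (step 3) ----------------------------------------------


def term_similarity(
    dag: OntologyDAG,
    annots: AnnotationSet,
    net: CoFunctionNetwork,
    t_a: str,
    t_b: str,
    p: str,
    cfg: MeasureConfig = MeasureConfig(),
    _D: float | None = None,
) -> SimilarityResult:
    """Score one (t_a, t_b, p) triple with the configured network-aware
    variant.  ``_D`` lets batch drivers reuse the (p-independent) gene-set
    distance across ancestors."""
    if cfg.measure not in NETSIM_MEASURES:
        raise ValueError(f"term_similarity computes the netsim family, not {cfg.measure!r}")
    t_a, t_b, p = dag.resolve(t_a), dag.resolve(t_b), dag.resolve(p)
    G_a = annots.term_genes(t_a)
    G_b = annots.term_genes(t_b)
    G_p = annots.term_genes(p)
    G = annots.universe
    if not (G_a and G_b and G_p):
        raise ValueError("propagated gene sets of t_a, t_b and p must be nonempty")
    if p not in dag.common_ancestors(t_a, t_b):
        raise ValueError(f"{p} is not a common ancestor of {t_a} and {t_b}")

    if _D is not None:
        D = _D
    elif cfg.measure == "netsim_v1":
        D = gene_set_distance_v1(net, G_a, G_b)
    else:
        D = gene_set_distance(net, G_a, G_b)

    if cfg.measure == "netsim_v2":
        U = frozenset(G_p)
    else:
        U = path_constrained_annotation(dag, annots, t_a, t_b, p)

    d2 = D * D
    f = d2 * len(U) + (1.0 - d2) * math.sqrt(len(G_a) * len(G_b))
    h = d2 * len(G) + (1.0 - d2) * max(len(G_a), len(G_b))

    ln_G = math.log(len(G))
    denom = 2.0 * ln_G - (math.log(len(G_a)) + math.log(len(G_b)))
    if denom == 0.0:
        # both terms annotated to the whole universe: zero information
        first = 0.0
    else:
        first = (2.0 * ln_G - 2.0 * math.log(f)) / denom
    if cfg.measure == "netsim_v3":
        second = 1.0 - len(G_p) / len(G)
    else:
        second = 1.0 - (h / len(G)) * (len(G_p) / len(G))
    S = first * second
    # guard floating error at the boundaries; the analytic range is [0,1]
    S = min(max(S, 0.0), 1.0)
    return SimilarityResult(t_a, t_b, p, D, U, f, h, S)


def term_similarity_max(
    dag: OntologyDAG,
    annots: AnnotationSet,
    net: CoFunctionNetwork,
    t_a: str,
    t_b: str,
    cfg: MeasureConfig = MeasureConfig(),
) -> SimilarityResult:
    """Maximize S(t_a, t_b, p) over all annotated common ancestors p.

    D does not depend on p, so it is computed once.  Value ties report the
    lexicographically smallest maximizing ancestor for reproducible logs.
    """
    t_a, t_b = dag.resolve(t_a), dag.resolve(t_b)
    G_a, G_b = annots.term_genes(t_a), annots.term_genes(t_b)
    if not (G_a and G_b):
        raise ValueError("propagated gene sets of t_a and t_b must be nonempty")
    if cfg.measure == "netsim_v1":
        D = gene_set_distance_v1(net, G_a, G_b)
    else:
        D = gene_set_distance(net, G_a, G_b)
    best: SimilarityResult | None = None
    for p in sorted(dag.common_ancestors(t_a, t_b)):
        if not annots.term_genes(p):
            continue
        res = term_similarity(dag, annots, net, t_a, t_b, p, cfg, _D=D)
        if best is None or res.S > best.S:
            best = res
    if best is None:  # unreachable when the root is annotated
        raise ValueError(f"no annotated common ancestor for {t_a}, {t_b}")
    return best


# -- baselines ------------------------------------------------------------


def resnik(annots: AnnotationSet, dag: OntologyDAG, t_a: str, t_b: str) -> float:
    """IC of the lowest common ancestor: -ln(|G_LCA| / |G|)."""
    return information_content(annots, _lca(annots, dag, t_a, t_b))


def schlicker(annots: AnnotationSet, dag: OntologyDAG, t_a: str, t_b: str) -> float:
    """Relevance-normalized Resnik:
    2 IC(LCA) / (IC(t_a) + IC(t_b)) * (1 - |G_LCA| / |G|)."""
    lca = _lca(annots, dag, t_a, t_b)
    ic_sum = information_content(annots, t_a) + information_content(annots, t_b)
    if ic_sum == 0.0:
        return 0.0  # both terms cover the universe: no information to share
    weight = 1.0 - len(annots.term_genes(lca)) / len(annots.universe)
    return 2.0 * information_content(annots, lca) / ic_sum * weight


def _wang_svalues(dag: OntologyDAG, term: str, weights: dict[str, float]) -> dict[str, float]:
    """Semantic contribution of each ancestor p to ``term``:
    S[term]=1; S[p] = max over on-path children c of p of w(c->p) * S[c]."""
    anc = dag.ancestors(term)
    s: dict[str, float] = {term: 1.0}
    # process ancestors in topological order away from the term
    remaining = set(anc) - {term}
    while remaining:
        progressed = False
        for p in sorted(remaining):
            kids = [c for c in dag.children(p) if c in anc]
            if any(c in remaining for c in kids):
                continue
            s[p] = max(
                weights[dag.graph.edges[c, p]["relation"]] * s[c] for c in kids
            )
            remaining.discard(p)
            progressed = True
        if not progressed:  # pragma: no cover - DAG guarantees progress
            raise RuntimeError("cycle encountered in ancestor closure")
    return s


def wang(
    dag: OntologyDAG, t_a: str, t_b: str, cfg: MeasureConfig = MeasureConfig(measure="wang")
) -> float:
    """Topology-only similarity from aggregated semantic contributions."""
    t_a, t_b = dag.resolve(t_a), dag.resolve(t_b)
    w = cfg.wang_weights
    s_a = _wang_svalues(dag, t_a, w)
    s_b = _wang_svalues(dag, t_b, w)
    common = dag.common_ancestors(t_a, t_b)
    num = sum(s_a[p] + s_b[p] for p in common)
    den = sum(s_a.values()) + sum(s_b.values())
    return num / den


# -- dispatch and batch drivers -------------------------------------------


def term_measure(
    dag: OntologyDAG,
    annots: AnnotationSet,
    net: CoFunctionNetwork,
    t_a: str,
    t_b: str,
    cfg: MeasureConfig = MeasureConfig(),
) -> float:
    """Scalar similarity under any configured measure (netsim family via
    ancestor maximization, or a baseline)."""
    if cfg.measure in NETSIM_MEASURES:
        return term_similarity_max(dag, annots, net, t_a, t_b, cfg).S
    if cfg.measure == "resnik":
        return resnik(annots, dag, t_a, t_b)
    if cfg.measure == "schlicker":
        return schlicker(annots, dag, t_a, t_b)
    return wang(dag, t_a, t_b, cfg)


def term_similarity_matrix(
    dag: OntologyDAG,
    annots: AnnotationSet,
    net: CoFunctionNetwork,
    terms: list[str],
    cfg: MeasureConfig = MeasureConfig(),
) -> pd.DataFrame:
    """Symmetric matrix of pairwise scalar similarities over ``terms``.

    Terms with empty propagated sets are skipped with a warning (they carry
    no annotation signal under IC-based measures).
    """
    kept: list[str] = []
    for t in terms:
        rt = dag.resolve(t)
        if cfg.measure != "wang" and not annots.term_genes(rt):
            warnings.warn(f"skipping term {t!r}: empty propagated gene set")
            continue
        kept.append(rt)
    n = len(kept)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            mat[i, j] = mat[j, i] = term_measure(dag, annots, net, kept[i], kept[j], cfg)
    return pd.DataFrame(mat, index=kept, columns=kept)
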