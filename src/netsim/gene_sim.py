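"""Gene-to-gene functional similarity by best-match aggregation with
leave-one-out.

For genes g_i, g_j with directly annotated term sets T_i, T_j:

    GS(g_i, g_j) = [ sum_{t in T_i} Sim(t, T_j) + sum_{t in T_j} Sim(t, T_i) ]
                   / (|T_i| + |T_j|)

where Sim(t, T_y) = max_{t_y in T_y} S(t, t_y) and S is the scalar term
measure.  To avoid circularity, the two genes are removed from *every*
term's gene set (and from the universe) before term similarities are
computed — but T_i and T_j themselves come from the original annotation:
the query keeps its own term list, it just stops supporting the model.

Only non-zero Sim values enter the numerator; by default the denominator
stays |T_i| + |T_j| as printed, with ``nonzero_denominator=True`` counting
only the non-zero contributions instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, remove_genes
from .cofunction import CoFunctionNetwork
from .ontology import OntologyDAG
from .similarity import MeasureConfig, term_measure


@dataclass
class GenePairScore:
    gene_i: str
    gene_j: str
    GS: float
    term_set_i: frozenset[str]
    term_set_j: frozenset[str]
    best_matches: dict[str, tuple[str | None, float]] = field(default_factory=dict)


def _sim_to_set(
    dag: OntologyDAG,
    annots: AnnotationSet,
    net: CoFunctionNetwork,
    t: str,
    T_y: frozenset[str],
    cfg: MeasureConfig,
) -> tuple[str | None, float]:
    """Best partner of t within T_y under the reduced annotation; terms
    whose propagated set emptied out contribute 0."""
    if cfg.measure != "wang" and not annots.term_genes(dag.resolve(t)):
        return None, 0.0
    best_term, best = None, 0.0
    for t_y in sorted(T_y):
        if cfg.measure != "wang" and not annots.term_genes(dag.resolve(t_y)):
            continue
        val = term_measure(dag, annots, net, t, t_y, cfg)
        if val > best:
            best_term, best = t_y, val
    return best_term, best


def gene_similarity(
    dag: OntologyDAG,
    annots: AnnotationSet,
    net: CoFunctionNetwork,
    g_i: str,
    g_j: str,
    cfg: MeasureConfig = MeasureConfig(),
    nonzero_denominator: bool = False,
) -> GenePairScore:
    """Aggregate term similarities into GS(g_i, g_j) with leave-one-out."""
    if g_i == g_j:
        # self-similarity is a boundary convention, not a measurement:
        # leave-one-out would delete the gene's own annotation support
        T = frozenset(annots.gene_terms.get(g_i, ()))
        if not T:
            raise ValueError(f"gene {g_i!r} has no annotations")
        return GenePairScore(g_i, g_i, 1.0, T, T)
    T_i = frozenset(annots.gene_terms.get(g_i, ()))
    T_j = frozenset(annots.gene_terms.get(g_j, ()))
    if not T_i or not T_j:
        raise ValueError(f"both genes need >=1 annotation: {g_i!r}, {g_j!r}")
    reduced = remove_genes(annots, {g_i, g_j})
    best_matches: dict[str, tuple[str | None, float]] = {}
    numerator = 0.0
    nonzero = 0
    for t in sorted(T_i):
        partner, val = _sim_to_set(dag, reduced, net, t, T_j, cfg)
        best_matches[f"i:{t}"] = (partner, val)
        if val > 0.0:
            numerator += val
            nonzero += 1
    for t in sorted(T_j):
        partner, val = _sim_to_set(dag, reduced, net, t, T_i, cfg)
        best_matches[f"j:{t}"] = (partner, val)
        if val > 0.0:
            numerator += val
            nonzero += 1
    denom = nonzero if nonzero_denominator else len(T_i) + len(T_j)
    gs = numerator / denom if denom else 0.0
    return GenePairScore(g_i, g_j, gs, T_i, T_j, best_matches)


def gene_similarity_matrix(
    dag: OntologyDAG,
    annots: AnnotationSet,
    net: CoFunctionNetwork,
    genes: list[str],
    cfg: MeasureConfig = MeasureConfig(),
    nonzero_denominator: bool = False,
) -> pd.DataFrame:
    """Symmetric GS matrix over ``genes``; diagonal 1 by convention.

    Unannotated genes are excluded with a warning.
    """
    kept = []
    for g in genes:
        if not annots.gene_terms.get(g):
            warnings.warn(f"excluding unannotated gene {g!r}")
            continue
        kept.append(g)
    n = len(kept)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = gene_similarity(
                dag, annots, net, kept[i], kept[j], cfg, nonzero_denominator
            ).GS
    return pd.DataFrame(mat, index=kept, columns=kept)
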