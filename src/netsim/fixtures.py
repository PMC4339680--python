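"""Seeded synthetic worlds: the worked-example toy ontology, random
DAG/annotation/network bundles, and a constructed-signal benchmark.

The toy world mirrors the illustrative figure the measure is usually
explained with: eleven terms (root, t_a ... t_j) in one namespace, thirteen
genes, a small co-function network, and the two common ancestors t_i (the
LCA) and t_j of the compared pair (t_a, t_b).  Its layout is pinned down by
the facts the worked examples assert — the path-constrained term sets, the
membership of U(t_a, t_b, t_j), the leave-one-out gene sets and the
product-form distances of the 1C example — rather than by any drawing.

The random generator emulates the shape of real inputs (a layered DAG with
1-3 parents per term, every gene annotated at least once, uniform edge
confidences) but none of GO's size, depth distribution, or the calibrated
confidence distributions of published networks; a passing property suite
therefore demonstrates correctness of the arithmetic, not biological
performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import AnnotationSet, propagate, write_gaf
from .cofunction import CoFunctionNetwork, network_from_edges, write_network
from .evaluation import ReactionMap, build_reaction_map, write_reaction_map
from .ontology import OntologyDAG, build_dag, write_obo

import pandas as pd

NS = "biological_process"


@dataclass
class FixtureBundle:
    dag: OntologyDAG
    annots: AnnotationSet  # propagated
    net: CoFunctionNetwork
    reaction_map: ReactionMap | None = None
    seed: int | None = None
    manifest: dict = field(default_factory=dict)
    example_gene_set: frozenset[str] | None = None

    def write(self, directory: str) -> dict[str, str]:
        """Emit OBO + GAF + network TSV (+ reactions TSV) + manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": str(d / "fixture.obo"),
            "gaf": str(d / "fixture.gaf"),
            "network": str(d / "network.tsv"),
            "manifest": str(d / "manifest.json"),
        }
        write_obo(self.dag, paths["obo"])
        write_gaf(self.annots, paths["gaf"])
        write_network(self.net, paths["network"])
        if self.reaction_map is not None:
            paths["reactions"] = str(d / "reactions.tsv")
            write_reaction_map(self.reaction_map, paths["reactions"])
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump({"seed": self.seed, **self.manifest}, fh, indent=2)
        return paths


def figure1_fixture() -> FixtureBundle:
    """The fixed worked-example world.

    Facts it satisfies (all checkable through the public API):
      (i)   t_i and t_j are common ancestors of (t_a, t_b), t_i the LCA;
      (ii)  path_terms(t_a,t_b,t_i) = {t_a,t_b,t_c,t_e,t_h,t_i} and
            path_terms(t_a,t_b,t_j) = {t_a,t_b,t_c,t_f,t_j};
      (iii) U(t_a,t_b,t_j) = {g1,g2,g3,g5,g6,g7,g10,g11}, containing no
            gene annotated to t_d or t_g;
      (iv)  with {g6,g7} removed, the propagated sets of t_b, t_e, t_f are
            {g1,g5}, {g1,g5,g8}, {g1,g2,g3,g4};
      (v)   the network holds a 3-gene worked set containing g1 whose two
            other members sit at distance 0.99 from g1, and g2 has no edge
            into that set.
    """
    terms = ["root"] + [f"t_{x}" for x in "abcdefghij"]
    edges = [
        ("t_a", "t_e", "is_a"),
        ("t_a", "t_f", "is_a"),
        ("t_b", "t_h", "is_a"),
        ("t_b", "t_j", "is_a"),
        ("t_c", "t_b", "is_a"),
        ("t_d", "t_f", "is_a"),
        ("t_e", "t_i", "is_a"),
        ("t_f", "t_j", "part_of"),
        ("t_g", "t_j", "is_a"),
        ("t_h", "t_i", "part_of"),
        ("t_i", "root", "is_a"),
        ("t_j", "root", "is_a"),
    ]
    dag = build_dag({t: NS for t in terms}, edges)
    direct = {
        "t_a": {"g1", "g6"},
        "t_b": {"g1", "g5"},
        "t_c": {"g6", "g7"},
        "t_d": {"g4"},
        "t_e": {"g5", "g8"},
        "t_f": {"g2", "g3"},
        "t_g": {"g9"},
        "t_h": {"g12"},
        "t_i": {"g13"},
        "t_j": {"g10", "g11"},
    }
    annots = propagate(
        AnnotationSet(direct={t: set(g) for t, g in direct.items()}, namespace=NS), dag
    )
    # worked 1C set: g1 plus two partners at confidence 0.01 (distance 0.99);
    # g2 has no edge into the set
    example_set = frozenset({"g1", "g12", "g13"})
    net = network_from_edges(
        [
            ("g1", "g12", 0.01),
            ("g1", "g13", 0.01),
            ("g2", "g3", 0.8),
            ("g6", "g7", 0.95),
            ("g10", "g11", 0.7),
            ("g4", "g8", 0.3),
        ]
    )
    return FixtureBundle(
        dag=dag,
        annots=annots,
        net=net,
        seed=None,
        manifest={"kind": "figure1"},
        example_gene_set=example_set,
    )


def random_fixture(
    n_terms: int = 20,
    n_genes: int = 30,
    annot_density: float = 0.1,
    net_density: float = 0.1,
    seed: int = 0,
    n_layers: int = 4,
) -> FixtureBundle:
    """A seeded layered random world; bit-identical per (parameters, seed).

    Terms occupy layers below a single root; every non-root term draws 1-3
    parents from strictly higher layers.  Every gene gets at least one
    direct annotation; extra annotations arrive at ``annot_density`` per
    (gene, term).  Network edges appear at ``net_density`` per gene pair
    with uniform confidences.
    """
    if n_terms < 2 or n_genes < 1:
        raise ValueError("need at least 2 terms and 1 gene")
    if not (0.0 < annot_density <= 1.0) or not (0.0 <= net_density <= 1.0):
        raise ValueError("densities must lie in (0,1] / [0,1]")
    rng = np.random.default_rng(seed)
    terms = [f"T:{i:04d}" for i in range(1, n_terms)]
    root = "T:0000"
    layer = {root: 0}
    for t in terms:
        layer[t] = int(rng.integers(1, n_layers + 1))
    edges = []
    for t in terms:
        uppers = [u for u in layer if layer[u] < layer[t]]
        uppers.sort()
        k = min(len(uppers), int(rng.integers(1, 4)))
        parents = rng.choice(len(uppers), size=k, replace=False)
        for idx in parents:
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            edges.append((t, uppers[idx], rel))
    dag = build_dag({root: NS, **{t: NS for t in terms}}, edges)

    genes = [f"g{i:03d}" for i in range(1, n_genes + 1)]
    direct: dict[str, set[str]] = {}
    for g in genes:
        first = terms[int(rng.integers(0, len(terms)))]
        direct.setdefault(first, set()).add(g)
        for t in terms:
            if t != first and rng.random() < annot_density:
                direct.setdefault(t, set()).add(g)
    annots = propagate(AnnotationSet(direct=direct, namespace=NS), dag)

    net_edges = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if rng.random() < net_density:
                net_edges.append((a, b, float(np.round(rng.uniform(0.05, 0.99), 3))))
    net = network_from_edges(net_edges)
    net.nodes |= set(genes)
    manifest = {
        "kind": "random",
        "n_terms": n_terms,
        "n_genes": n_genes,
        "annot_density": annot_density,
        "net_density": net_density,
        "n_layers": n_layers,
    }
    return FixtureBundle(dag=dag, annots=annots, net=net, seed=seed, manifest=manifest)


def delete_annotations(
    annots: AnnotationSet, dag: OntologyDAG, coverage: float, seed: int
) -> AnnotationSet:
    """Randomly keep ``coverage`` of direct annotations, never dropping a
    gene's last one (so the gene universe is unchanged across coverage
    levels)."""
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0,1]")
    rng = np.random.default_rng(seed)
    per_gene: dict[str, list[str]] = {
        g: sorted(ts) for g, ts in annots.gene_terms.items()
    }
    direct: dict[str, set[str]] = {}
    for g in sorted(per_gene):
        ts = per_gene[g]
        keep_n = max(1, int(round(coverage * len(ts))))
        kept_idx = rng.choice(len(ts), size=keep_n, replace=False)
        for idx in kept_idx:
            direct.setdefault(ts[idx], set()).add(g)
    return propagate(
        AnnotationSet(direct=direct, namespace=annots.namespace), dag
    )


def signal_benchmark(
    seed: int = 0,
    n_reactions: int = 10,
    genes_per_reaction: int = 3,
    signal_conf: float = 0.9,
    background_density: float = 0.05,
    noise_term_prob: float = 0.5,
    n_groups: int = 3,
) -> FixtureBundle:
    """A world where co-function edges encode reaction adjacency that the
    annotations do not.

    Reactions form a ring via shared compounds (plus a currency compound on
    every reaction, which must not create adjacency).  Each reaction has its
    own leaf term annotating its genes; the leaves hang off ``n_groups``
    mid-level terms assigned at random, so ontology topology and annotation
    overlap carry no adjacency signal.  High-confidence network edges join
    genes within a reaction and across adjacent reactions; sparse uniform
    background edges join random other pairs.  A network-aware measure can
    therefore separate adjacent from non-adjacent gene pairs; a purely
    annotation-based one cannot.
    """
    rng = np.random.default_rng(seed)
    R = n_reactions
    root = "T:0000"
    mids = [f"T:M{k}" for k in range(n_groups)]
    leaves = [f"T:R{k:02d}" for k in range(R)]
    noise_terms = [f"T:N{k}" for k in range(n_groups)]
    term_ns = {root: NS, **{t: NS for t in mids + leaves + noise_terms}}
    edges = [(m, root, "is_a") for m in mids]
    edges += [(t, root, "is_a") for t in noise_terms]
    group_of = {leaf: mids[int(rng.integers(0, n_groups))] for leaf in leaves}
    edges += [(leaf, group_of[leaf], "is_a") for leaf in leaves]
    dag = build_dag(term_ns, edges)

    genes_of: dict[str, set[str]] = {}
    direct: dict[str, set[str]] = {}
    genes: list[str] = []
    for k in range(R):
        r = f"rxn{k:02d}"
        members = {f"g{k:02d}_{i}" for i in range(genes_per_reaction)}
        genes_of[r] = members
        genes.extend(sorted(members))
        direct.setdefault(leaves[k], set()).update(members)
        for g in sorted(members):
            if rng.random() < noise_term_prob:
                direct.setdefault(
                    noise_terms[int(rng.integers(0, len(noise_terms)))], set()
                ).add(g)
    annots = propagate(AnnotationSet(direct=direct, namespace=NS), dag)

    # ring of reactions: rxn k shares compound c{k} with rxn k+1; ATP is a
    # currency compound shared by all and must not induce adjacency
    rows = []
    for k in range(R):
        r = f"rxn{k:02d}"
        substrates = [f"c{(k - 1) % R}", "ATP"]
        products = [f"c{k}"]
        rows.append(
            {
                "reaction": r,
                "genes": ",".join(sorted(genes_of[r])),
                "substrates": ",".join(substrates),
                "products": ",".join(products),
            }
        )
    rmap = build_reaction_map(pd.DataFrame(rows))

    net_edges: list[tuple[str, str, float]] = []
    reaction_index = {g: k for k in range(R) for g in genes_of[f"rxn{k:02d}"]}
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            ka, kb = reaction_index[a], reaction_index[b]
            ring_dist = min((ka - kb) % R, (kb - ka) % R)
            if ring_dist <= 1:
                net_edges.append((a, b, signal_conf))
            elif rng.random() < background_density:
                net_edges.append((a, b, float(np.round(rng.uniform(0.05, 0.3), 3))))
    net = network_from_edges(net_edges)
    net.nodes |= set(genes)

    manifest = {
        "kind": "signal_benchmark",
        "n_reactions": R,
        "genes_per_reaction": genes_per_reaction,
        "signal_conf": signal_conf,
        "background_density": background_density,
        "noise_term_prob": noise_term_prob,
        "n_groups": n_groups,
    }
    return FixtureBundle(
        dag=dag, annots=annots, net=net, reaction_map=rmap, seed=seed, manifest=manifest
    )
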