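"""Weighted gene co-function networks and the product-form distances.

Edge confidences conf(g_i, g_j) estimate the probability that two genes are
truly functionally linked; they must lie in [0, 1].  The pairwise distance is

    d_ij = 0            if i = j
         = 1            if <g_i, g_j> is not a network edge
         = 1 - conf     otherwise

and the distance from a gene to a gene *set* is the product of its pairwise
distances into the set, so one strong link (or set membership itself)
collapses the distance to ~0 while full disconnection gives exactly 1.
Genes absent from the network behave exactly like unconnected nodes, so the
measure degrades gracefully when network coverage is partial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd


class NetworkFormatError(Exception):
    """Malformed edge-list input."""


class NetworkDomainError(Exception):
    """Scores outside [0, 1] under normalize='none'."""


@dataclass
class CoFunctionNetwork:
    """Undirected weighted gene graph keyed by unordered pairs."""

    _conf: dict[frozenset, float] = field(default_factory=dict)
    nodes: set[str] = field(default_factory=set)
    raw_score_range: tuple[float, float] | None = None

    @property
    def n_edges(self) -> int:
        return len(self._conf)

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for pair, conf in self._conf.items():
            a, b = sorted(pair)
            yield a, b, conf

    def conf(self, g_i: str, g_j: str) -> float | None:
        """Edge confidence, or None when the pair has no edge."""
        return self._conf.get(frozenset((g_i, g_j)))

    def degree(self, gene: str) -> int:
        return sum(1 for pair in self._conf if gene in pair)


def network_from_edges(
    edges: Iterable[tuple[str, str, float]],
    raw_score_range: tuple[float, float] | None = None,
) -> CoFunctionNetwork:
    """Build a network from (gene_a, gene_b, conf) triples, conf in [0, 1]."""
    conf_map: dict[frozenset, float] = {}
    nodes: set[str] = set()
    for a, b, c in edges:
        if a == b:
            continue  # d_ii is 0 by definition, not by edge
        if not 0.0 <= c <= 1.0:
            raise NetworkDomainError(f"confidence {c} for ({a},{b}) outside [0,1]")
        pair = frozenset((a, b))
        conf_map[pair] = max(c, conf_map.get(pair, 0.0))
        nodes.update((a, b))
    return CoFunctionNetwork(_conf=conf_map, nodes=nodes, raw_score_range=raw_score_range)


def parse_network(path: str, normalize: str = "minmax") -> CoFunctionNetwork:
    """Read a 3-column TSV edge list (gene1, gene2, score).

    Published co-function networks (YeastNet/AraNet/HumanNet style) carry
    log-likelihood scores, not probabilities, so the default maps scores
    affinely onto [0, 1] from the observed min/max.  With ``normalize='none'``
    the scores are used as-is and must already lie in [0, 1].  Duplicate
    edges keep the maximum score; self-loops are dropped with a warning.
    """
    if normalize not in ("none", "minmax"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["gene1", "gene2", "score"],
            dtype={"gene1": str, "gene2": str},
        )
        scores = pd.to_numeric(df["score"], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise NetworkFormatError(f"non-numeric score in {path}: {exc}") from exc
    if df.isna().any().any():
        raise NetworkFormatError(f"missing fields in {path}")

    self_loops = int((df["gene1"] == df["gene2"]).sum())
    if self_loops:
        warnings.warn(f"dropping {self_loops} self-loop edge(s)")

    lo, hi = (float(scores.min()), float(scores.max())) if len(scores) else (0.0, 0.0)
    if normalize == "minmax" and len(scores):
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
        else:
            # degenerate single-valued input: every edge is equally (fully)
            # supported relative to the observed evidence
            scores = np.ones_like(scores)
    elif normalize == "none" and len(scores) and (lo < 0.0 or hi > 1.0):
        raise NetworkDomainError(
            f"scores span [{lo}, {hi}] outside [0,1]; use normalize='minmax'"
        )
    net = network_from_edges(
        zip(df["gene1"], df["gene2"], scores), raw_score_range=(lo, hi)
    )
    return net


def write_network(net: CoFunctionNetwork, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, conf in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{conf:.12g}\n")


# -- distances ------------------------------------------------------------


def pair_distance(net: CoFunctionNetwork, g_i: str, g_j: str) -> float:
    """d_ij: 0 for identical genes, 1 for non-edges, else 1 - conf."""
    if g_i == g_j:
        return 0.0
    conf = net.conf(g_i, g_j)
    return 1.0 if conf is None else 1.0 - conf


def gene_to_set_distance(net: CoFunctionNetwork, g: str, S: Iterable[str]) -> float:
    """Product over g_j in S of d(g, g_j); 0 when g is a member of S."""
    members = list(S)
    if not members:
        raise ValueError("gene set S must be nonempty")
    prod = 1.0
    for g_j in members:
        prod *= pair_distance(net, g, g_j)
        if prod == 0.0:
            break
    return prod


# -- perturbations for quality/density experiments ------------------------


def delete_edges(net: CoFunctionNetwork, fraction: float, seed: int) -> CoFunctionNetwork:
    """Randomly drop ``fraction`` of the edges (density degradation)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    pairs = sorted(net._conf, key=lambda p: tuple(sorted(p)))
    n_drop = int(round(fraction * len(pairs)))
    dropped = set(rng.choice(len(pairs), size=n_drop, replace=False)) if n_drop else set()
    kept = [
        (min(p), max(p), net._conf[pair])
        for i, pair in enumerate(pairs)
        if i not in dropped
        for p in [tuple(sorted(pair))]
    ]
    out = network_from_edges(kept, raw_score_range=net.raw_score_range)
    out.nodes |= net.nodes  # keep isolated nodes so coverage is unchanged
    return out


def rewire_network(
    net: CoFunctionNetwork, fraction: float, seed: int, max_tries_factor: int = 200
) -> CoFunctionNetwork:
    """Degree-preserving rewiring until ``fraction`` of the original edges
    are gone (quality degradation; fraction 1.0 = fully randomized).

    Repeated double-edge swaps: pick edges (a,b), (c,d) and replace with
    (a,d), (c,b) when that creates neither self-loops nor duplicates.
    Confidence values travel with the swapped endpoints, so the confidence
    multiset and the degree multiset are both preserved.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    edges = {tuple(sorted(p)): c for p, c in net._conf.items()}
    original = set(edges)
    if fraction == 0.0 or len(edges) < 2:
        out = network_from_edges((a, b, c) for (a, b), c in edges.items())
        out.nodes |= net.nodes
        return out
    target_remaining = int(round((1.0 - fraction) * len(original)))
    tries = 0
    max_tries = max_tries_factor * len(original)
    while tries < max_tries:
        still_original = sorted(e for e in edges if e in original)
        if len(still_original) <= target_remaining:
            break
        tries += 1
        # always swap an edge that still needs replacing against a random one
        keys = sorted(edges)
        (a, b) = still_original[int(rng.integers(0, len(still_original)))]
        (c, d) = keys[int(rng.integers(0, len(keys)))]
        if (a, b) == (c, d):
            continue
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if new1 in edges or new2 in edges:
            continue
        c1, c2 = edges.pop((a, b)), edges.pop((c, d))
        edges[new1], edges[new2] = c1, c2
    out = network_from_edges((a, b, c) for (a, b), c in edges.items())
    out.nodes |= net.nodes
    return out
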