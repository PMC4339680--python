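"""Independent brute-force implementations used as oracles.

Everything here is written from the formulas directly, with explicit loops
and no reuse of the package's computation paths (only its data containers
are read).  Deliberately slow and simple.
"""

from __future__ import annotations

import math
from itertools import combinations


# -- ontology -------------------------------------------------------------


def brute_ancestors(dag, term):
    """Reflexive ancestor closure by naive BFS over parent edges."""
    seen = {term}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in dag.graph.successors(t):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return frozenset(seen)


def brute_ancestors_matrix(dag, term):
    """Reflexive ancestor closure by repeated squaring of the reachability
    matrix (a second, independent route)."""
    import numpy as np

    nodes = sorted(dag.graph.nodes)
    idx = {t: i for i, t in enumerate(nodes)}
    n = len(nodes)
    adj = np.eye(n, dtype=bool)
    for c, p in dag.graph.edges:
        adj[idx[c], idx[p]] = True
    reach = adj.copy()
    for _ in range(max(1, n.bit_length())):
        reach = reach @ reach
    return frozenset(nodes[j] for j in range(n) if reach[idx[term], j])


def brute_path_terms(dag, t_a, t_b, p):
    """Enumerate all simple upward paths from t_a / t_b to p by DFS, union
    their nodes, and add all reflexive descendants of t_a and t_b."""
    def upward_paths(start, goal):
        out = []

        def dfs(node, path):
            if node == goal:
                out.append(list(path))
                return
            for parent in dag.graph.successors(node):
                if parent not in path:
                    dfs(parent, path + [parent])

        dfs(start, [start])
        return out

    terms = set()
    for start in (t_a, t_b):
        for path in upward_paths(start, p):
            terms.update(path)
    def down(t):
        seen = {t}
        stack = [t]
        while stack:
            x = stack.pop()
            for c in dag.graph.predecessors(x):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    return frozenset(terms | down(t_a) | down(t_b))


# -- annotations ----------------------------------------------------------


def brute_propagated(dag, direct, term):
    """Union of direct sets over explicitly enumerated reflexive descendants."""
    descendants = {term}
    stack = [term]
    while stack:
        t = stack.pop()
        for c in dag.graph.predecessors(t):
            if c not in descendants:
                descendants.add(c)
                stack.append(c)
    out = set()
    for t in descendants:
        out |= set(direct.get(t, ()))
    return out


# -- network distances ----------------------------------------------------


def brute_pair_distance(net, a, b):
    if a == b:
        return 0.0
    c = net.conf(a, b)
    return 1.0 if c is None else 1.0 - c


def brute_gene_set_distance(net, G_a, G_b):
    """Eq.-1 style evaluation with explicit nested loops."""
    def prod_to_set(g, S):
        out = 1.0
        for x in S:
            out *= brute_pair_distance(net, g, x)
        return out

    sum_a = sum(prod_to_set(g, G_b) for g in G_a)
    sum_b = sum(prod_to_set(g, G_a) for g in G_b)
    return (sum_a + sum_b) / (2 * len(set(G_a) | set(G_b)) - sum_a - sum_b)


def brute_gene_set_distance_v1(net, G_a, G_b):
    return sum(
        brute_pair_distance(net, a, b) for a in G_a for b in G_b
    ) / (len(G_a) * len(G_b))


# -- path-constrained annotation ------------------------------------------


def brute_U(dag, annots, t_a, t_b, p):
    genes = set(annots.term_genes(t_a)) | set(annots.term_genes(t_b))
    for t in brute_path_terms(dag, t_a, t_b, p):
        genes |= set(annots.direct.get(t, ()))
    return frozenset(genes)


# -- term similarity ------------------------------------------------------


def brute_term_similarity(dag, annots, net, t_a, t_b, p):
    """Spreadsheet-style evaluation of the full score at one ancestor."""
    G_a, G_b = annots.term_genes(t_a), annots.term_genes(t_b)
    G_p, G = annots.term_genes(p), annots.universe
    D = brute_gene_set_distance(net, G_a, G_b)
    U = brute_U(dag, annots, t_a, t_b, p)
    f = D ** 2 * len(U) + (1 - D ** 2) * math.sqrt(len(G_a) * len(G_b))
    h = D ** 2 * len(G) + (1 - D ** 2) * max(len(G_a), len(G_b))
    denom = 2 * math.log(len(G)) - (math.log(len(G_a)) + math.log(len(G_b)))
    if denom == 0:
        return 0.0
    first = (2 * math.log(len(G)) - 2 * math.log(f)) / denom
    second = 1 - h / len(G) * len(G_p) / len(G)
    return first * second


def brute_term_similarity_max(dag, annots, net, t_a, t_b):
    best = 0.0
    found = False
    for p in dag.common_ancestors(t_a, t_b):
        if not annots.term_genes(p):
            continue
        val = brute_term_similarity(dag, annots, net, t_a, t_b, p)
        best = val if not found else max(best, val)
        found = True
    return best


def brute_schlicker_fixed_p(annots, t_a, t_b, p):
    """Textbook relevance score evaluated at a prescribed ancestor."""
    G_a, G_b = annots.term_genes(t_a), annots.term_genes(t_b)
    G_p, G = annots.term_genes(p), annots.universe
    ic = lambda s: -math.log(len(s) / len(G))
    if ic(G_a) + ic(G_b) == 0:
        return 0.0
    return 2 * ic(G_p) / (ic(G_a) + ic(G_b)) * (1 - len(G_p) / len(G))


# -- Wang -----------------------------------------------------------------


def brute_wang(dag, t_a, t_b, weights):
    """Path-product enumeration: the contribution of ancestor p to t is the
    max over all simple upward paths t -> ... -> p of the product of edge
    weights along the path."""
    def contributions(t):
        anc = brute_ancestors(dag, t)
        best = {t: 1.0}

        def dfs(node, value):
            for parent in dag.graph.successors(node):
                w = weights[dag.graph.edges[node, parent]["relation"]]
                v = value * w
                if v > best.get(parent, 0.0):
                    best[parent] = v
                dfs(parent, v)

        # exhaustive: repeat DFS from every path prefix; simple DAG walk
        dfs(t, 1.0)
        return {p: best[p] for p in anc}

    s_a = contributions(t_a)
    s_b = contributions(t_b)
    common = set(s_a) & set(s_b)
    num = sum(s_a[p] + s_b[p] for p in common)
    den = sum(s_a.values()) + sum(s_b.values())
    return num / den


# -- gene similarity ------------------------------------------------------


def brute_gene_similarity(dag, annots, net, g_i, g_j):
    """Double loop over all term pairs with explicit maxima; leave-one-out
    by rebuilding the reduced annotation from scratch."""
    from netsim.annotations import AnnotationSet, propagate

    T_i = sorted(annots.gene_terms[g_i])
    T_j = sorted(annots.gene_terms[g_j])
    reduced_direct = {
        t: {g for g in gs if g not in (g_i, g_j)}
        for t, gs in annots.direct.items()
    }
    reduced = propagate(
        AnnotationSet(
            direct={t: set(g) for t, g in reduced_direct.items() if g},
            namespace=annots.namespace,
        ),
        dag,
    )

    def sim(t, T_y):
        if not reduced.term_genes(t):
            return 0.0
        vals = [
            brute_term_similarity_max(dag, reduced, net, t, ty)
            for ty in T_y
            if reduced.term_genes(ty)
        ]
        return max(vals) if vals else 0.0

    total = sum(v for t in T_i if (v := sim(t, T_j)) > 0)
    total += sum(v for t in T_j if (v := sim(t, T_i)) > 0)
    return total / (len(T_i) + len(T_j))


# -- LFC ------------------------------------------------------------------


def brute_lfc_gene(g, r, gs_lookup, rmap, c):
    """Direct evaluation of the log fold change with explicit set algebra.

    ``gs_lookup(a, b)`` returns GS or None for unscored genes.
    """
    g_r = set(rmap.genes_of[r])
    g_adj = set()
    for r2 in rmap.adjacency[r]:
        g_adj |= set(rmap.genes_of[r2])
    g_non = set()
    for r2 in rmap.reactions:
        if r2 != r and r2 not in rmap.adjacency[r]:
            g_non |= set(rmap.genes_of[r2])
    ambiguous = g_adj & g_non
    g_adj = g_adj - ambiguous - g_r
    g_non = g_non - ambiguous - g_r
    inter = [1 - v + c for x in g_non if (v := gs_lookup(g, x)) is not None]
    intra = [1 - v + c for x in g_adj if (v := gs_lookup(g, x)) is not None]
    if not inter or not intra:
        return None
    return math.log((sum(inter) / len(inter)) / (sum(intra) / len(intra)))


# -- multiple testing -----------------------------------------------------


def brute_bh(pvals, alpha):
    """Step-up Benjamini-Hochberg: reject H_(1..k) for the largest k with
    p_(k) <= k/m * alpha."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank / m * alpha:
            k_max = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_max:
            reject[i] = True
    return reject
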