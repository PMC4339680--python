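"""The similarity core: gene-set distance, path-constrained annotation,
the network-aware score and its reductions, and the baseline measures."""

import math

import pytest

from netsim import (
    CoFunctionNetwork,
    gene_set_distance,
    gene_set_distance_v1,
    information_content,
    network_from_edges,
    path_constrained_annotation,
    resnik,
    schlicker,
    term_similarity,
    term_similarity_matrix,
    term_similarity_max,
    wang,
)
from netsim.similarity import MeasureConfig

from oracles import (
    brute_gene_set_distance,
    brute_gene_set_distance_v1,
    brute_schlicker_fixed_p,
    brute_term_similarity,
    brute_term_similarity_max,
    brute_U,
    brute_wang,
)

EMPTY = CoFunctionNetwork()


def _annotated_pairs(bundle, limit=None):
    dag, annots = bundle.dag, bundle.annots
    terms = sorted(t for t in dag.terms if annots.term_genes(t))
    pairs = [(a, b) for i, a in enumerate(terms) for b in terms[i:]]
    return pairs[:limit] if limit else pairs


class TestGeneSetDistance:
    def test_identical_sets_zero(self, fig1):
        G = fig1.annots.term_genes("t_b")
        assert gene_set_distance(fig1.net, G, G) == 0.0

    def test_disjoint_unconnected_one(self):
        assert gene_set_distance(EMPTY, {"a", "b"}, {"c", "d"}) == 1.0

    def test_two_by_two_with_cross_edge(self):
        net = network_from_edges([("a1", "b1", 0.5)])
        G_a, G_b = {"a1", "a2"}, {"b1", "b2"}
        got = gene_set_distance(net, G_a, G_b)
        assert got == pytest.approx(brute_gene_set_distance(net, G_a, G_b), abs=1e-15)
        # hand evaluation: products a1->Gb = 0.5*1, a2->Gb = 1; b1->Ga = 0.5,
        # b2->Ga = 1; D = 3/(8-3)
        assert got == pytest.approx(3.0 / 5.0)

    def test_range_and_symmetry_random(self, random_bundles):
        for b in random_bundles:
            for t_a, t_b in _annotated_pairs(b, limit=40):
                G_a = b.annots.term_genes(t_a)
                G_b = b.annots.term_genes(t_b)
                d = gene_set_distance(b.net, G_a, G_b)
                assert 0.0 <= d <= 1.0
                assert d == pytest.approx(
                    gene_set_distance(b.net, G_b, G_a), abs=1e-14
                )

    def test_empty_set_rejected(self, fig1):
        with pytest.raises(ValueError):
            gene_set_distance(fig1.net, set(), {"g1"})

    def test_no_network_reduces_to_set_overlap_distance(self, random_bundles):
        # with all confidences -> 0 the measure becomes the plain
        # Czekanovski-Dice set distance
        for b in random_bundles[:2]:
            for t_a, t_b in _annotated_pairs(b, limit=20):
                G_a = b.annots.term_genes(t_a)
                G_b = b.annots.term_genes(t_b)
                expected = (len(G_a | G_b) - len(G_a & G_b)) / (
                    len(G_a | G_b) + len(G_a & G_b)
                )
                assert gene_set_distance(EMPTY, G_a, G_b) == pytest.approx(
                    expected, abs=1e-12
                )


class TestGeneSetDistanceV1:
    def test_unconnected_disjoint_one(self):
        assert gene_set_distance_v1(EMPTY, {"a"}, {"b", "c"}) == 1.0

    def test_shared_singleton_zero(self):
        assert gene_set_distance_v1(EMPTY, {"g"}, {"g"}) == 0.0

    def test_matches_enumeration(self, small_random):
        b = small_random
        for t_a, t_b in _annotated_pairs(b, limit=30):
            G_a, G_b = b.annots.term_genes(t_a), b.annots.term_genes(t_b)
            assert gene_set_distance_v1(b.net, G_a, G_b) == pytest.approx(
                brute_gene_set_distance_v1(b.net, G_a, G_b), abs=1e-12
            )


class TestPathConstrainedAnnotation:
    def test_figure_value_excludes_off_path_genes(self, fig1):
        U = path_constrained_annotation(fig1.dag, fig1.annots, "t_a", "t_b", "t_j")
        assert U == {"g1", "g2", "g3", "g5", "g6", "g7", "g10", "g11"}
        for off_path_term in ("t_d", "t_g"):
            assert not (fig1.annots.direct[off_path_term] & U)

    def test_degenerate_triple(self, fig1):
        U = path_constrained_annotation(fig1.dag, fig1.annots, "t_b", "t_b", "t_b")
        assert U == fig1.annots.term_genes("t_b")

    def test_containment_and_oracle(self, small_random):
        b = small_random
        checked = 0
        for t_a, t_b in _annotated_pairs(b, limit=25):
            for p in sorted(b.dag.common_ancestors(t_a, t_b)):
                U = path_constrained_annotation(b.dag, b.annots, t_a, t_b, p)
                assert U == brute_U(b.dag, b.annots, t_a, t_b, p)
                assert U <= (
                    b.annots.term_genes(p)
                    | b.annots.term_genes(t_a)
                    | b.annots.term_genes(t_b)
                )
                assert (b.annots.term_genes(t_a) | b.annots.term_genes(t_b)) <= U
                checked += 1
        assert checked > 30


class TestTermSimilarity:
    def test_figure_triple_matches_hand_computation(self, fig1):
        res = term_similarity(fig1.dag, fig1.annots, fig1.net, "t_a", "t_b", "t_j")
        expected = brute_term_similarity(
            fig1.dag, fig1.annots, fig1.net, "t_a", "t_b", "t_j"
        )
        assert res.S == pytest.approx(expected, abs=1e-12)
        assert res.U == {"g1", "g2", "g3", "g5", "g6", "g7", "g10", "g11"}

    def test_self_similarity_resnik_proportional(self, fig1, random_bundles):
        for b in [fig1] + random_bundles:
            G = b.annots.universe
            for t in sorted(b.dag.terms):
                G_t = b.annots.term_genes(t)
                if not G_t:
                    continue
                res = term_similarity(b.dag, b.annots, b.net, t, t, t)
                assert res.S == pytest.approx(
                    1 - (len(G_t) / len(G)) ** 2, abs=1e-12
                )

    def test_schlicker_reduction_disjoint_no_network(self, random_bundles):
        # with no network and disjoint gene sets, D = 1 and the score takes
        # Schlicker's functional form with ln|U| in the first factor; when
        # the path-constrained set coincides with G_p this is exactly the
        # fixed-ancestor Schlicker value
        strict = 0
        for b in random_bundles:
            for t_a, t_b in _annotated_pairs(b):
                G_a, G_b = b.annots.term_genes(t_a), b.annots.term_genes(t_b)
                if G_a & G_b:
                    continue
                for p in sorted(b.dag.common_ancestors(t_a, t_b)):
                    if not b.annots.term_genes(p):
                        continue
                    res = term_similarity(b.dag, b.annots, EMPTY, t_a, t_b, p)
                    assert res.D == 1.0
                    if len(res.U) == len(b.annots.term_genes(p)):
                        expected = brute_schlicker_fixed_p(b.annots, t_a, t_b, p)
                        assert abs(res.S - expected) <= 1e-12
                        strict += 1
        assert strict >= 20

    def test_invariant_ranges(self, random_bundles):
        for b in random_bundles:
            G = b.annots.universe
            for t_a, t_b in _annotated_pairs(b, limit=30):
                res = term_similarity_max(b.dag, b.annots, b.net, t_a, t_b)
                G_a, G_b = b.annots.term_genes(t_a), b.annots.term_genes(t_b)
                assert 0.0 <= res.S <= 1.0
                assert 0.0 <= res.D <= 1.0
                assert res.U >= (G_a | G_b)
                lo_f = math.sqrt(len(G_a) * len(G_b)) - 1e-9
                assert lo_f <= res.f <= len(G) + 1e-9
                assert max(len(G_a), len(G_b)) - 1e-9 <= res.h <= len(G) + 1e-9

    def test_v2_changes_only_f(self, small_random):
        b = small_random
        for t_a, t_b in _annotated_pairs(b, limit=15):
            for p in sorted(b.dag.common_ancestors(t_a, t_b)):
                if not b.annots.term_genes(p):
                    continue
                full = term_similarity(b.dag, b.annots, b.net, t_a, t_b, p)
                v2 = term_similarity(
                    b.dag, b.annots, b.net, t_a, t_b, p,
                    MeasureConfig("netsim_v2"),
                )
                assert v2.D == full.D
                assert v2.h == full.h
                assert len(v2.U) >= len(full.U)

    def test_v3_uses_schlicker_weight(self, fig1):
        res = term_similarity(
            fig1.dag, fig1.annots, fig1.net, "t_a", "t_b", "t_j",
            MeasureConfig("netsim_v3"),
        )
        full = term_similarity(fig1.dag, fig1.annots, fig1.net, "t_a", "t_b", "t_j")
        G_p = fig1.annots.term_genes("t_j")
        G = fig1.annots.universe
        ratio_second = 1 - len(G_p) / len(G)
        assert res.S == pytest.approx(
            full.S / (1 - full.h / len(G) * len(G_p) / len(G)) * ratio_second,
            abs=1e-12,
        )


class TestTermSimilarityMax:
    def test_self_max_at_own_term(self, fig1):
        res = term_similarity_max(fig1.dag, fig1.annots, fig1.net, "t_e", "t_e")
        assert res.ancestor == "t_e"
        G_t = fig1.annots.term_genes("t_e")
        assert res.S == pytest.approx(
            1 - (len(G_t) / len(fig1.annots.universe)) ** 2, abs=1e-12
        )

    def test_equals_exhaustive_enumeration(self, fig1, small_random):
        for b in (fig1, small_random):
            for t_a, t_b in _annotated_pairs(b, limit=25):
                got = term_similarity_max(b.dag, b.annots, b.net, t_a, t_b).S
                expected = brute_term_similarity_max(b.dag, b.annots, b.net, t_a, t_b)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_symmetry(self, small_random):
        b = small_random
        for t_a, t_b in _annotated_pairs(b, limit=25):
            ab = term_similarity_max(b.dag, b.annots, b.net, t_a, t_b).S
            ba = term_similarity_max(b.dag, b.annots, b.net, t_b, t_a).S
            assert ab == pytest.approx(ba, abs=1e-14)


class TestBaselines:
    def test_resnik_root_and_self(self, fig1):
        annots, dag = fig1.annots, fig1.dag
        assert resnik(annots, dag, "t_e", "root") == 0.0
        assert resnik(annots, dag, "t_e", "t_e") == pytest.approx(
            information_content(annots, "t_e")
        )

    def test_resnik_counts(self, fig1):
        # LCA of (t_a, t_b) is t_i with the smaller propagated set
        expected = -math.log(
            len(fig1.annots.term_genes("t_i")) / len(fig1.annots.universe)
        )
        assert resnik(fig1.annots, fig1.dag, "t_a", "t_b") == pytest.approx(expected)

    def test_schlicker_root_and_self(self, fig1):
        annots, dag = fig1.annots, fig1.dag
        assert schlicker(annots, dag, "t_e", "root") == 0.0
        G_t = annots.term_genes("t_e")
        assert schlicker(annots, dag, "t_e", "t_e") == pytest.approx(
            1 - len(G_t) / len(annots.universe)
        )

    def test_schlicker_substitution(self, fig1):
        assert schlicker(fig1.annots, fig1.dag, "t_a", "t_b") == pytest.approx(
            brute_schlicker_fixed_p(fig1.annots, "t_a", "t_b", "t_i"), abs=1e-12
        )

    def test_wang_identity(self, fig1):
        assert wang(fig1.dag, "t_e", "t_e") == pytest.approx(1.0)

    def test_wang_chain_closed_form(self):
        from netsim.ontology import build_dag

        w = 0.8
        dag = build_dag(
            {"a": "biological_process", "b": "biological_process"},
            [("a", "b", "is_a")],
        )
        # S_a = {a: 1, b: w}; S_b = {b: 1}; common = {b}
        assert wang(dag, "a", "b") == pytest.approx((w + 1) / (w + 2))

    def test_wang_matches_path_enumeration(self, fig1, small_random):
        for b in (fig1, small_random):
            terms = sorted(b.dag.terms)
            for t_a in terms[::2]:
                for t_b in terms[::3]:
                    got = wang(b.dag, t_a, t_b)
                    expected = brute_wang(
                        b.dag, t_a, t_b, {"is_a": 0.8, "part_of": 0.6}
                    )
                    assert got == pytest.approx(expected, abs=1e-10)
                    assert got == pytest.approx(wang(b.dag, t_b, t_a), abs=1e-14)


class TestMatrix:
    def test_single_term(self, fig1):
        m = term_similarity_matrix(fig1.dag, fig1.annots, fig1.net, ["t_e"])
        assert m.shape == (1, 1)

    def test_matches_elementwise_and_permutes(self, fig1):
        terms = ["t_a", "t_b", "t_e"]
        m = term_similarity_matrix(fig1.dag, fig1.annots, fig1.net, terms)
        for t_a in terms:
            for t_b in terms:
                assert m.at[t_a, t_b] == pytest.approx(
                    term_similarity_max(fig1.dag, fig1.annots, fig1.net, t_a, t_b).S
                )
        perm = ["t_e", "t_a", "t_b"]
        m2 = term_similarity_matrix(fig1.dag, fig1.annots, fig1.net, perm)
        assert (m2.loc[terms, terms].to_numpy() == m.to_numpy()).all()

    def test_empty_terms_skipped_with_warning(self, fig1):
        from netsim.annotations import remove_genes

        red = remove_genes(fig1.annots, {"g6", "g7"})  # t_c empties out
        with pytest.warns(UserWarning):
            m = term_similarity_matrix(fig1.dag, red, fig1.net, ["t_b", "t_c"])
        assert list(m.index) == ["t_b"]
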