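"""Aggregate term similarities into gene-to-gene functional similarity.

Scores the worked-example pair (g10, g11) — both annotated to t_j — with
the leave-one-out convention: the pair is removed from every term's gene
set (and the universe) before any term similarity is computed.
"""

from netsim import figure1_fixture, gene_similarity, gene_similarity_matrix

bundle = figure1_fixture()
dag, annots, net = bundle.dag, bundle.annots, bundle.net

score = gene_similarity(dag, annots, net, "g10", "g11")
print(f"GS(g10, g11) = {score.GS:.6f}")
print("  term sets:", sorted(score.term_set_i), sorted(score.term_set_j))
for key, (partner, val) in sorted(score.best_matches.items()):
    print(f"  best match {key} -> {partner}  Sim = {val:.6f}")

genes = ["g1", "g5", "g8", "g10"]
m = gene_similarity_matrix(dag, annots, net, genes)
print("\npairwise GS matrix (diagonal 1 by convention):")
print(m.round(4))
print("GS in [0,1]: 1 = functionally indistinguishable annotation profiles.")
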