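"""Benchmark measures against a metabolic reaction map.

Generates a seeded world where co-function edges encode reaction adjacency
that the GO annotations do not, scores all gene pairs with the
network-aware measure and with the annotation-only Schlicker measure, and
compares their logged-fold-change (LFC) distributions.  Higher LFC means
the measure separates within-pathway gene pairs from unrelated ones
better.
"""

from netsim import (
    gene_similarity_matrix,
    lfc_benchmark,
    rewire_network,
    signal_benchmark,
)
from netsim.similarity import MeasureConfig

bundle = signal_benchmark(seed=1)
rmap = bundle.reaction_map
genes = sorted({g for r in rmap.reactions for g in rmap.genes_of[r]})
print(f"{len(rmap.reactions)} reactions in a ring, {len(genes)} genes, "
      f"{bundle.net.n_edges} network edges")

gs = {
    "netsim": gene_similarity_matrix(bundle.dag, bundle.annots, bundle.net, genes),
    "schlicker": gene_similarity_matrix(
        bundle.dag, bundle.annots, bundle.net, genes, MeasureConfig("schlicker")
    ),
}
result = lfc_benchmark(rmap, gs)
print("\nLFC summary (median / quartiles) and reactions won:")
summary = result.summary.copy()
summary["wins"] = result.winners
print(summary.round(4))

print("\nnetwork-quality degradation (median netsim LFC):")
for frac in (0.0, 0.5, 1.0):
    net = rewire_network(bundle.net, frac, seed=101)
    gs_deg = gene_similarity_matrix(bundle.dag, bundle.annots, net, genes)
    med = lfc_benchmark(rmap, {"netsim": gs_deg}).summary.loc["netsim", "median"]
    print(f"  {int(frac * 100):>3}% of edges rewired: {med: .4f}")
print("Rewiring destroys the adjacency signal, so the advantage over an "
      "annotation-only measure disappears.")
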