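# Methods

## Model

The package scores the functional similarity of two GO terms within one
namespace by combining three sources: the ontology DAG (is_a and part_of
child→parent edges only), propagated gene annotations, and a weighted
undirected gene co-function network whose edge confidences lie in [0, 1].

Annotation follows the true-path rule: the gene set G_t of a term is the
union of direct annotations over its reflexive descendants, and the
universe G is the root's propagated set — genes are in the model only by
virtue of annotation, never by genome membership. All ancestor and
descendant closures are reflexive, which makes self-similarity well
defined for every measure. Cross-namespace term pairs are errors, not
zeros: the measures are only meaningful within one GO category.

The three computation steps, with exact formulas, are in the README. The
assumptions worth making explicit:

- **Network distances are probabilistic complements.** d = 1 − conf treats
  the confidence as the probability of a true functional link; the product
  over a set treats links as independent, so the gene-to-set distance is
  the probability that a gene is linked to *none* of the set. Genes absent
  from the network behave exactly like unconnected nodes, so the measure
  degrades continuously as network coverage shrinks, reaching the plain
  Czekanovski–Dice set-overlap distance with no network at all.
- **Path constraining uses direct annotations of interior terms.** The
  constrained set U mixes the *propagated* sets of the two compared terms
  with the *direct* annotations of every term on the upward paths to the
  chosen ancestor. Propagating interior terms would re-import exactly the
  off-path descendants the constraint exists to exclude.
- **Ancestor maximization is exhaustive.** S is maximized over every
  annotated common ancestor. Memoized ancestor closures and a per-pair
  gene-set distance (D does not depend on the ancestor) keep this cheap;
  value ties report the lexicographically smallest ancestor so logs are
  reproducible.
- **Terms on a path are closure intersections.** A term lies on some
  directed path t → … → p iff it is an ancestor of t and a descendant of
  p, so path sets are computed set-algebraically; is_a and part_of edges
  participate identically, since both are loaded as plain parent edges.

## Parameters

| parameter | default | meaning |
|---|---|---|
| evidence exclusion | {IEA} | GAF rows dropped before propagation; empty set keeps electronic annotations. NOT-qualified rows are always dropped by default. |
| network normalization | minmax | affine map of raw scores onto [0,1]; published log-likelihood-scored networks are not probabilities. `none` requires scores already in [0,1]. Duplicate edges keep the max score. |
| log base | e (fixed) | the first factor of S is a log ratio, so the base cancels; fixing it keeps results bit-identical. |
| Wang edge weights | 0.8 is_a / 0.6 part_of | conventional semantic-contribution factors; exposed in `MeasureConfig`. |
| LFC smoothing c | 0.001 | keeps the log ratio finite when GS = 1; any small positive value, configurable in `LfcConfig`. |
| min genes per reaction | 2 | single-gene reactions carry no within-reaction signal and are skipped. |
| currency compounds | 24-entry list (ATP, H2O, NAD+, …) | compounds never allowed to justify reaction adjacency; a stand-in list of the usual ubiquitous metabolites — real analyses should pass the identifiers of their own pathway database. |
| GS denominator | \|T_i\|+\|T_j\| | zero best-matches contribute nothing to the numerator but still count in the denominator, following the printed aggregation formula; `nonzero_denominator=True` counts only non-zero matches. |
| genome-specificity test | one-sample t vs. global mean, BH FDR 0.01 | the published procedure is under-specified; this construction tests each pair's organism-pair components against the mean of all pairs' components. Zero-variance components give p = 1 on the global mean, p = 0 off it. |

## Degenerate inputs and numerical choices

- Both terms annotated to the whole universe make the first factor 0/0;
  S is defined as 0 (such terms carry no information, matching the
  IC-measure limits). The Schlicker denominator IC(t_a)+IC(t_b) = 0 is
  handled the same way.
- The Czekanovski–Dice denominator cannot vanish: it reaches 0 only if
  both row sums are maximal *and* the sets coincide, which forces the row
  sums to 0 instead.
- S is clamped to [0, 1] against floating-point drift; analytically it is
  already in range because |U| ≥ |G_a ∪ G_b| ≥ √(|G_a||G_b|) bounds f
  from below and |G| bounds f and h from above.
- GS(g, g) = 1 by convention: leave-one-out would delete the gene's own
  annotations, so self-similarity is a boundary definition, not a
  measurement. Terms whose propagated set empties under leave-one-out
  contribute Sim = 0 rather than erroring.
- Relation filtering can disconnect an ontology into several parentless
  terms; the most-covering one is taken as the namespace root, with a
  warning.

## Synthetic worlds

`figure1_fixture` pins down the small worked-example world (11 terms, 13
genes). Only its observable facts are fixed — path-constrained term sets,
the membership of U(t_a,t_b,t_j), the leave-one-out gene sets, the two
product-form distances — and tests assert those facts, not the particular
edge layout chosen to satisfy them.

`random_fixture` generates layered DAGs (each non-root term takes 1–3
parents from strictly higher layers), at-least-one annotation per gene,
and Bernoulli network edges with uniform confidences, all from one seeded
RNG recorded in the bundle manifest. It emulates the *shape* of real
inputs, not GO's topology statistics or calibrated confidence
distributions — so green property suites certify the arithmetic and the
contracts, not biological performance.

`signal_benchmark` constructs the one situation the network-aware measure
exists for: a ring of 10 reactions × 3 genes whose adjacency is encoded by
high-confidence (0.9) co-function edges but *not* by the ontology — each
reaction has its own leaf term, leaves are grouped under mid-level terms
at random, and each gene may carry one random noise term. A ring gives
every reaction the same 2-adjacent / 7-non-adjacent split, so median LFC
differences are attributable to the measures, not the topology. Sizes are
the package's own choice of a desk-scale benchmark: large enough for
stable medians, small enough that the full suite runs in seconds.
Network-quality degradation uses seeded degree-preserving double-edge
swaps that carry confidences with the swapped endpoints, preserving both
the degree and the confidence multisets; density degradation deletes edges
uniformly.

## Design choices made where the design was open

- The reduction to the Schlicker measure in the no-network, disjoint-set
  limit is exact in functional form, with ln|U| standing where ln|G_p|
  stands in the textbook score; the two coincide exactly when every
  annotated descendant of the ancestor lies on the constrained paths. The
  test suite asserts the functional form everywhere and the literal
  equality on the (abundant) triples satisfying that premise.
- Leave-one-out removes the evaluated pair from the universe as well as
  from every term's set, since IC-type quantities divide by |G|; the
  genes' own term lists T_i, T_j still come from the original annotation.
- "Non-adjacent" reactions are all reactions that are neither the focal
  reaction nor adjacent to it (not merely distance-2);
  `ReactionMap.reaction_distances` supports stratifying by path length
  separately.
- Genome-specificity Diff sums over ordered organism pairs (each unordered
  difference counted twice), while the t test runs on the unordered
  components; the factor of two cancels in the test but matches the
  printed Diff definition.

## Known limitations

- The product-form distance assumes edge independence; correlated evidence
  in real networks will overstate connectivity.
- Exhaustive ancestor maximization is quadratic in annotated terms for
  full-matrix workloads; fine at benchmark scale, unoptimized for
  whole-GO × whole-genome runs.
- The Wang measure here uses only is_a/part_of; ontologies where
  `regulates` matters need those edges, which the parser deliberately
  drops.
- The currency-compound default list is generic; reaction adjacency on a
  real pathway database is only as good as the compound identifiers
  supplied.
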