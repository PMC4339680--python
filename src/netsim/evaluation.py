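"""Benchmark statistics over metabolic reaction maps, and the
genome-specificity score.

Reaction maps connect two reactions when they share at least one
non-currency compound; ubiquitous currency metabolites (ATP, H2O, ...) are
excluded because they interconnect most of the network and create
biologically unrealistic shortcuts.  The benchmark contrasts, per gene, its
GO-based distances to genes of adjacent reactions (intra) against genes of
non-adjacent reactions (inter) as a logged fold change:

    lfc(g, r) = ln [ mean_{g' in G_non(r)} (1 - GS(g,g') + c) ]
                 / [ mean_{g* in G_adj(r)} (1 - GS(g,g*) + c) ]
    LFC(r)    = mean_{g in G(r)} lfc(g, r)

with c a small positive smoothing constant.  Larger LFC means the measure
separates within-pathway gene pairs from unrelated pairs better.

Genome specificity asks whether adding the co-function network makes term
similarities more organism-specific: for a term pair scored in k organisms
with (S_net) and without (S_nonet) the network,

    Diff = sum_{m != n} |S_net(o_m) - S_net(o_n)|
         - sum_{m != n} |S_nonet(o_m) - S_nonet(o_n)|.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Ubiquitous metabolites excluded when linking reactions.  A 24-entry
#: default list of the usual suspects; real analyses should supply the
#: compound identifiers of their own pathway database.
DEFAULT_CURRENCY = (
    "H2O", "H+", "ATP", "ADP", "AMP", "Pi", "PPi", "NAD+", "NADH",
    "NADP+", "NADPH", "FAD", "FADH2", "CO2", "O2", "NH3", "CoA",
    "acetyl-CoA", "UDP", "UTP", "GDP", "GTP", "S-adenosyl-methionine",
    "glutamate",
)


@dataclass(frozen=True)
class LfcConfig:
    """Smoothing constant and reaction filters for the LFC benchmark."""

    c: float = 0.001
    min_genes_per_reaction: int = 2
    max_path_length: int | None = None

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be a small positive constant")


@dataclass
class ReactionMap:
    """Reactions, their gene sets and compound sets, and shared-compound
    adjacency (currency compounds excluded)."""

    reactions: list[str]
    genes_of: dict[str, set[str]]
    compounds_of: dict[str, set[str]]
    adjacency: dict[str, set[str]]
    currency: frozenset[str]

    def adjacent_genes(self, r: str) -> set[str]:
        """G_adj(r): genes of reactions adjacent to r."""
        out: set[str] = set()
        for r2 in self.adjacency[r]:
            out |= self.genes_of[r2]
        return out

    def non_adjacent_genes(self, r: str) -> set[str]:
        """G_non(r): genes of every reaction neither r nor adjacent to r."""
        out: set[str] = set()
        for r2 in self.reactions:
            if r2 != r and r2 not in self.adjacency[r]:
                out |= self.genes_of[r2]
        return out

    def reaction_distances(self, source: str) -> dict[str, int]:
        """Breadth-first shortest path lengths in reaction steps."""
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for r in frontier:
                for r2 in self.adjacency[r]:
                    if r2 not in dist:
                        dist[r2] = dist[r] + 1
                        nxt.append(r2)
            frontier = nxt
        return dist


def build_reaction_map(
    table: str | pd.DataFrame,
    currency: tuple[str, ...] | list[str] = DEFAULT_CURRENCY,
) -> ReactionMap:
    """Build a :class:`ReactionMap` from a TSV table (or DataFrame) with
    columns: reaction id, comma-separated genes, comma-separated substrates,
    comma-separated products.

    Two reactions are adjacent when they share at least one non-currency
    compound, on either side.
    """
    if isinstance(table, str):
        df = pd.read_csv(
            table, sep="\t", header=None, comment="#",
            names=["reaction", "genes", "substrates", "products"],
            dtype=str, keep_default_na=False,
        )
    else:
        df = table
    currency_set = frozenset(currency)

    def split(cell: str) -> set[str]:
        return {x.strip() for x in str(cell).split(",") if x.strip()}

    reactions: list[str] = []
    genes_of: dict[str, set[str]] = {}
    compounds_of: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        r = str(row["reaction"])
        reactions.append(r)
        genes_of[r] = split(row["genes"])
        compounds_of[r] = split(row.get("substrates", "")) | split(row.get("products", ""))
        if not compounds_of[r]:
            warnings.warn(f"reaction {r!r} lists no compounds; it will be isolated")
    adjacency: dict[str, set[str]] = {r: set() for r in reactions}
    for i, r1 in enumerate(reactions):
        c1 = compounds_of[r1] - currency_set
        for r2 in reactions[i + 1:]:
            if c1 & (compounds_of[r2] - currency_set):
                adjacency[r1].add(r2)
                adjacency[r2].add(r1)
    return ReactionMap(reactions, genes_of, compounds_of, adjacency, currency_set)


def write_reaction_map(rmap: ReactionMap, path: str) -> None:
    """Serialize a map back to the 4-column TSV contract (compounds are
    written as substrates; sidedness does not affect adjacency)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in rmap.reactions:
            fh.write(
                f"{r}\t{','.join(sorted(rmap.genes_of[r]))}"
                f"\t{','.join(sorted(rmap.compounds_of[r]))}\t\n"
            )


# -- LFC ------------------------------------------------------------------


class LfcUndefinedError(ValueError):
    """Adjacent or non-adjacent gene set emptied out by filtering."""


def _filtered_sets(rmap: ReactionMap, r: str) -> tuple[set[str], set[str]]:
    """Apply the ambiguity filters: genes in both G_adj and G_non leave
    both; genes shared with G(r) leave the side sets."""
    g_r = rmap.genes_of[r]
    g_adj = rmap.adjacent_genes(r)
    g_non = rmap.non_adjacent_genes(r)
    both = g_adj & g_non
    g_adj = (g_adj - both) - g_r
    g_non = (g_non - both) - g_r
    return g_adj, g_non


def _gs_lookup(gs: pd.DataFrame, g1: str, g2: str) -> float | None:
    try:
        return float(gs.at[g1, g2])
    except KeyError:
        return None


def lfc_gene(
    g: str,
    r: str,
    gs: pd.DataFrame,
    rmap: ReactionMap,
    cfg: LfcConfig = LfcConfig(),
) -> float:
    """lfc(g, r): log ratio of mean inter-distance to mean intra-distance."""
    if g not in rmap.genes_of[r]:
        raise ValueError(f"gene {g!r} is not in reaction {r!r}")
    g_adj, g_non = _filtered_sets(rmap, r)
    inter = [1.0 - v + cfg.c for x in sorted(g_non)
             if (v := _gs_lookup(gs, g, x)) is not None]
    intra = [1.0 - v + cfg.c for x in sorted(g_adj)
             if (v := _gs_lookup(gs, g, x)) is not None]
    if not inter or not intra:
        raise LfcUndefinedError(
            f"reaction {r!r}: empty adjacent or non-adjacent set after filtering"
        )
    return math.log((sum(inter) / len(inter)) / (sum(intra) / len(intra)))


def lfc_reaction(
    r: str,
    gs: pd.DataFrame,
    rmap: ReactionMap,
    cfg: LfcConfig = LfcConfig(),
) -> float:
    """LFC(r): mean of lfc(g, r) over the reaction's scored genes.

    Returns NaN (with a log entry) when the reaction is undefined —
    too few genes, or a side set emptied by filtering.
    """
    genes = sorted(g for g in rmap.genes_of[r] if g in gs.index)
    if len(rmap.genes_of[r]) < cfg.min_genes_per_reaction:
        logger.info("skipping reaction %s: fewer than %d genes", r, cfg.min_genes_per_reaction)
        return float("nan")
    if not genes:
        logger.info("skipping reaction %s: no genes with GS scores", r)
        return float("nan")
    try:
        vals = [lfc_gene(g, r, gs, rmap, cfg) for g in genes]
    except LfcUndefinedError as exc:
        logger.info("skipping reaction %s: %s", r, exc)
        return float("nan")
    return float(np.mean(vals))


@dataclass
class LfcBenchmark:
    """Per-reaction LFC table plus winner counts and quartile summary."""

    per_reaction: pd.DataFrame  # rows: reactions; columns: measures
    winners: pd.Series          # measure -> number of reactions won
    summary: pd.DataFrame       # rows: measures; columns: median/q25/q75


def lfc_benchmark(
    rmap: ReactionMap,
    gs_by_measure: Mapping[str, pd.DataFrame],
    cfg: LfcConfig = LfcConfig(),
) -> LfcBenchmark:
    """Run the LFC benchmark for several measures over one reaction map."""
    table = pd.DataFrame(
        {
            name: [lfc_reaction(r, gs, rmap, cfg) for r in rmap.reactions]
            for name, gs in gs_by_measure.items()
        },
        index=rmap.reactions,
    )
    scored = table.dropna(how="any")
    winners = (
        scored.idxmax(axis=1).value_counts().reindex(table.columns, fill_value=0)
        if len(scored)
        else pd.Series(0, index=table.columns)
    )
    summary = pd.DataFrame(
        {
            "median": table.median(),
            "q25": table.quantile(0.25),
            "q75": table.quantile(0.75),
        }
    )
    return LfcBenchmark(per_reaction=table, winners=winners, summary=summary)


# -- genome specificity ---------------------------------------------------


@dataclass
class GenomeSpecificity:
    """Inter-genome disagreement gap for one term pair.

    ``components`` holds, per unordered organism pair, the contribution
    |S_net(m) - S_net(n)| - |S_nonet(m) - S_nonet(n)|; the printed Diff
    sums over ordered pairs, i.e. twice the component sum.
    """

    term_pair: tuple[str, str]
    s_net: dict[str, float]
    s_nonet: dict[str, float]
    diff_net: float = field(init=False)
    diff_nonet: float = field(init=False)
    diff: float = field(init=False)
    components: list[float] = field(init=False)

    def __post_init__(self) -> None:
        orgs = sorted(self.s_net)
        if sorted(self.s_nonet) != orgs:
            raise ValueError("s_net and s_nonet must cover the same organisms")
        if len(orgs) < 2:
            warnings.warn(
                f"term pair {self.term_pair}: fewer than 2 organisms; Diff = 0"
            )
        comp = []
        for i, m in enumerate(orgs):
            for n in orgs[i + 1:]:
                comp.append(
                    abs(self.s_net[m] - self.s_net[n])
                    - abs(self.s_nonet[m] - self.s_nonet[n])
                )
        self.components = comp
        # ordered-pair sums (m != n) count each unordered pair twice
        self.diff_net = 2.0 * sum(
            abs(self.s_net[m] - self.s_net[n])
            for i, m in enumerate(orgs) for n in orgs[i + 1:]
        )
        self.diff_nonet = 2.0 * sum(
            abs(self.s_nonet[m] - self.s_nonet[n])
            for i, m in enumerate(orgs) for n in orgs[i + 1:]
        )
        self.diff = self.diff_net - self.diff_nonet


def genome_specificity(
    term_pair: tuple[str, str],
    s_net: Mapping[str, float],
    s_nonet: Mapping[str, float],
) -> GenomeSpecificity:
    """Score one term pair's genome specificity across organisms."""
    return GenomeSpecificity(tuple(term_pair), dict(s_net), dict(s_nonet))


def genome_specific_pairs(
    records: list[GenomeSpecificity],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Flag term pairs whose specificity differs from the global average.

    Each pair's organism-pair components are tested (one-sample t) against
    the global mean of all pairs' components; p-values are Benjamini-
    Hochberg corrected and pairs with FDR < ``alpha`` are flagged.  Pairs
    with fewer than 2 components are excluded.  Zero-variance components
    get p = 1 when they sit on the global mean (nothing to distinguish)
    and p = 0 when they are constant but displaced from it.
    """
    usable = [rec for rec in records if len(rec.components) >= 2]
    if not usable:
        return pd.DataFrame(
            columns=["term_a", "term_b", "diff", "p_value", "q_value", "significant"]
        )
    all_components = np.concatenate([rec.components for rec in usable])
    global_mean = float(all_components.mean())
    pvals = []
    for rec in usable:
        comp = np.asarray(rec.components, dtype=float)
        if comp.std(ddof=1) == 0.0:
            p = 1.0 if math.isclose(comp.mean(), global_mean, abs_tol=1e-12) else 0.0
        else:
            p = float(stats.ttest_1samp(comp, popmean=global_mean).pvalue)
        pvals.append(p)
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = pd.DataFrame(
        {
            "term_a": [rec.term_pair[0] for rec in usable],
            "term_b": [rec.term_pair[1] for rec in usable],
            "diff": [rec.diff for rec in usable],
            "p_value": pvals,
            "q_value": qvals,
            "significant": reject,
        }
    )
    return out
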