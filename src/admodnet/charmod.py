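"""Functional and cell-type characterisation of the disease module.

Overrepresentation of gene sets in the module (one-sided Fisher exact test
with Benjamini-Hochberg correction), rank-based one-tail gene-set
enrichment by the Kolmogorov-Smirnov statistic, and evidence-based ranking
and partitioning of the module-internal edges.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    EvidenceTable,
    GeneSetCollection,
    RankedEdgeList,
    SeedSet,
    WeightedGeneNetwork,
)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def overrepresentation(
    module: set[str], collection: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """One-sided Fisher exact test of module membership against each set.

    Each 2x2 table crosses (in module) x (in set) over the universe; the
    one-sided alternative tests for overrepresentation. Sets with no genes
    in the universe are skipped with a warning. Returns a DataFrame
    indexed by set id with columns overlap, set_size, p, p_adj.
    """
    if not module <= universe:
        raise ValueError("module must be a subset of the universe")
    rows = []
    for set_id in sorted(collection.sets):
        genes = collection.sets[set_id] & universe
        if not genes:
            warnings.warn(f"gene set {set_id!r} has no genes in the universe; skipped")
            continue
        a = len(module & genes)
        b = len(module) - a
        c = len(genes) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"set_id": set_id, "overlap": a, "set_size": len(genes), "p": float(p)}
        )
    out = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = []
    return out.set_index("set_id")


def ks_gsea(ranking: list[str], gene_set: set[str]) -> tuple[float, float]:
    """One-tail KS enrichment of a gene set toward the top of a ranking.

    The rank positions of set members (normalised to (0, 1]) are compared
    against the uniform distribution with the one-sided alternative that
    they are shifted toward the top (small positions). Returns
    (KS statistic, one-sided p).
    """
    members = gene_set & set(ranking)
    if not members:
        raise ValueError("gene set has no genes in the ranking")
    n = len(ranking)
    pos = np.array(
        [(i + 1) / n for i, g in enumerate(ranking) if g in members], dtype=float
    )
    # 'greater': empirical CDF above the uniform CDF, i.e. mass at the top
    res = stats.kstest(pos, stats.uniform.cdf, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def rank_module_edges(
    network: WeightedGeneNetwork,
    module: set[str],
    evidence: EvidenceTable,
    seeds: SeedSet | None = None,
) -> RankedEdgeList:
    """Rank module-internal edges by summed endpoint evidence counts.

    Edge score = evidence count of one endpoint plus the other's;
    descending score, ties broken by descending consensus weight, then by
    the lexicographic (gene_a, gene_b) pair. If ``seeds`` is given each
    edge also carries its partition label (seed_seed / seed_other / other).
    """
    e = network.edges
    inside = e[e["gene_a"].isin(module) & e["gene_b"].isin(module)].copy()
    inside["score"] = [
        evidence.count(a) + evidence.count(b)
        for a, b in inside[["gene_a", "gene_b"]].itertuples(index=False)
    ]
    order = np.lexsort(
        (
            inside["gene_b"].to_numpy(),
            inside["gene_a"].to_numpy(),
            -inside["weight"].to_numpy(float),
            -inside["score"].to_numpy(float),
        )
    )
    inside = inside.iloc[order].reset_index(drop=True)
    if seeds is not None:
        n_seed = inside["gene_a"].isin(seeds.genes).astype(int) + inside[
            "gene_b"
        ].isin(seeds.genes).astype(int)
        inside["partition"] = np.select(
            [n_seed == 2, n_seed == 1], ["seed_seed", "seed_other"], default="other"
        )
    else:
        inside["partition"] = "other"
    return RankedEdgeList(
        edges=inside[["gene_a", "gene_b", "score", "weight", "partition"]]
    )


def partition_edges(
    ranked: RankedEdgeList, seeds: SeedSet
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split ranked edges by seed membership of their endpoints.

    Returns (seed_seed, seed_other, other): both endpoints seeds / exactly
    one / neither. The three frames partition the input exhaustively.
    """
    e = ranked.edges
    n_seed = e["gene_a"].isin(seeds.genes).astype(int) + e["gene_b"].isin(
        seeds.genes
    ).astype(int)
    return (
        e[n_seed == 2].reset_index(drop=True),
        e[n_seed == 1].reset_index(drop=True),
        e[n_seed == 0].reset_index(drop=True),
    )
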