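"""Network gene ranks, evidence assembly and seed selection.

Combines two data-driven network criteria (differential centrality and
bridge genes) with the meta-analysis consensus and three prior-knowledge
gene lists into a per-gene evidence table; genes with at least
``min_evidence`` pieces of evidence become the seed set for module
expansion.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import EVIDENCE_SOURCES, EvidenceTable, SeedSet, WeightedGeneNetwork


def _rank_desc(values: pd.Series) -> pd.Series:
    """Rank 1 = largest value; ties get the average rank.

    Scores are rounded to 1e-9 first so that nodes tied by graph symmetry
    are not split by floating-point accumulation order.
    """
    return values.round(9).rank(ascending=False, method="average")


def centrality_median_rank(network: WeightedGeneNetwork) -> pd.Series:
    """Median of each node's betweenness, closeness and degree ranks.

    Rank 1 is the most central node per measure; ties take the average
    rank. Closeness uses the harmonic variant so disconnected graphs are
    handled per component without special-casing. Shortest paths are
    unweighted: consensus weights are ranks, not distances.
    """
    g = network.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(network.nodes)
    bet = pd.Series(nx.betweenness_centrality(g), index=nodes, dtype=float)
    clo = pd.Series(nx.harmonic_centrality(g), index=nodes, dtype=float)
    deg = pd.Series(dict(g.degree()), index=nodes, dtype=float)
    ranks = pd.concat(
        [_rank_desc(bet), _rank_desc(clo), _rank_desc(deg)], axis=1
    )
    return ranks.median(axis=1).rename("median_rank")


def differential_centrality(
    lesional_ranks: pd.Series, nonlesional_ranks: pd.Series
) -> pd.DataFrame:
    """|delta median rank| between the two networks, descending.

    Returns a DataFrame ordered by descending absolute difference (ties
    broken lexicographically) with columns delta and rank.
    """
    if set(lesional_ranks.index) != set(nonlesional_ranks.index):
        missing = set(lesional_ranks.index) ^ set(nonlesional_ranks.index)
        raise ValueError(f"gene universes differ: {sorted(missing)[:5]}")
    genes = sorted(lesional_ranks.index)
    delta = (lesional_ranks.loc[genes] - nonlesional_ranks.loc[genes]).abs()
    order = np.lexsort((np.array(genes), -delta.to_numpy(float)))
    out = pd.DataFrame({"delta": delta.to_numpy(float)[order]},
                       index=np.array(genes)[order])
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def bridge_genes(
    network: WeightedGeneNetwork,
    disease_genes: set[str],
    max_path_length: int = 1,
) -> set[str]:
    """Genes bridging pairs of known disease genes.

    With the default one-hop reading, a bridge is a non-disease gene
    adjacent to at least two distinct disease genes (a common neighbour of
    a disease-gene pair). ``max_path_length=2`` additionally admits
    interior nodes of shortest paths of length <= 2 between disease genes
    (equivalent to the same criterion on this graph; kept for the wider
    reading of 'connecting').
    """
    g = network.to_networkx()
    present = sorted(d for d in disease_genes if d in g)
    if len(present) < 2:
        warnings.warn("fewer than 2 disease genes in the network; no bridges")
        return set()
    bridges: set[str] = set()
    if max_path_length == 1:
        for node in g.nodes:
            if node in disease_genes:
                continue
            if len(set(g.neighbors(node)) & set(present)) >= 2:
                bridges.add(node)
    elif max_path_length == 2:
        for a, b in combinations(present, 2):
            common = set(g.neighbors(a)) & set(g.neighbors(b))
            bridges |= {c for c in common if c not in disease_genes}
    else:
        raise ValueError("max_path_length must be 1 or 2")
    return bridges


def build_evidence(
    meta_rank: pd.Series,
    diff_centrality_rank: pd.Series,
    bridge_set: set[str],
    gwas_set: set[str],
    disease_gene_set: set[str],
    drug_target_set: set[str],
    top_n: int = 1000,
) -> EvidenceTable:
    """Assemble the six-source evidence table.

    The two ranked data-driven sources grant evidence iff a gene sits in
    their top ``top_n``; the four set-valued sources grant evidence by
    membership. The universe is the union of the two rank indices and all
    sets.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    universe = sorted(
        set(meta_rank.index)
        | set(diff_centrality_rank.index)
        | bridge_set
        | gwas_set
        | disease_gene_set
        | drug_target_set
    )
    flags = pd.DataFrame(False, index=universe, columns=list(EVIDENCE_SOURCES))
    flags.loc[
        [g for g in universe if g in meta_rank.index and meta_rank[g] <= top_n],
        "meta_analysis",
    ] = True
    flags.loc[
        [
            g
            for g in universe
            if g in diff_centrality_rank.index and diff_centrality_rank[g] <= top_n
        ],
        "differential_centrality",
    ] = True
    flags.loc[sorted(bridge_set & set(universe)), "bridge"] = True
    flags.loc[sorted(gwas_set & set(universe)), "gwas"] = True
    flags.loc[sorted(disease_gene_set & set(universe)), "disease_gene"] = True
    flags.loc[sorted(drug_target_set & set(universe)), "drug_target"] = True
    flags["count"] = flags[list(EVIDENCE_SOURCES)].sum(axis=1)
    return EvidenceTable(table=flags)


def select_seeds(evidence: EvidenceTable, min_evidence: int = 3) -> SeedSet:
    """Genes with at least ``min_evidence`` pieces of evidence."""
    if not 1 <= min_evidence <= 6:
        raise ValueError("min_evidence must lie in 1..6")
    genes = set(evidence.table.index[evidence.table["count"] >= min_evidence])
    return SeedSet(genes=genes, min_evidence=min_evidence)
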