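"""Disease-module inference by differential DIAMOnD expansion.

DIAMOnD grows a module from a seed set by repeatedly adding the node whose
number of links to the current module is most statistically surprising
under a hypergeometric null (connectivity p-value). Running the identical
expansion on the lesional and the non-lesional consensus network and
keeping the genes significant only in the lesional one yields the
condition-specific disease module: seeds plus lesional-specific genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DiamondTrace, DiseaseModule, WeightedGeneNetwork


def diamond_pvalue(k: int, k_s: int, n_nodes: int, n_seeds: int) -> float:
    """Hypergeometric upper-tail connectivity p-value.

    A node with degree ``k`` and ``k_s`` links into the current ``n_seeds``
    module genes, in a graph of ``n_nodes`` nodes:
    p = sum_{i=k_s}^{k} C(s, i) C(N - s, k - i) / C(N, k).
    A degree-0 node gets p = 1.
    """
    if k == 0:
        return 1.0
    if not 0 <= k_s <= min(k, n_seeds):
        raise ValueError("k_s must lie in 0..min(k, n_seeds)")
    return float(stats.hypergeom.sf(k_s - 1, n_nodes, n_seeds, k))


def _adjacency(network: WeightedGeneNetwork):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.edges[["gene_a", "gene_b"]].itertuples(index=False))
    return g


def diamond_expand(
    network: WeightedGeneNetwork, seeds: set[str], n_iterations: int
) -> DiamondTrace:
    """Iterative DIAMOnD expansion on the binarised consensus network.

    At each iteration every non-module node adjacent to the module is
    scored with the connectivity p-value against the *current* module
    (seeds plus previously added genes); the node with the smallest p is
    added (ties: larger ``k_s``, then lexicographic gene id). Stops early,
    with ``exhausted`` set, if no connected candidate remains.

    Because the added node is the minimum over all scored candidates, its
    raw p-value is biased small; the trace therefore also records the
    number of candidates and the Bonferroni-corrected
    ``p_adj = min(1, p * n_candidates)``, which downstream significance
    filtering uses by default.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    g = _adjacency(network)
    module = set(s for s in seeds if s in g)
    if not module:
        raise ValueError("no seed gene is present in the network")
    n = g.number_of_nodes()
    degree = dict(g.degree())
    links = {
        node: sum(1 for nb in g.neighbors(node) if nb in module)
        for node in g.nodes
        if node not in module
    }

    rows = []
    exhausted = False
    for it in range(1, n_iterations + 1):
        s = len(module)
        best = None
        n_cand = 0
        for node in sorted(nd for nd, ks in links.items() if ks > 0):
            n_cand += 1
            p = diamond_pvalue(degree[node], links[node], n, s)
            key = (p, -links[node], node)
            if best is None or key < best[0]:
                best = (key, node, p)
        if best is None:
            exhausted = True
            break
        _, node, p = best
        rows.append(
            {
                "gene": node,
                "iteration": it,
                "p": p,
                "n_candidates": n_cand,
                "p_adj": min(1.0, p * n_cand),
            }
        )
        module.add(node)
        del links[node]
        for nb in g.neighbors(node):
            if nb in links:
                links[nb] += 1
    return DiamondTrace(
        rows=pd.DataFrame(
            rows, columns=["gene", "iteration", "p", "n_candidates", "p_adj"]
        ),
        exhausted=exhausted,
    )


def differential_module(
    lesional_trace: DiamondTrace,
    nonlesional_trace: DiamondTrace,
    seeds: set[str],
    alpha: float = 0.05,
    correction: str = "candidates",
) -> DiseaseModule:
    """Seeds plus genes significant in the lesional expansion only.

    A gene counts as significant in a network iff it appears in that
    network's trace with a p-value <= alpha; 'not significant in
    non-lesional' covers both absence from the trace and p > alpha.
    ``correction='candidates'`` (default) applies alpha to the
    candidate-corrected ``p_adj``, which controls the per-iteration error
    of the argmin selection; ``correction='none'`` uses the raw p.
    """
    if correction not in ("candidates", "none"):
        raise ValueError("correction must be 'candidates' or 'none'")
    column = "p_adj" if correction == "candidates" else "p"
    s_les = lesional_trace.significant(alpha, column=column)
    s_non = nonlesional_trace.significant(alpha, column=column)
    specific = sorted((s_les - s_non) - seeds)
    p_by_gene = dict(
        zip(lesional_trace.rows["gene"], lesional_trace.rows["p"])
    )
    members = pd.DataFrame(
        [{"gene": g, "provenance": "seed", "p": np.nan} for g in sorted(seeds)]
        + [
            {"gene": g, "provenance": "diamond_lesional_specific", "p": p_by_gene[g]}
            for g in specific
        ],
        columns=["gene", "provenance", "p"],
    )
    return DiseaseModule(members=members)
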