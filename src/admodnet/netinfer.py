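"""Ensemble co-expression network inference.

One association matrix is computed per estimator (three correlation
measures stored as absolute values, four discrete mutual-information
estimators on equal-frequency bins), each is post-processed by each of the
CLR, ARACNE and MRNET network algorithms, and the resulting matrices are
fused into a single consensus network by Borda rank aggregation over
edges. Edge-rank ties always break on the lexicographic (gene_a, gene_b)
pair so the consensus is reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AssociationMatrix, WeightedGeneNetwork

CORRELATION_ESTIMATORS = ("pearson", "spearman", "kendall")
MI_ESTIMATORS = ("mi_empirical", "mi_millermadow", "mi_shrink", "mi_sg")
ALL_ESTIMATORS = CORRELATION_ESTIMATORS + MI_ESTIMATORS
NETWORK_ALGORITHMS = ("clr", "aracne", "mrnet")


# ---------------------------------------------------------------- estimators

def _discretize_equalfreq(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning per gene (row); returns integer codes 0..b-1."""
    n = x.shape[1]
    order = np.argsort(x, axis=1, kind="stable")
    codes = np.empty_like(x, dtype=np.int64)
    bin_of_pos = (np.arange(n) * n_bins) // n
    np.put_along_axis(codes, order, bin_of_pos[None, :], axis=1)
    return codes


def _entropy_ml(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _entropy_millermadow(counts: np.ndarray) -> float:
    m = int((counts > 0).sum())
    n = counts.sum()
    return _entropy_ml(counts) + (m - 1) / (2.0 * n)


def _entropy_dirichlet(counts: np.ndarray, a: float) -> float:
    """Plug-in entropy of Dirichlet-smoothed cell probabilities,
    pseudocount ``a`` added to every cell (including empty ones)."""
    c = counts.astype(float) + a
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def _entropy_shrink(counts: np.ndarray) -> float:
    """James-Stein shrinkage of cell probabilities toward the uniform
    target, with the closed-form optimal intensity lambda."""
    n = counts.sum()
    p_ml = counts / n
    t = 1.0 / counts.size
    denom = (n - 1) * float(((p_ml - t) ** 2).sum())
    lam = 1.0 if denom == 0 else min(1.0, float((1.0 - (p_ml**2).sum()) / denom))
    p = lam * t + (1.0 - lam) * p_ml
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


_ENTROPIES = {
    "mi_empirical": _entropy_ml,
    "mi_millermadow": _entropy_millermadow,
    "mi_shrink": _entropy_shrink,
}


def mutual_information(
    joint: np.ndarray, estimator: str = "mi_empirical"
) -> float:
    """MI in nats from a joint contingency table, I = H(X) + H(Y) - H(X,Y),
    with each entropy term under the requested estimator."""
    if estimator == "mi_sg":
        # Schurmann-Grassberger: Dirichlet smoothing with pseudocount 1/m,
        # m = number of cells of the distribution being estimated.
        hx = _entropy_dirichlet(joint.sum(1), 1.0 / joint.shape[0])
        hy = _entropy_dirichlet(joint.sum(0), 1.0 / joint.shape[1])
        hxy = _entropy_dirichlet(joint.ravel(), 1.0 / joint.size)
    else:
        h = _ENTROPIES[estimator]
        hx, hy, hxy = h(joint.sum(1)), h(joint.sum(0)), h(joint.ravel())
    return max(0.0, hx + hy - hxy)


def association(
    expr: pd.DataFrame, estimator: str, n_bins: int | None = None
) -> AssociationMatrix:
    """Pairwise gene-gene association on a genes x samples matrix.

    Correlation estimators are stored as absolute values so that strong
    negative co-expression ranks as strong association; MI estimators work
    on equal-frequency discretised data with ``n_bins`` bins (default
    floor(sqrt(n_samples))). Constant genes get association 0 with every
    partner.
    """
    if estimator not in ALL_ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    x = expr.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    constant = x.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s); association set to 0")

    if estimator in CORRELATION_ESTIMATORS:
        if estimator == "kendall":
            m = np.eye(n_genes)
            for i in range(n_genes):
                for j in range(i + 1, n_genes):
                    if constant[i] or constant[j]:
                        tau = 0.0
                    else:
                        tau = stats.kendalltau(x[i], x[j]).statistic
                    m[i, j] = m[j, i] = 0.0 if np.isnan(tau) else tau
        else:
            xr = stats.rankdata(x, axis=1) if estimator == "spearman" else x
            with np.errstate(invalid="ignore"):
                m = np.corrcoef(xr)
            m[np.isnan(m)] = 0.0
        m = np.abs(m)
    else:
        b = n_bins or max(2, int(np.floor(np.sqrt(n_samples))))
        codes = _discretize_equalfreq(x, b)
        m = np.zeros((n_genes, n_genes))
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if constant[i] or constant[j]:
                    continue
                joint = np.bincount(
                    codes[i] * b + codes[j], minlength=b * b
                ).reshape(b, b)
                m[i, j] = m[j, i] = mutual_information(joint, estimator)
    np.fill_diagonal(m, 0.0)
    return AssociationMatrix(genes=list(expr.index), values=m, estimator=estimator)


# --------------------------------------------------------- network algorithms

def clr(mi: AssociationMatrix) -> AssociationMatrix:
    """Context Likelihood of Relatedness.

    z_ij = sqrt(max(0, zi)^2 + max(0, zj)^2) where zi is the z-score of
    mi_ij against the mean/sd of row i's off-diagonal entries (the gene's
    association background). Rows with zero sd contribute 0.
    """
    m = mi.values
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    mean = np.where(off, m, np.nan)
    sd = np.nanstd(mean, axis=1, keepdims=True)
    mean = np.nanmean(mean, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (m - mean) / sd, 0.0)
    z = np.maximum(z, 0.0)
    out = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(out, 0.0)
    return AssociationMatrix(mi.genes, out, f"clr({mi.estimator})")


def aracne(mi: AssociationMatrix, dpi_eps: float = 0.0) -> AssociationMatrix:
    """ARACNE Data Processing Inequality pruning.

    In every triangle (i, j, k) the edge (i, j) is removed iff
    mi_ij < min(mi_ik, mi_jk) - dpi_eps; survivors keep their weights.
    """
    if dpi_eps < 0:
        raise ValueError("dpi_eps must be >= 0")
    m = mi.values.copy()
    n = m.shape[0]
    # strongest indirect path through any k: max_k min(m_ik, m_kj)
    indirect = np.zeros_like(m)
    for k in range(n):
        col = m[:, k]
        pair_min = np.minimum(col[:, None], col[None, :])
        pair_min[:, k] = 0.0
        pair_min[k, :] = 0.0
        np.maximum(indirect, pair_min, out=indirect)
    keep = ~((m > 0) & (m < indirect - dpi_eps))
    out = np.where(keep, m, 0.0)
    np.fill_diagonal(out, 0.0)
    return AssociationMatrix(mi.genes, out, f"aracne({mi.estimator})")


def _mrmr_scores(m: np.ndarray, target: int) -> np.ndarray:
    """Greedy maximum-relevance-minimum-redundancy forward ranking of all
    predictors for one target; returns each predictor's score at the step
    it was selected."""
    n = m.shape[0]
    predictors = [i for i in range(n) if i != target]
    relevance = m[target].copy()
    red_sum = np.zeros(n)
    remaining = np.array(predictors)
    scores = np.full(n, -np.inf)
    k = 0
    while remaining.size:
        s = relevance[remaining] - (red_sum[remaining] / k if k else 0.0)
        best = int(remaining[np.argmax(s)])
        scores[best] = float(s.max())
        remaining = remaining[remaining != best]
        red_sum[remaining] += m[best, remaining]
        k += 1
    return scores


def mrnet(mi: AssociationMatrix) -> AssociationMatrix:
    """MRNET: w_ij = max(score of i for target j, score of j for target i),
    floored at 0, where scores come from greedy MRMR forward selection."""
    m = mi.values
    n = m.shape[0]
    s = np.zeros((n, n))
    for t in range(n):
        s[t] = _mrmr_scores(m, t)      # s[t, x] = score of predictor x for target t
    out = np.maximum(np.maximum(s, s.T), 0.0)
    np.fill_diagonal(out, 0.0)
    return AssociationMatrix(mi.genes, out, f"mrnet({mi.estimator})")


_ALGORITHMS = {"clr": clr, "aracne": aracne, "mrnet": mrnet}


def apply_algorithm(mi: AssociationMatrix, algorithm: str) -> AssociationMatrix:
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown network algorithm {algorithm!r}")
    return _ALGORITHMS[algorithm](mi)


# ----------------------------------------------------------------- consensus

def _edge_index(genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    return iu


def ensemble_consensus(
    matrices: list[AssociationMatrix], top_edges: int | None = None
) -> WeightedGeneNetwork:
    """Fuse an ensemble of association matrices into one consensus network.

    Each matrix ranks all gene pairs by descending score (ties broken by
    the lexicographic pair); the Borda score of an edge is its mean rank
    across matrices. The ``top_edges`` edges with the best (lowest) mean
    rank are kept; weight = 1 - normalised mean rank. The default edge
    budget targets mean node degree 20.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 matrices for a consensus")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValueError("all matrices must share the same gene set")
    n = len(genes)
    iu, ju = _edge_index(genes)
    n_pairs = len(iu)
    if top_edges is None:
        top_edges = min(n_pairs, n * 10)          # mean degree 20
    if top_edges > n_pairs:
        warnings.warn("top_edges exceeds the number of gene pairs; keeping all")
        top_edges = n_pairs

    # lexicographic pair order == (iu, ju) order since genes are sorted on
    # input from datamodel_io; ranks computed with stable sort on -score.
    mean_rank = np.zeros(n_pairs)
    for m in matrices:
        scores = m.values[iu, ju]
        order = np.argsort(-scores, kind="stable")
        ranks = np.empty(n_pairs)
        ranks[order] = np.arange(1, n_pairs + 1)
        mean_rank += ranks
    mean_rank /= len(matrices)

    final_order = np.lexsort((ju, iu, mean_rank))  # mean rank, then lex pair
    kept = final_order[:top_edges]
    weight = 1.0 - (mean_rank[kept] - 1.0) / max(1, n_pairs - 1)
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[kept]],
            "gene_b": [genes[j] for j in ju[kept]],
            "weight": weight,
            "rank": np.arange(1, top_edges + 1),
        }
    )
    return WeightedGeneNetwork(nodes=list(genes), edges=edges)


def infer_network(
    expr: pd.DataFrame,
    estimators: tuple[str, ...] = ALL_ESTIMATORS,
    algorithms: tuple[str, ...] = NETWORK_ALGORITHMS,
    top_edges: int | None = None,
    n_bins: int | None = None,
) -> WeightedGeneNetwork:
    """Full ensemble: every estimator x every network algorithm, fused by
    Borda consensus."""
    matrices = []
    for est in estimators:
        assoc = association(expr, est, n_bins=n_bins)
        for alg in algorithms:
            matrices.append(apply_algorithm(assoc, alg))
    return ensemble_consensus(matrices, top_edges=top_edges)


def walktrap_communities(
    network: WeightedGeneNetwork, walk_length: int = 4
) -> dict[str, int]:
    """Random-walk (walktrap) community detection on the consensus network,
    cut at maximum modularity. Returns gene -> community id."""
    import igraph

    nodes = list(network.nodes)
    if not nodes:
        return {}
    index = {g: i for i, g in enumerate(nodes)}
    edges = [
        (index[a], index[b])
        for a, b in network.edges[["gene_a", "gene_b"]].itertuples(index=False)
    ]
    g = igraph.Graph(n=len(nodes), edges=edges)
    weights = network.edges["weight"].tolist() if len(network.edges) else None
    dendro = g.community_walktrap(weights=weights, steps=walk_length)
    membership = dendro.as_clustering().membership
    return {gene: int(membership[i]) for gene, i in index.items()}
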