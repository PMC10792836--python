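"""Consensus disease-similarity and drug prioritisation.

Diseases are compared as gene sets via six measures (Jaccard, cosine,
Sorensen-Dice, overlap coefficient — inverted to distances by subtraction
from 1 — plus Euclidean and Hamming distances on binary membership
vectors, scaled to [0, 1] by their maximum). The six resulting
disease-disease distance matrices are themselves compared by the
Ipsen-Mikhailov spectral graph distance, clustered, and fused into one
consensus matrix by hierarchical averaging along the dendrogram. Diseases
are then ranked by consensus distance to the query disease, and
disease-drug-target triples whose target lies in the disease module are
prioritised by that ranking, the query disease always first.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster.hierarchy import linkage
from scipy.integrate import quad
from scipy.spatial.distance import squareform

from .datamodel import (
    DISTANCE_MEASURES,
    DiseaseGeneCatalog,
    DiseaseModule,
    DiseaseSimilarityEnsemble,
    DrugTargetTriple,
)


# ------------------------------------------------------------------ catalog

def filter_catalog(
    catalog: DiseaseGeneCatalog,
    min_genes: int = 5,
    merge_map: dict[str, str] | None = None,
) -> DiseaseGeneCatalog:
    """Merge synonym diseases into their canonical id and drop small ones.

    ``merge_map`` maps alias -> canonical disease id; gene sets are
    unioned. Diseases with fewer than ``min_genes`` genes are removed;
    removing the query disease is fatal.
    """
    merge_map = dict(merge_map or catalog.synonyms)
    merged: dict[str, set[str]] = {}
    for disease, genes in catalog.diseases.items():
        canonical = merge_map.get(disease, disease)
        merged.setdefault(canonical, set()).update(genes)
    kept = {d: g for d, g in merged.items() if len(g) >= min_genes}
    query = merge_map.get(catalog.query_disease_id, catalog.query_disease_id)
    if query not in kept:
        raise ValueError(
            f"query disease {query!r} removed by the min_genes={min_genes} filter"
        )
    return DiseaseGeneCatalog(diseases=kept, query_disease_id=query)


# ------------------------------------------------------- distance matrices

def similarity_matrices(catalog: DiseaseGeneCatalog) -> dict[str, pd.DataFrame]:
    """Six disease x disease distance matrices in [0, 1].

    Set-overlap similarities are inverted by 1 - s; Euclidean and Hamming
    distances on binary gene-membership vectors are scaled by their matrix
    maximum (an all-zero matrix if the maximum is 0).
    """
    diseases = sorted(catalog.diseases)
    if len(diseases) < 2:
        raise ValueError("need >= 2 diseases")
    union = sorted(set().union(*catalog.diseases.values()))
    idx = {g: i for i, g in enumerate(union)}
    b = np.zeros((len(diseases), len(union)), dtype=float)
    for r, d in enumerate(diseases):
        for g in catalog.diseases[d]:
            b[r, idx[g]] = 1.0

    inter = b @ b.T
    sizes = b.sum(axis=1)
    sa = sizes[:, None]
    sb = sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = inter / (sa + sb - inter)
        dice = 2 * inter / (sa + sb)
        overlap = inter / np.minimum(sa, sb)
        cos = inter / np.sqrt(sa * sb)
    ham = (sa + sb - 2 * inter)                   # count of differing genes
    euc = np.sqrt(ham)

    def scale(m):
        mx = m.max()
        return m / mx if mx > 0 else np.zeros_like(m)

    mats = {
        "jaccard": 1 - jac,
        "dice": 1 - dice,
        "overlap": 1 - overlap,
        "cosine": 1 - cos,
        "euclidean": scale(euc),
        "hamming": scale(ham),
    }
    out = {}
    for name in DISTANCE_MEASURES:
        m = np.nan_to_num(mats[name], nan=0.0)
        np.fill_diagonal(m, 0.0)
        out[name] = pd.DataFrame(m, index=diseases, columns=diseases)
    return out


# ------------------------------------------------- Ipsen-Mikhailov distance

def _laplacian_frequencies(adj: np.ndarray) -> np.ndarray:
    """omega_i = sqrt(lambda_i) over the non-trivial Laplacian spectrum."""
    deg = adj.sum(axis=1)
    lap = np.diag(deg) - adj
    eig = np.linalg.eigvalsh(lap)
    eig = np.clip(eig, 0.0, None)
    return np.sqrt(eig[1:])       # drop the structural zero eigenvalue


def _spectral_density(omegas: np.ndarray, gamma: float):
    """Normalised Lorentzian-smoothed spectral density on [0, inf)."""
    norm = float(np.sum(np.pi / 2 + np.arctan(omegas / gamma)))

    def rho(w: float) -> float:
        return float((gamma / ((w - omegas) ** 2 + gamma**2)).sum() / norm)

    return rho


def _im_distance_given_gamma(
    adj_a: np.ndarray, adj_b: np.ndarray, gamma: float
) -> float:
    wa = _laplacian_frequencies(adj_a)
    wb = _laplacian_frequencies(adj_b)
    ra = _spectral_density(wa, gamma)
    rb = _spectral_density(wb, gamma)
    upper = float(max(wa.max(initial=0.0), wb.max(initial=0.0)) + 100 * gamma)
    val, _ = quad(lambda w: (ra(w) - rb(w)) ** 2, 0.0, upper, limit=400)
    tail, _ = quad(lambda w: (ra(w) - rb(w)) ** 2, upper, np.inf, limit=200)
    return float(np.sqrt(val + tail))


@lru_cache(maxsize=None)
def calibrate_gamma(n: int) -> float:
    """Lorentzian width making distance(empty graph, complete graph) = 1
    for graphs on ``n`` nodes (the canonical IM normalisation)."""
    empty = np.zeros((n, n))
    complete = 1.0 - np.eye(n)

    def objective(gamma):
        return _im_distance_given_gamma(empty, complete, gamma) - 1.0

    return float(optimize.brentq(objective, 1e-3, 10.0, xtol=1e-12))


def ipsen_mikhailov(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    gamma: float | None = None,
    weights: str = "similarity",
) -> float:
    """Ipsen-Mikhailov spectral distance between two disease-distance
    matrices viewed as weighted graphs.

    With ``weights='similarity'`` (default) the adjacency is 1 - distance
    with zero diagonal; ``weights='distance'`` uses the distances directly
    as edge weights. gamma defaults to the per-n calibration that makes
    the empty-vs-complete distance exactly 1.
    """
    a = matrix_a.to_numpy(dtype=float)
    b = matrix_b.to_numpy(dtype=float)
    if a.shape != b.shape or list(matrix_a.index) != list(matrix_b.index):
        raise ValueError("matrices must share the same disease set")
    for m, name in ((a, "a"), (b, "b")):
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError(f"matrix {name} is not symmetric")
    if weights == "similarity":
        a, b = 1.0 - a, 1.0 - b
    elif weights != "distance":
        raise ValueError("weights must be 'similarity' or 'distance'")
    a, b = a.copy(), b.copy()
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(b, 0.0)
    if gamma is None:
        gamma = calibrate_gamma(a.shape[0])
    return _im_distance_given_gamma(a, b, gamma)


# ----------------------------------------------------- hierarchical fusion

def im_matrix(
    matrices: dict[str, pd.DataFrame], weights: str = "similarity"
) -> pd.DataFrame:
    """Pairwise IM distances between the six distance matrices."""
    names = [m for m in DISTANCE_MEASURES if m in matrices]
    gamma = calibrate_gamma(len(matrices[names[0]]))
    out = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = ipsen_mikhailov(
                matrices[names[i]], matrices[names[j]], gamma=gamma, weights=weights
            )
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=names, columns=names)


def hierarchical_consensus(
    matrices: dict[str, pd.DataFrame], im: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fuse the six distance matrices guided by their IM dendrogram.

    Average-linkage hierarchical clustering of the measures on their
    pairwise IM distances; the fusion walks the dendrogram bottom-up,
    replacing each merge by the elementwise mean of its two (already
    fused) children. The root is the consensus. Returns (consensus, im).
    """
    names = [m for m in DISTANCE_MEASURES if m in matrices]
    if im is None:
        im = im_matrix(matrices)
    condensed = squareform(im.loc[names, names].to_numpy(), checks=False)
    z = linkage(condensed, method="average")
    fused: dict[int, pd.DataFrame] = {i: matrices[n] for i, n in enumerate(names)}
    k = len(names)
    for step, (left, right, _, _) in enumerate(z):
        fused[k + step] = (fused[int(left)] + fused[int(right)]) / 2.0
    return fused[k + len(z) - 1], im


def rank_diseases(consensus: pd.DataFrame, query: str) -> pd.DataFrame:
    """Diseases ordered by ascending consensus distance to the query
    (ties lexicographic); the query itself is excluded."""
    if query not in consensus.index:
        raise ValueError(f"query disease {query!r} not in the consensus matrix")
    d = consensus.loc[query].drop(query)
    order = np.lexsort((d.index.to_numpy(), d.to_numpy(float)))
    out = pd.DataFrame(
        {"disease": d.index.to_numpy()[order], "distance": d.to_numpy(float)[order]}
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def build_ensemble(
    catalog: DiseaseGeneCatalog, weights: str = "similarity"
) -> DiseaseSimilarityEnsemble:
    """similarity_matrices -> IM matrix -> hierarchical consensus -> ranking."""
    mats = similarity_matrices(catalog)
    consensus, im = hierarchical_consensus(mats)
    ranking = rank_diseases(consensus, catalog.query_disease_id)
    return DiseaseSimilarityEnsemble(
        diseases=sorted(catalog.diseases),
        matrices=mats,
        im_matrix=im,
        consensus=consensus,
        ranking=ranking,
    )


# ----------------------------------------------------------- drug ranking

def prioritize_drugs(
    triples: list[DrugTargetTriple],
    disease_ranking: pd.DataFrame,
    module: DiseaseModule,
    query: str,
) -> pd.DataFrame:
    """Rank disease-drug-target triples restricted to module targets.

    Triples whose target is outside the disease module are dropped. The
    surviving triples are ordered by: the query disease first, then the
    disease's similarity rank ascending; within a disease, drugs with more
    module targets first, then lexicographic drug id, then target id.
    """
    module_genes = module.genes
    kept = [t for t in triples if t.target in module_genes]
    if not kept:
        warnings.warn("no triple targets a module gene; empty prioritisation")
        return pd.DataFrame(
            columns=["disease_id", "drug_id", "target", "source", "disease_rank", "rank"]
        )
    rank_of = dict(zip(disease_ranking["disease"], disease_ranking["rank"]))
    n_targets: dict[str, int] = {}
    for t in kept:
        n_targets[t.drug_id] = n_targets.get(t.drug_id, 0) + 1

    def disease_key(d: str) -> tuple:
        if d == query:
            return (0, 0)
        return (1, rank_of.get(d, np.inf))

    kept.sort(
        key=lambda t: (
            disease_key(t.disease_id),
            -n_targets[t.drug_id],
            t.drug_id,
            t.target,
        )
    )
    out = pd.DataFrame(
        [
            {
                "disease_id": t.disease_id,
                "drug_id": t.drug_id,
                "target": t.target,
                "source": t.source,
                "disease_rank": 0 if t.disease_id == query else rank_of.get(t.disease_id, np.nan),
            }
            for t in kept
        ]
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
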