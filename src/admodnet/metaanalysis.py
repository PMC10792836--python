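"""Per-study differential expression and three-branch consensus meta-analysis.

Each study contributes a two-sample comparison (lesional vs non-lesional):
a linear-model t statistic, Hedges' g with its sampling variance, and a
log2 fold change. Three meta-analytic branches — Fisher p-value
combination, DerSimonian-Laird random-effects effect pooling, and the
rank product — each yield a gene ranking, and the final consensus rank is
their Borda (mean-rank) merge.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionStudySet


# ------------------------------------------------------------ preprocessing

def batch_adjust(matrix: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Mean-adjust a combined genes x samples matrix for a batch variable.

    Per gene and batch: x' = x - batch mean + grand mean, so the per-gene
    grand mean is preserved. Singleton batches are warned about and left
    unchanged.
    """
    out = matrix.copy()
    grand = matrix.mean(axis=1)
    for batch in pd.unique(batches):
        cols = batches.index[batches == batch]
        if len(cols) < 2:
            warnings.warn(f"singleton batch {batch!r} left unadjusted")
            continue
        bm = matrix[cols].mean(axis=1)
        out[cols] = matrix[cols].sub(bm, axis=0).add(grand, axis=0)
    return out


# ------------------------------------------------------- per-study statistics

def study_de(expr: pd.DataFrame, conditions: pd.Series) -> pd.DataFrame:
    """Two-group DE statistics per gene.

    Returns a DataFrame indexed by gene with columns g (Hedges' g, with the
    small-sample correction J = 1 - 3/(4 df - 1)), var_g, t, p (two-sided),
    log2fc. Genes with zero pooled variance get t = 0, p = 1, g = 0 and are
    flagged in the ``degenerate`` column.
    """
    les = conditions.index[conditions == "lesional"]
    non = conditions.index[conditions == "nonlesional"]
    n1, n2 = len(les), len(non)
    if min(n1, n2) < 3:
        raise ValueError("need >= 3 samples per group")
    x1 = expr[list(les)].to_numpy(float)
    x2 = expr[list(non)].to_numpy(float)
    m1, m2 = x1.mean(1), x2.mean(1)
    v1, v2 = x1.var(1, ddof=1), x2.var(1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    degenerate = sp2 <= 0
    sp2_safe = np.where(degenerate, 1.0, sp2)

    se = np.sqrt(sp2_safe * (1 / n1 + 1 / n2))
    t = (m1 - m2) / se
    p = 2 * stats.t.sf(np.abs(t), df)
    d = (m1 - m2) / np.sqrt(sp2_safe)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var_g = j**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2 * df))

    t[degenerate] = 0.0
    p[degenerate] = 1.0
    g[degenerate] = 0.0
    var_g[degenerate] = np.nan
    return pd.DataFrame(
        {
            "g": g,
            "var_g": var_g,
            "t": t,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "log2fc": m1 - m2,
            "degenerate": degenerate,
        },
        index=expr.index,
    )


# ------------------------------------------------------------------ branches

def fisher_combine(pvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fisher's method across studies, vectorised over genes.

    ``pvalues`` is genes x studies; returns (X, combined p) with
    X = -2 sum(ln p) ~ chi2(2K) under the null.
    """
    p = np.asarray(pvalues, dtype=float)
    if (p <= 0).any():
        warnings.warn("p = 0 input clamped to the smallest positive normal")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum(axis=-1)
    k = p.shape[-1]
    return x, stats.chi2.sf(x, 2 * k)


def effect_combine(
    g: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DerSimonian-Laird random-effects pooling, vectorised over genes.

    tau2 = max(0, (Q - df) / C) with C = sum w - sum w^2 / sum w computed
    from the fixed-effect weights w = 1/v; final weights 1/(v + tau2).
    Returns (pooled g, z, two-sided p).
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    v = np.atleast_2d(np.asarray(variances, dtype=float))
    k = g.shape[1]
    if k < 2:
        raise ValueError("need >= 2 studies")
    w = 1.0 / v
    sw = w.sum(1)
    mu_fe = (w * g).sum(1) / sw
    q = (w * (g - mu_fe[:, None]) ** 2).sum(1)
    c = sw - (w**2).sum(1) / sw
    tau2 = np.maximum(0.0, (q - (k - 1)) / c)
    w_re = 1.0 / (v + tau2[:, None])
    mu = (w_re * g).sum(1) / w_re.sum(1)
    se = np.sqrt(1.0 / w_re.sum(1))
    z = mu / se
    p = 2 * stats.norm.sf(np.abs(z))
    return mu, z, np.clip(p, np.finfo(float).tiny, 1.0)


def rank_product(
    ranks: np.ndarray, n_perm: int = 200, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Rank product across studies with a within-study permutation p-value.

    ``ranks`` is genes x studies, each column a complete ranking 1..n.
    RP_g = (prod_k r_gk)^(1/K); the p-value is the fraction of permuted
    rank products (ranks shuffled independently within each study) at or
    below the observed one.
    """
    r = np.asarray(ranks, dtype=float)
    n, k = r.shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    log_rp = np.log(r).mean(axis=1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n)
    for _ in range(n_perm):
        perm = np.column_stack([rng.permutation(n) + 1 for _ in range(k)])
        null = np.log(perm).mean(axis=1)
        # each permutation contributes n null RPs; count fraction <= observed
        exceed += np.searchsorted(np.sort(null), log_rp, side="right")
    p = (exceed + 1) / (n_perm * n + 1)
    return np.exp(log_rp), p


def borda_merge(rank_lists: list[pd.Series]) -> pd.Series:
    """Borda (mean-rank) aggregation of rankings over one gene universe.

    Input Series map gene -> rank (1 = best). Output is the final rank per
    gene: ascending mean rank, ties broken lexicographically; a permutation
    of 1..n.
    """
    universe = sorted(rank_lists[0].index)
    for rl in rank_lists[1:]:
        if sorted(rl.index) != universe:
            missing = set(universe) ^ set(rl.index)
            raise ValueError(f"rank lists disagree on the gene universe: {sorted(missing)[:5]}")
    mean_rank = sum(rl.loc[universe].to_numpy(float) for rl in rank_lists) / len(
        rank_lists
    )
    order = np.lexsort((np.array(universe), mean_rank))
    final = np.empty(len(universe), dtype=int)
    final[order] = np.arange(1, len(universe) + 1)
    return pd.Series(final, index=universe, name="borda_rank")


def _competition_rank(values: np.ndarray, genes: list[str]) -> pd.Series:
    """Rank 1 = smallest value; ties broken by lexicographic gene id so the
    result is a permutation of 1..n."""
    order = np.lexsort((np.array(genes), np.asarray(values, float)))
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(1, len(genes) + 1)
    return pd.Series(ranks, index=genes)


# ----------------------------------------------------------------- top level

def consensus_meta_analysis(
    studyset: ExpressionStudySet,
    n_perm: int = 200,
    seed: int = 0,
    rank_product_mode: str = "best_of_both",
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the three-branch meta-analysis over all studies.

    Returns (consensus table, per-study DE results). The consensus table is
    indexed by gene with columns fisher_rank, effect_rank, rp_rank and the
    final borda_rank (each a permutation of 1..n).

    ``rank_product_mode``: 'best_of_both' ranks up- and down-regulation
    separately (by signed log2 fold change) and takes each gene's better
    rank product; 'single' uses one two-sided ranking by |log2fc|.
    """
    genes = list(studyset.genes)
    per_study: dict[str, pd.DataFrame] = {}
    for st in studyset.studies:
        per_study[st.study_id] = study_de(st.matrix, st.conditions)

    study_ids = sorted(per_study)
    pmat = np.column_stack([per_study[s]["p"].to_numpy() for s in study_ids])
    gmat = np.column_stack([per_study[s]["g"].to_numpy() for s in study_ids])
    vmat = np.column_stack(
        [per_study[s]["var_g"].fillna(1.0).to_numpy() for s in study_ids]
    )
    fc = np.column_stack([per_study[s]["log2fc"].to_numpy() for s in study_ids])

    _, fisher_p = fisher_combine(pmat)
    fisher_rank = _competition_rank(fisher_p, genes)

    _, _, effect_p = effect_combine(gmat, vmat)
    effect_rank = _competition_rank(effect_p, genes)

    if rank_product_mode == "best_of_both":
        up = np.column_stack(
            [stats.rankdata(-fc[:, k], method="ordinal") for k in range(fc.shape[1])]
        )
        down = np.column_stack(
            [stats.rankdata(fc[:, k], method="ordinal") for k in range(fc.shape[1])]
        )
        rp_up, p_up = rank_product(up, n_perm=n_perm, seed=seed)
        rp_down, p_down = rank_product(down, n_perm=n_perm, seed=seed + 1)
        rp_p = np.minimum(p_up, p_down)
    elif rank_product_mode == "single":
        r = np.column_stack(
            [
                stats.rankdata(-np.abs(fc[:, k]), method="ordinal")
                for k in range(fc.shape[1])
            ]
        )
        _, rp_p = rank_product(r, n_perm=n_perm, seed=seed)
    else:
        raise ValueError(f"unknown rank_product_mode {rank_product_mode!r}")
    rp_rank = _competition_rank(rp_p, genes)

    borda = borda_merge([fisher_rank, effect_rank, rp_rank])
    consensus = pd.DataFrame(
        {
            "fisher_rank": fisher_rank,
            "effect_rank": effect_rank,
            "rp_rank": rp_rank,
            "borda_rank": borda,
        }
    )
    return consensus, per_study
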