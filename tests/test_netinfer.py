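"""Association estimators, CLR/ARACNE/MRNET and the Borda consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admodnet import netinfer
from admodnet.datamodel import AssociationMatrix
from admodnet.netinfer import (
    aracne,
    association,
    clr,
    ensemble_consensus,
    mrnet,
    mutual_information,
    walktrap_communities,
)


def _assoc(values, genes=None):
    v = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(v.shape[0])]
    return AssociationMatrix(genes=genes, values=v, estimator="test")


# ------------------------------------------------------------- estimators

def test_perfect_correlation_and_abs_storage():
    x = np.arange(10.0)
    expr = pd.DataFrame([x, 3 * x + 1, -2 * x], index=["a", "b", "c"])
    for est in ("pearson", "spearman", "kendall"):
        m = association(expr, est)
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(1.0)   # negative stored as |r|


def test_independent_uniform_mi_small():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.uniform(size=(2, 1000)), index=["x", "y"])
    m = association(expr, "mi_empirical", n_bins=10)
    # plug-in MI bias is about (b-1)^2 / (2n) = 81/2000 nats
    assert m.values[0, 1] <= 0.1


def test_miller_madow_matches_direct_entropy_formula():
    """On a fixed 4-bin contingency table, the Miller-Madow MI equals the
    hand-assembled H_MM = H_ML + (m-1)/(2n) combination of entropy terms."""
    joint = np.array([[5, 1, 0, 0], [1, 6, 1, 0], [0, 1, 4, 2], [0, 0, 2, 7]])
    n = joint.sum()

    def h_ml(c):
        p = c[c > 0] / c.sum()
        return -(p * np.log(p)).sum()

    def h_mm(c):
        return h_ml(c) + ((c > 0).sum() - 1) / (2 * n)

    expected = h_mm(joint.sum(1)) + h_mm(joint.sum(0)) - h_mm(joint.ravel())
    assert mutual_information(joint, "mi_millermadow") == pytest.approx(expected)


def test_mi_estimators_nonnegative_and_symmetric():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.normal(size=(6, 40)), index=list("abcdef"))
    for est in netinfer.MI_ESTIMATORS:
        m = association(expr, est)
        assert (m.values >= 0).all()
        assert np.allclose(m.values, m.values.T)


def test_constant_gene_flagged_zero():
    expr = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["flat", "x"])
    with pytest.warns(UserWarning, match="constant"):
        m = association(expr, "pearson")
    assert m.values[0, 1] == 0.0


# ---------------------------------------------------------------------- clr

def test_clr_constant_matrix_is_zero():
    m = clr(_assoc(0.5 * (1 - np.eye(4))))
    assert np.allclose(m.values, 0.0)


def test_clr_direct_formula_ranks_strongest_edge_first():
    mi = _assoc([[0, 0.9, 0.1], [0.9, 0, 0.2], [0.1, 0.2, 0]])
    out = clr(mi)

    def z_row(row, j):
        r = np.delete(mi.values[row], row)       # off-diagonal background
        return max(0.0, (mi.values[row, j] - r.mean()) / r.std())

    for i, j in [(0, 1), (0, 2), (1, 2)]:
        expect = np.hypot(z_row(i, j), z_row(j, i))
        assert out.values[i, j] == pytest.approx(expect)
    assert out.values[0, 1] == out.values.max()


def test_clr_shift_invariance():
    rng = np.random.default_rng(2)
    v = rng.random((5, 5))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    a = clr(_assoc(v))
    shifted = v + 0.3
    np.fill_diagonal(shifted, 0)
    # shift applied off-diagonal only alters row stats; compare via raw rows
    b_vals = v + 0.3
    b = clr(AssociationMatrix(a.genes, (b_vals + b_vals.T) / 2, "t"))
    # z-scores are invariant to adding a constant to every entry of a row
    rows_a = (v - v.mean(1, keepdims=True)) / v.std(1, keepdims=True)
    rows_b = (b_vals - b_vals.mean(1, keepdims=True)) / b_vals.std(1, keepdims=True)
    assert np.allclose(rows_a, rows_b)


# ------------------------------------------------------------------- aracne

def test_aracne_triangle_weakest_removed():
    mi = _assoc([[0, 0.9, 0.1], [0.9, 0, 0.8], [0.1, 0.8, 0]])
    out = aracne(mi)
    assert out.values[0, 2] == 0.0
    assert out.values[0, 1] == pytest.approx(0.9)
    assert out.values[1, 2] == pytest.approx(0.8)


def test_aracne_path_without_triangle_unchanged():
    mi = _assoc([[0, 0.5, 0], [0.5, 0, 0.7], [0, 0.7, 0]])
    assert np.allclose(aracne(mi).values, mi.values)


def test_aracne_equal_triangle_kept():
    mi = _assoc(0.5 * (1 - np.eye(3)))
    assert np.allclose(aracne(mi).values, mi.values)


def test_aracne_edge_set_subset_and_dpi_exhaustive():
    """Every retained triangle satisfies the DPI condition; output edges
    are a subset of input edges (criterion on random matrices)."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        mi = _assoc(v)
        out = aracne(mi).values
        assert set(zip(*np.nonzero(out))) <= set(zip(*np.nonzero(v)))
        n = v.shape[0]
        for i, j in itertools.combinations(range(n), 2):
            removed_oracle = any(
                v[i, j] < min(v[i, k], v[j, k])
                for k in range(n)
                if k not in (i, j) and v[i, k] > 0 and v[j, k] > 0
            )
            assert (out[i, j] == 0.0) == (removed_oracle or v[i, j] == 0)


# -------------------------------------------------------------------- mrnet

def _mrmr_bruteforce(v, target):
    """Exhaustive MRMR forward selection for one target: at each step pick
    the argmax of relevance minus mean redundancy to already-selected."""
    n = v.shape[0]
    remaining = [i for i in range(n) if i != target]
    selected, scores = [], {}
    while remaining:
        best, best_s = None, -np.inf
        for x in remaining:
            red = np.mean([v[x, z] for z in selected]) if selected else 0.0
            s = v[target, x] - red
            if s > best_s:
                best, best_s = x, s
        scores[best] = best_s
        selected.append(best)
        remaining.remove(best)
    return scores


def test_mrnet_two_genes_equals_mi():
    mi = _assoc([[0, 0.4], [0.4, 0]])
    assert mrnet(mi).values[0, 1] == pytest.approx(0.4)


def test_mrnet_matches_bruteforce_on_small_instances():
    rng = np.random.default_rng(4)
    for n in (3, 4):
        for _ in range(10):
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            out = mrnet(_assoc(v)).values
            scores = {t: _mrmr_bruteforce(v, t) for t in range(n)}
            for i, j in itertools.combinations(range(n), 2):
                expect = max(0.0, scores[j][i], scores[i][j])
                assert out[i, j] == pytest.approx(expect)


def test_mrnet_output_symmetric_nonnegative():
    rng = np.random.default_rng(14)
    v = rng.random((6, 6))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    out = mrnet(_assoc(v)).values
    assert np.allclose(out, out.T)
    assert (out >= 0).all()


# ---------------------------------------------------------------- consensus

def test_consensus_identical_matrices_idempotent():
    rng = np.random.default_rng(5)
    v = rng.random((5, 5))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    m = _assoc(v)
    net = ensemble_consensus([m, m, m], top_edges=10)
    iu, ju = np.triu_indices(5, 1)
    scores = v[iu, ju]
    order = np.argsort(-scores, kind="stable")
    expected_first = (m.genes[iu[order[0]]], m.genes[ju[order[0]]])
    top = net.edges.iloc[0]
    assert (top["gene_a"], top["gene_b"]) == expected_first
    assert list(net.edges["rank"]) == list(range(1, 11))


def test_consensus_reversed_rankings_resolved_lexicographically():
    """Two matrices ranking 4 edges in exactly opposite order: all Borda
    mean ranks tie and the lexicographic pair decides."""
    genes = ["a", "b", "c"]   # pairs in lex order: (a,b), (a,c), (b,c)
    v1 = np.array([[0, 0.9, 0.6], [0.9, 0, 0.3], [0.6, 0.3, 0]])
    v2 = np.array([[0, 0.3, 0.6], [0.3, 0, 0.9], [0.6, 0.9, 0]])
    net = ensemble_consensus([_assoc(v1, genes), _assoc(v2, genes)], top_edges=3)
    assert list(zip(net.edges["gene_a"], net.edges["gene_b"])) == [
        ("a", "b"), ("a", "c"), ("b", "c")
    ]


def test_consensus_permutation_equivariance():
    """Renaming genes (and reordering rows to the new lexicographic order)
    permutes the consensus edge set identically — no hidden dependence on
    input identity beyond the documented lexicographic tie-break."""
    rng = np.random.default_rng(6)
    v = rng.random((6, 6))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    # second matrix = monotone transform of the first: same per-matrix
    # rankings, hence tie-free mean ranks (ties would fall back to the
    # label-dependent lexicographic rule, which is not equivariant)
    w = v**2
    genes = [f"g{i}" for i in range(6)]
    net = ensemble_consensus([_assoc(v, genes), _assoc(w, genes)], top_edges=8)

    rename = dict(zip(genes, ["x5", "x2", "x0", "x4", "x1", "x3"]))
    new_order = sorted(genes, key=lambda g: rename[g])
    idx = [genes.index(g) for g in new_order]
    pv, pw = v[np.ix_(idx, idx)], w[np.ix_(idx, idx)]
    new_names = [rename[g] for g in new_order]
    net_p = ensemble_consensus(
        [AssociationMatrix(new_names, pv, "t"), AssociationMatrix(new_names, pw, "t")],
        top_edges=8,
    )
    inv = {v2: k for k, v2 in rename.items()}
    mapped = {
        tuple(sorted((inv[a], inv[b]))) for a, b in net_p.edge_set()
    }
    assert mapped == net.edge_set()


def test_consensus_warns_when_top_edges_too_large():
    v = 0.5 * (1 - np.eye(3))
    with pytest.warns(UserWarning, match="top_edges"):
        net = ensemble_consensus([_assoc(v), _assoc(v)], top_edges=10)
    assert len(net.edges) == 3


def test_consensus_recovers_planted_module_edges():
    """At strong signal the top-|planted pairs| consensus edges are mostly
    within the planted module."""
    from admodnet.synthdata import generate_expression

    ss, truth = generate_expression(
        n_genes=80, n_studies=1, samples_per_condition=50, seed=9
    )
    mat, _ = ss.combined("lesional")
    mats = [association(mat, e) for e in ("pearson", "spearman", "mi_empirical")]
    k = len(truth.module_genes) * (len(truth.module_genes) - 1) // 2
    net = ensemble_consensus(mats, top_edges=k)
    mod = set(truth.module_genes)
    frac = (net.edges["gene_a"].isin(mod) & net.edges["gene_b"].isin(mod)).mean()
    assert frac >= 0.8


# ----------------------------------------------------------------- walktrap

def _clique_network(cliques, bridges=()):
    import pandas as pd

    edges = []
    for c in cliques:
        edges += [tuple(sorted(p)) for p in itertools.combinations(c, 2)]
    edges += [tuple(sorted(b)) for b in bridges]
    nodes = sorted({n for e in edges for n in e})
    df = pd.DataFrame(edges, columns=["gene_a", "gene_b"]).drop_duplicates()
    df = df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    df["weight"] = 1.0
    df["rank"] = np.arange(1, len(df) + 1)
    from admodnet.datamodel import WeightedGeneNetwork

    return WeightedGeneNetwork(nodes=nodes, edges=df)


def test_walktrap_separates_disconnected_cliques():
    c1 = [f"a{i}" for i in range(5)]
    c2 = [f"b{i}" for i in range(5)]
    comm = walktrap_communities(_clique_network([c1, c2]))
    assert len({comm[n] for n in c1}) == 1
    assert len({comm[n] for n in c2}) == 1
    assert comm[c1[0]] != comm[c2[0]]


def test_walktrap_ring_of_cliques():
    cliques = [[f"c{k}_{i}" for i in range(6)] for k in range(4)]
    bridges = [
        (cliques[k][0], cliques[(k + 1) % 4][1]) for k in range(4)
    ]
    comm = walktrap_communities(_clique_network(cliques, bridges))
    labels = [{comm[n] for n in c} for c in cliques]
    assert all(len(s) == 1 for s in labels)
    assert len({next(iter(s)) for s in labels}) == 4
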