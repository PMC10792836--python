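"""Shared domain types for the disease-module discovery pipeline.

All gene identifiers are opaque strings; lexicographic order over them is
the universal tie-break key so that every downstream result is reproducible
bit-for-bit for a fixed configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("lesional", "nonlesional")

EVIDENCE_SOURCES = (
    "meta_analysis",
    "differential_centrality",
    "bridge",
    "gwas",
    "disease_gene",
    "drug_target",
)


@dataclass
class Study:
    """One expression study: a genes x samples matrix plus per-sample labels."""

    study_id: str
    matrix: pd.DataFrame          # genes x samples, log2 scale
    conditions: pd.Series         # sample -> 'lesional' | 'nonlesional'
    batches: pd.Series            # sample -> batch label

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.matrix.columns if self.conditions[s] == condition]


@dataclass
class ExpressionStudySet:
    """Multi-study two-condition expression compendium on a common gene set."""

    genes: list[str]
    studies: list[Study]

    def __post_init__(self) -> None:
        for st in self.studies:
            if list(st.matrix.index) != list(self.genes):
                raise ValueError(
                    f"study {st.study_id!r} is not restricted to the common gene set"
                )
            if st.matrix.isna().any().any():
                raise ValueError(f"study {st.study_id!r} contains missing values")
            bad = set(st.conditions) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown condition labels {sorted(bad)}")

    def combined(self, condition: str | None = None) -> tuple[pd.DataFrame, pd.Series]:
        """Column-concatenate all studies; returns (matrix, batch labels).

        Sample columns are prefixed with the study id to stay unique.
        """
        mats, batches = [], []
        for st in self.studies:
            cols = st.matrix.columns if condition is None else st.samples(condition)
            m = st.matrix[list(cols)].copy()
            m.columns = [f"{st.study_id}:{c}" for c in cols]
            mats.append(m)
            batches.append(
                pd.Series([st.batches[c] for c in cols], index=m.columns)
            )
        mat = pd.concat(mats, axis=1)
        return mat, pd.concat(batches)


@dataclass
class AssociationMatrix:
    """Symmetric gene-gene association scores from one estimator."""

    genes: list[str]
    values: np.ndarray            # (n, n) symmetric, zero diagonal
    estimator: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genes), len(self.genes)):
            raise ValueError("matrix shape does not match gene list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v


@dataclass
class WeightedGeneNetwork:
    """Consensus co-expression network: edges carry weight in [0,1] and a rank.

    Ranks are a permutation of 1..|E|; lower rank = stronger consensus.
    """

    nodes: list[str]
    edges: pd.DataFrame           # columns: gene_a, gene_b, weight, rank

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["gene_a"] >= e["gene_b"]).any():
                raise ValueError("edges must be stored with gene_a < gene_b")
            ranks = np.sort(e["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(1, len(e) + 1)):
                raise ValueError("ranks must be a permutation of 1..|E|")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, w, r in self.edges[["gene_a", "gene_b", "weight", "rank"]].itertuples(
            index=False
        ):
            g.add_edge(a, b, weight=float(w), rank=int(r))
        return g

    def edge_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.edges[["gene_a", "gene_b"]].to_numpy()))


@dataclass
class EvidenceTable:
    """Per-gene flags over the six evidence sources and their count."""

    table: pd.DataFrame           # index: gene; columns: six flags + 'count'

    def __post_init__(self) -> None:
        missing = [c for c in EVIDENCE_SOURCES if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing evidence columns: {missing}")
        counts = self.table[list(EVIDENCE_SOURCES)].sum(axis=1)
        if "count" not in self.table.columns:
            self.table["count"] = counts
        elif not (self.table["count"] == counts).all():
            raise ValueError("count column inconsistent with flags")

    def count(self, gene: str) -> int:
        return int(self.table.loc[gene, "count"]) if gene in self.table.index else 0


@dataclass
class SeedSet:
    """Genes with at least ``min_evidence`` pieces of evidence."""

    genes: set[str]
    min_evidence: int = 3

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty seed set: the disease module is undefined")


@dataclass
class DiamondTrace:
    """Ordered record of the module-expansion iterations.

    Each row: (gene, iteration, p) — the connectivity p-value the gene had
    when it was added — plus the number of candidates scored at that
    iteration and the candidate-corrected p-value ``p_adj`` (the added
    node is the argmin over all scored candidates, so its raw p is biased
    small; ``p_adj = min(1, p * n_candidates)`` restores a per-iteration
    error rate). ``exhausted`` is set when the graph ran out of connected
    candidates before the requested number of iterations.
    """

    rows: pd.DataFrame            # columns: gene, iteration, p, n_candidates, p_adj
    exhausted: bool = False

    def __post_init__(self) -> None:
        r = self.rows
        if len(r):
            if r["gene"].duplicated().any():
                raise ValueError("trace genes must be unique")
            it = r["iteration"].to_numpy()
            if not np.array_equal(it, np.arange(1, len(r) + 1)):
                raise ValueError("iteration indices must run 1..k")

    def significant(self, alpha: float, column: str = "p_adj") -> set[str]:
        col = column if column in self.rows.columns else "p"
        return set(self.rows.loc[self.rows[col] <= alpha, "gene"])


@dataclass
class DiseaseModule:
    """Seed genes plus genes specific to the lesional-network expansion."""

    members: pd.DataFrame         # columns: gene, provenance, p (NaN for seeds)

    def __post_init__(self) -> None:
        prov = set(self.members["provenance"])
        if not prov <= {"seed", "diamond_lesional_specific"}:
            raise ValueError(f"unknown provenance labels: {prov}")
        if self.members["gene"].duplicated().any():
            raise ValueError("module genes must be unique")

    @property
    def genes(self) -> set[str]:
        return set(self.members["gene"])

    @property
    def seeds(self) -> set[str]:
        return set(self.members.loc[self.members["provenance"] == "seed", "gene"])

    @property
    def diamond_genes(self) -> set[str]:
        m = self.members
        return set(m.loc[m["provenance"] == "diamond_lesional_specific", "gene"])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. cell-type signatures or pathways)."""

    sets: dict[str, set[str]]
    category: str = "pathway"     # 'cell_type' | 'pathway'
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class RankedEdgeList:
    """Module-internal edges ranked by summed endpoint evidence."""

    edges: pd.DataFrame           # columns: gene_a, gene_b, score, weight, partition


@dataclass
class DiseaseGeneCatalog:
    """disease_id -> associated gene set, with a designated query disease."""

    diseases: dict[str, set[str]]
    query_disease_id: str
    synonyms: dict[str, str] = field(default_factory=dict)  # alias -> canonical

    def __post_init__(self) -> None:
        if self.query_disease_id not in self.diseases and not any(
            self.synonyms.get(d) == self.query_disease_id for d in self.diseases
        ):
            raise ValueError(
                f"query disease {self.query_disease_id!r} absent from catalog"
            )


DISTANCE_MEASURES = ("jaccard", "cosine", "dice", "overlap", "euclidean", "hamming")


@dataclass
class DiseaseSimilarityEnsemble:
    """Six disease-disease distance matrices, their spectral meta-distance,
    the fused consensus and the ranking relative to the query disease."""

    diseases: list[str]
    matrices: dict[str, pd.DataFrame]      # measure -> disease x disease distance
    im_matrix: pd.DataFrame                # 6 x 6 Ipsen-Mikhailov distances
    consensus: pd.DataFrame
    ranking: pd.DataFrame                  # columns: disease, distance, rank


@dataclass
class DrugTargetTriple:
    disease_id: str
    drug_id: str
    target: str
    source: str

    def __post_init__(self) -> None:
        if not (self.disease_id and self.drug_id and self.target):
            raise ValueError("triple identifiers must be non-empty")
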