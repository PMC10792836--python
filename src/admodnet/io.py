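"""Readers and writers for the plain-text formats the pipeline exchanges.

Every reader rejects malformed input with an error naming the offending
location; every writer produces files its paired reader parses back to an
equal value. Gene order is canonicalised lexicographically on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITIONS,
    DiseaseGeneCatalog,
    DrugTargetTriple,
    ExpressionStudySet,
    GeneSetCollection,
    Study,
    WeightedGeneNetwork,
)


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionStudySet:
    """Read a genes x samples TSV plus a sample-metadata TSV.

    The metadata maps each sample column to (study_id, condition, batch).
    Studies are restricted to their common gene set and genes are ordered
    lexicographically.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "study_id", "condition", "batch"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")

    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    if mat.isna().any().any():
        rows = mat.index[mat.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in expression matrix (genes {rows[:5]})")

    studies = []
    study_ids = sorted(set(meta.loc[list(mat.columns), "study_id"]))
    # common gene set: here a single matrix, but drop genes with any NA per
    # study has already been excluded above; intersection is the full index.
    genes = sorted(str(g) for g in mat.index)
    mat = mat.loc[genes]
    for sid in study_ids:
        cols = [s for s in mat.columns if meta.loc[s, "study_id"] == sid]
        studies.append(
            Study(
                study_id=sid,
                matrix=mat[cols],
                conditions=meta.loc[cols, "condition"],
                batches=meta.loc[cols, "batch"],
            )
        )
    return ExpressionStudySet(genes=genes, studies=studies)


def combine_study_sets(sets: list[ExpressionStudySet]) -> ExpressionStudySet:
    """Merge study sets, restricting to the genes common to all of them."""
    common: set[str] = set(sets[0].genes)
    for s in sets[1:]:
        common &= set(s.genes)
    genes = sorted(common)
    studies = []
    for s in sets:
        for st in s.studies:
            studies.append(
                Study(st.study_id, st.matrix.loc[genes], st.conditions, st.batches)
            )
    return ExpressionStudySet(genes=genes, studies=studies)


def write_expression(
    studyset: ExpressionStudySet, path: str | Path, metadata_path: str | Path
) -> None:
    mat, _ = studyset.combined()
    rows = []
    for st in studyset.studies:
        for s in st.matrix.columns:
            rows.append(
                {
                    "sample_id": f"{st.study_id}:{s}",
                    "study_id": st.study_id,
                    "condition": st.conditions[s],
                    "batch": st.batches[s],
                }
            )
    mat.to_csv(path, sep="\t", float_format="%.10g")
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def read_gmt(path: str | Path, category: str = "pathway") -> GeneSetCollection:
    """Parse a standard GMT file: set_id <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            set_id, desc, genes = fields[0], fields[1], fields[2:]
            sets[set_id] = set(g for g in genes if g)
            descriptions[set_id] = desc
    return GeneSetCollection(sets=sets, category=category, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection.sets):
            desc = collection.descriptions.get(set_id, "")
            genes = "\t".join(sorted(collection.sets[set_id]))
            fh.write(f"{set_id}\t{desc}\t{genes}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_network(path: str | Path) -> WeightedGeneNetwork:
    """Edge-list TSV: gene_a, gene_b, weight, rank (+ node list header row
    is not stored; nodes = union of endpoints plus an optional sidecar)."""
    e = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "weight", "rank"}
    if not required <= set(e.columns):
        raise ValueError(f"network TSV must have columns {sorted(required)}")
    nodes_path = Path(path).with_suffix(".nodes.txt")
    if nodes_path.exists():
        nodes = sorted(read_gene_list(nodes_path))
    else:
        nodes = sorted(set(e["gene_a"]) | set(e["gene_b"]))
    return WeightedGeneNetwork(nodes=nodes, edges=e)


def write_network(net: WeightedGeneNetwork, path: str | Path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    write_gene_list(set(net.nodes), Path(path).with_suffix(".nodes.txt"))


def read_disease_catalog(
    path: str | Path, query_disease_id: str, synonyms: dict[str, str] | None = None
) -> DiseaseGeneCatalog:
    """TSV with columns disease_id, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"disease_id", "gene"} <= set(df.columns):
        raise ValueError("disease catalog TSV must have columns disease_id, gene")
    diseases: dict[str, set[str]] = {}
    for d, g in df[["disease_id", "gene"]].itertuples(index=False):
        diseases.setdefault(d, set()).add(g)
    return DiseaseGeneCatalog(
        diseases=diseases,
        query_disease_id=query_disease_id,
        synonyms=synonyms or {},
    )


def write_disease_catalog(catalog: DiseaseGeneCatalog, path: str | Path) -> None:
    rows = [
        {"disease_id": d, "gene": g}
        for d in sorted(catalog.diseases)
        for g in sorted(catalog.diseases[d])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_triples(path: str | Path) -> list[DrugTargetTriple]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"disease_id", "drug_id", "target", "source"}
    if not required <= set(df.columns):
        raise ValueError(f"triples TSV must have columns {sorted(required)}")
    return [
        DrugTargetTriple(r.disease_id, r.drug_id, r.target, r.source)
        for r in df.itertuples(index=False)
    ]


def write_triples(triples: list[DrugTargetTriple], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "disease_id": t.disease_id,
                "drug_id": t.drug_id,
                "target": t.target,
                "source": t.source,
            }
            for t in triples
        ],
        columns=["disease_id", "drug_id", "target", "source"],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
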