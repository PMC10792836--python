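"""Synthetic multi-study expression data and knowledge bases with planted truth.

The generator emulates the statistical structure the pipeline assumes in
real compendia: several studies of lesional and non-lesional samples on a
shared gene set, per-study additive batch shifts, a planted gene module
that is co-expressed only in the lesional condition, differential
expression on the planted genes, and prior-knowledge tables (GWAS hits,
disease genes, drug targets, a disease-gene catalog and
disease-drug-target triples) with controlled overlap with the module.

Co-expression is induced by a single-factor Gaussian model
``x = lambda * f + eps`` with ``eps ~ N(0, 1)``: the expected pairwise
correlation of two module genes is ``lambda^2 / (lambda^2 + 1)``, so the
loading that yields a target correlation rho is
``lambda = sqrt(rho / (1 - rho))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import DiseaseGeneCatalog, DrugTargetTriple, ExpressionStudySet, Study

QUERY_DISEASE = "D_QUERY"


@dataclass
class TruthParams:
    """Knobs of the planted structure. Defaults are the study conditions."""

    module_size: int = 20
    n_core: int = 10              # knowledge-core genes shared by all prior sources
    rho_in: float = 0.8           # within-module correlation, lesional
    rho_out: float = 0.0          # within-module correlation, non-lesional
    effect_size: float = 1.0      # standardised lesional shift of module genes
    batch_sd: float = 0.5         # sd of per-study per-gene mean shifts

    def __post_init__(self) -> None:
        if not (0 <= self.rho_out < 1 and 0 <= self.rho_in < 1):
            raise ValueError("correlations must lie in [0, 1)")
        if self.rho_in < self.rho_out:
            raise ValueError("rho_in must be >= rho_out")
        if self.n_core > self.module_size:
            raise ValueError("knowledge core cannot exceed the module")


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside every generated dataset."""

    module_genes: list[str]
    core_genes: list[str]                       # designated seed-knowledge genes
    knowledge: dict[str, list[str]] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    rho_in: float = 0.8
    rho_out: float = 0.0
    batch_sd: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _loading(rho: float) -> float:
    return float(np.sqrt(rho / (1.0 - rho)))


def generate_expression(
    n_genes: int = 200,
    n_studies: int = 2,
    samples_per_condition: int = 25,
    truth_params: TruthParams | None = None,
    seed: int = 0,
) -> tuple[ExpressionStudySet, SyntheticTruth]:
    """Simulate a multi-study two-condition compendium with a planted
    differentially co-expressed module.

    ``samples_per_condition`` is per study; the compendium therefore holds
    ``n_studies * samples_per_condition`` samples of each condition.
    """
    tp = truth_params or TruthParams()
    if samples_per_condition < 3:
        raise ValueError("need >= 3 samples per condition for DE statistics")
    if n_genes < tp.module_size:
        raise ValueError("gene universe smaller than the planted module")
    rng = np.random.default_rng(seed)

    width = len(str(n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    module = sorted(rng.choice(genes, size=tp.module_size, replace=False).tolist())
    core = sorted(rng.choice(module, size=tp.n_core, replace=False).tolist())
    module_idx = np.array([genes.index(g) for g in module])

    lam = {"lesional": _loading(tp.rho_in), "nonlesional": _loading(tp.rho_out)}
    effects = {g: tp.effect_size for g in module}

    studies = []
    for s in range(n_studies):
        sid = f"S{s}"
        batch_shift = rng.normal(0.0, tp.batch_sd, size=n_genes)
        cols, labels, blocks = [], [], []
        for cond in ("lesional", "nonlesional"):
            n = samples_per_condition
            factor = rng.normal(size=n)                      # shared latent factor
            x = rng.normal(size=(n_genes, n))                # eps ~ N(0, 1)
            x[module_idx] += lam[cond] * factor[None, :]
            if cond == "lesional":
                x[module_idx] += tp.effect_size
            x += batch_shift[:, None]
            blocks.append(x)
            cols += [f"{cond[:3]}{j}" for j in range(n)]
            labels += [cond] * n
        mat = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
        studies.append(
            Study(
                study_id=sid,
                matrix=mat,
                conditions=pd.Series(labels, index=cols),
                batches=pd.Series([sid] * len(cols), index=cols),
            )
        )

    truth = SyntheticTruth(
        module_genes=module,
        core_genes=core,
        effect_sizes=effects,
        rho_in=tp.rho_in,
        rho_out=tp.rho_out,
        batch_sd=tp.batch_sd,
        seed=seed,
    )
    return ExpressionStudySet(genes=genes, studies=studies), truth


def generate_knowledge(
    truth: SyntheticTruth,
    gene_universe: list[str],
    overlap_fracs: dict[str, float] | None = None,
    n_decoys: int = 30,
    n_diseases: int = 12,
    n_drugs: int = 8,
    seed: int = 0,
) -> tuple[set[str], set[str], set[str], DiseaseGeneCatalog, list[DrugTargetTriple]]:
    """Build prior-knowledge tables with controlled overlap with the module.

    Each of the three prior sources (GWAS hits, disease genes, drug targets)
    contains the designated knowledge-core genes, extra planted genes up to
    ``overlap_frac * module_size``, and ``n_decoys`` decoy genes drawn
    uniformly from outside the module. The disease-gene catalog holds the
    query disease (gene set = the core plus decoys) and decoy diseases at a
    graded similarity to it; triples link diseases to drugs and to module /
    non-module targets.
    """
    rng = np.random.default_rng(seed)
    fracs = {"gwas": 0.5, "disease_gene": 0.5, "drug_target": 0.5}
    if overlap_fracs:
        fracs.update(overlap_fracs)
    module = list(truth.module_genes)
    core = list(truth.core_genes)
    non_module = sorted(set(gene_universe) - set(module))

    sources: dict[str, set[str]] = {}
    for name in ("gwas", "disease_gene", "drug_target"):
        n_planted = int(round(fracs[name] * len(module)))
        extra_needed = max(0, n_planted - len(core))
        pool = sorted(set(module) - set(core))
        extra = (
            rng.choice(pool, size=min(extra_needed, len(pool)), replace=False).tolist()
            if extra_needed
            else []
        )
        planted = (core + extra)[:n_planted] if n_planted >= len(core) else core[:n_planted]
        decoys = (
            rng.choice(non_module, size=min(n_decoys, len(non_module)), replace=False)
            .tolist()
            if n_decoys
            else []
        )
        sources[name] = set(planted) | set(decoys)

    # --- disease-gene catalog: query + diseases at graded Jaccard similarity
    query_genes = set(core) | set(
        rng.choice(non_module, size=min(10, len(non_module)), replace=False).tolist()
    )
    diseases: dict[str, set[str]] = {QUERY_DISEASE: query_genes}
    q = sorted(query_genes)
    for d in range(n_diseases):
        share = 1.0 - (d + 1) / (n_diseases + 1)  # graded similarity ladder
        n_shared = int(round(share * len(q)))
        shared = q[:n_shared]
        others = rng.choice(
            non_module, size=max(5, len(q)) - n_shared + 2, replace=False
        ).tolist()
        diseases[f"D{d:03d}"] = set(shared) | set(others)
    catalog = DiseaseGeneCatalog(diseases=diseases, query_disease_id=QUERY_DISEASE)

    # --- disease-drug-target triples, mixing module and non-module targets
    disease_ids = sorted(diseases)
    triples: list[DrugTargetTriple] = []
    for k in range(n_drugs):
        drug = f"DRUG{k:02d}"
        disease = disease_ids[k % len(disease_ids)]
        n_t = int(rng.integers(1, 4))
        targets = rng.choice(module, size=n_t, replace=False).tolist()
        off = rng.choice(non_module, size=1).tolist()
        for t in targets + off:
            triples.append(DrugTargetTriple(disease, drug, t, "synthetic"))
    # guarantee the query disease has at least one module-target drug
    triples.append(DrugTargetTriple(QUERY_DISEASE, "DRUG_Q", module[0], "synthetic"))

    truth.knowledge = {k: sorted(v) for k, v in sources.items()}
    return (
        sources["gwas"],
        sources["disease_gene"],
        sources["drug_target"],
        catalog,
        triples,
    )
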