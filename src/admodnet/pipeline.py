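"""End-to-end orchestration: simulate -> networks -> meta-analysis ->
evidence -> differential module -> characterisation -> drugs.

Every stage writes its inputs and outputs under the run directory in the
plain-text formats of :mod:`admodnet.io`, and a provenance block (config
hash, global seed, per-stage child seeds) is stored with the results so a
run is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import charmod, diseasemodule, generank, io, metaanalysis, netinfer, synthdata
from . import druggability
from .config import config_hash, derive_seed, load_config, validate_config
from .datamodel import GeneSetCollection


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict | None = None, seed: int = 0, out_dir: str | Path = "run") -> Path:
    """Run the full synthetic-to-drugs pipeline; returns the run directory."""
    cfg = validate_config(config or {}) if config is not None else load_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ----------------------------------------------------------- simulate
        stage = "simulate"
        sd = cfg["synthdata"]
        tp = synthdata.TruthParams(
            module_size=sd["module_size"],
            n_core=sd["n_core"],
            rho_in=sd["rho_in"],
            rho_out=sd["rho_out"],
            effect_size=sd["effect_size"],
            batch_sd=sd["batch_sd"],
        )
        studyset, truth = synthdata.generate_expression(
            n_genes=sd["n_genes"],
            n_studies=sd["n_studies"],
            samples_per_condition=sd["samples_per_condition"],
            truth_params=tp,
            seed=derive_seed(seed, "simulate"),
        )
        gwas, dgenes, dtargets, catalog, triples = synthdata.generate_knowledge(
            truth,
            studyset.genes,
            overlap_fracs=sd["overlap_fracs"],
            n_decoys=sd["n_decoys"],
            n_diseases=sd["n_diseases"],
            n_drugs=sd["n_drugs"],
            seed=derive_seed(seed, "knowledge"),
        )
        io.write_expression(studyset, out / "expression.tsv", out / "samples.tsv")
        io.write_gene_list(gwas, out / "gwas.txt")
        io.write_gene_list(dgenes, out / "disease_genes.txt")
        io.write_gene_list(dtargets, out / "drug_targets.txt")
        io.write_disease_catalog(catalog, out / "disease_catalog.tsv")
        io.write_triples(triples, out / "triples.tsv")
        io.write_json(truth.to_dict(), out / "truth.json")

        # ------------------------------------------- batch adjust + networks
        stage = "infer-network"
        ni = cfg["netinfer"]
        networks = {}
        for condition in ("lesional", "nonlesional"):
            mat, batches = studyset.combined(condition)
            adj = metaanalysis.batch_adjust(mat, batches)
            net = netinfer.infer_network(
                adj,
                estimators=tuple(ni["estimators"]),
                algorithms=tuple(ni["algorithms"]),
                top_edges=ni["top_edges"],
                n_bins=ni["n_bins"],
            )
            networks[condition] = net
            io.write_network(net, out / f"network_{condition}.tsv")

        # --------------------------------------------------------- meta-analyze
        stage = "meta-analyze"
        ma = cfg["metaanalysis"]
        consensus, per_study = metaanalysis.consensus_meta_analysis(
            studyset,
            n_perm=ma["n_perm"],
            seed=derive_seed(seed, "meta"),
            rank_product_mode=ma["rank_product_mode"],
        )
        consensus.to_csv(out / "meta_consensus.tsv", sep="\t")
        for sid, de in per_study.items():
            de.to_csv(out / f"de_{sid}.tsv", sep="\t", float_format="%.10g")

        # ----------------------------------------------------------- rank-genes
        stage = "rank-genes"
        gr = cfg["generank"]
        med = {
            c: generank.centrality_median_rank(networks[c])
            for c in ("lesional", "nonlesional")
        }
        diff = generank.differential_centrality(med["lesional"], med["nonlesional"])
        bridges = set()
        for c in ("lesional", "nonlesional"):
            bridges |= generank.bridge_genes(
                networks[c], dgenes, max_path_length=gr["bridge_max_path_length"]
            )
        evidence = generank.build_evidence(
            meta_rank=consensus["borda_rank"],
            diff_centrality_rank=diff["rank"],
            bridge_set=bridges,
            gwas_set=gwas,
            disease_gene_set=dgenes,
            drug_target_set=dtargets,
            top_n=gr["top_n"],
        )
        evidence.table.to_csv(out / "evidence.tsv", sep="\t")
        seeds = generank.select_seeds(evidence, min_evidence=gr["min_evidence"])
        io.write_gene_list(seeds.genes, out / "seeds.txt")

        # --------------------------------------------------------------- module
        stage = "module"
        dm = cfg["diseasemodule"]
        n_iter = dm["n_iterations"] or 2 * len(seeds.genes)
        traces = {
            c: diseasemodule.diamond_expand(networks[c], seeds.genes, n_iter)
            for c in ("lesional", "nonlesional")
        }
        for c, tr in traces.items():
            tr.rows.to_csv(out / f"diamond_{c}.tsv", sep="\t", index=False,
                           float_format="%.10g")
        module = diseasemodule.differential_module(
            traces["lesional"],
            traces["nonlesional"],
            seeds.genes,
            alpha=dm["alpha"],
            correction=dm["correction"],
        )
        module.members.to_csv(out / "module.tsv", sep="\t", index=False,
                              float_format="%.10g")

        # --------------------------------------------------------- characterize
        stage = "characterize"
        truth_sets = GeneSetCollection(
            sets={"planted_module": set(truth.module_genes)}, category="pathway"
        )
        enrich = charmod.overrepresentation(
            module.genes, truth_sets, set(studyset.genes)
        )
        enrich.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.10g")
        ranked_edges = charmod.rank_module_edges(
            networks["lesional"], module.genes, evidence, seeds=seeds
        )
        ranked_edges.edges.to_csv(out / "ranked_edges.tsv", sep="\t", index=False,
                                  float_format="%.10g")

        # ---------------------------------------------------------------- drugs
        stage = "drugs"
        dg = cfg["druggability"]
        filtered = druggability.filter_catalog(catalog, min_genes=dg["min_genes"])
        ensemble = druggability.build_ensemble(filtered, weights=dg["im_weights"])
        ensemble.ranking.to_csv(out / "disease_ranking.tsv", sep="\t", index=False,
                                float_format="%.10g")
        ensemble.consensus.to_csv(out / "consensus_distance.tsv", sep="\t",
                                  float_format="%.10g")
        drugs = druggability.prioritize_drugs(
            triples, ensemble.ranking, module, filtered.query_disease_id
        )
        drugs.to_csv(out / "drug_ranking.tsv", sep="\t", index=False,
                     float_format="%.10g")

        # ----------------------------------------------------------- provenance
        stage = "provenance"
        provenance = {
            "config_hash": config_hash(cfg),
            "seed": seed,
            "stage_seeds": {
                s: derive_seed(seed, s) for s in ("simulate", "knowledge", "meta")
            },
            "n_genes": len(studyset.genes),
            "n_seeds": len(seeds.genes),
            "n_module": len(module.genes),
            "n_lesional_specific": len(module.diamond_genes),
        }
        io.write_json({"provenance": provenance, "config": cfg}, out / "results.json")
    except Exception as exc:        # noqa: BLE001 - abort names the stage
        raise PipelineError(stage, exc) from exc
    return out


def load_run(out_dir: str | Path) -> dict:
    """Re-load the key artefacts of a finished run."""
    out = Path(out_dir)
    with open(out / "results.json") as fh:
        results = json.load(fh)
    return {
        "results": results,
        "truth": json.loads((out / "truth.json").read_text()),
        "networks": {
            c: io.read_network(out / f"network_{c}.tsv")
            for c in ("lesional", "nonlesional")
        },
        "module": pd.read_csv(out / "module.tsv", sep="\t"),
        "seeds": io.read_gene_list(out / "seeds.txt"),
        "drugs": pd.read_csv(out / "drug_ranking.tsv", sep="\t"),
    }
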