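"""Pipeline configuration: defaults, YAML loading, schema validation."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "synthdata": {
        "n_genes": 200,
        "n_studies": 2,
        "samples_per_condition": 25,   # per study
        "module_size": 20,
        "n_core": 10,
        "rho_in": 0.8,
        "rho_out": 0.0,
        "effect_size": 1.0,
        "batch_sd": 0.5,
        "overlap_fracs": {"gwas": 0.5, "disease_gene": 0.5, "drug_target": 0.5},
        "n_decoys": 30,
        "n_diseases": 12,
        "n_drugs": 8,
    },
    "netinfer": {
        "estimators": [
            "pearson",
            "spearman",
            "kendall",
            "mi_empirical",
            "mi_millermadow",
            "mi_shrink",
            "mi_sg",
        ],
        "algorithms": ["clr", "aracne", "mrnet"],
        "top_edges": None,             # null -> mean degree 20
        "n_bins": None,                # null -> floor(sqrt(n_samples))
        "walk_length": 4,
    },
    "metaanalysis": {
        "n_perm": 200,
        "rank_product_mode": "best_of_both",
    },
    "generank": {
        "top_n": 20,                   # evidence cut-off for ranked sources
        "min_evidence": 3,
        "bridge_max_path_length": 1,
    },
    "diseasemodule": {
        "alpha": 0.05,
        "n_iterations": None,          # null -> 2 * |seeds|
        "correction": "candidates",    # 'candidates' | 'none' (raw trace p)
    },
    "druggability": {
        "min_genes": 5,
        "im_weights": "similarity",    # 'similarity' | 'distance'
    },
}

_REQUIRED_SECTIONS = tuple(DEFAULT_CONFIG)


def validate_config(config: dict) -> dict:
    """Check section/key names against the schema; unknown keys are fatal,
    missing ones filled from the defaults."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in config.items():
        if section not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config section {section!r}")
        if values is None:
            continue
        for key, val in values.items():
            if key not in DEFAULT_CONFIG[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            merged[section][key] = val
    return merged


def load_config(path: str | Path | None = None) -> dict:
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the global seed (< 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
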