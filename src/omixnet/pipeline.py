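"""End-to-end orchestration: simulate/load -> preprocess -> associate ->
pathways -> network -> subnetwork -> signature, with a run manifest.

The manifest records package and library versions, the resolved config and
its hash, the seed, and per-stage counts (features removed, significant
molecules, edges, subnetwork size), so a run can be audited and repeated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import io as omio
from .differential import (
    extract_signature,
    fit_association,
    results_to_frame,
    run_clinical_panel,
    significant,
)
from .errors import ConfigError
from .ggm import annotate_network, infer_network
from .matrix import OmicsMatrix, concat_matrices
from .pathway import annotate_and_filter
from .preprocess import run_chain
from .subnetwork import extract_subnetwork
from .synthetic import SyntheticSpec, generate_cohort, write_truth

log = logging.getLogger(__name__)

DEFAULTS = {
    "preprocess": {"max_missing_frac": 0.25, "knn_k": 10},
    "differential": {"fdr": 0.05, "lfc_threshold": 2.0},
    "network": {"edge_fdr": 0.05, "edge_fdr_method": "bh"},
    "subnetwork": {"depth": 2},
}


def _resolve_config(config: dict) -> dict:
    cfg = json.loads(json.dumps(config))  # deep copy, JSON-serializable check
    for section, defaults in DEFAULTS.items():
        merged = dict(defaults)
        merged.update(cfg.get(section) or {})
        cfg[section] = merged
    if ("synthetic" in cfg) == ("inputs" in cfg):
        raise ConfigError("config needs exactly one of 'synthetic' or 'inputs'")
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_inputs(cfg: dict) -> tuple[OmicsMatrix, pd.DataFrame, dict | None]:
    inputs = cfg["inputs"]
    parts = []
    if "metabolites" in inputs:
        parts.append(omio.read_matrix(inputs["metabolites"], "metabolite"))
    if "proteins" in inputs:
        parts.append(omio.read_matrix(inputs["proteins"], "protein"))
    if not parts:
        raise ConfigError("inputs must name 'metabolites' and/or 'proteins'")
    matrix = parts[0] if len(parts) == 1 else concat_matrices(parts[0], parts[1])
    samples = omio.read_sample_table(inputs["samples"])
    dup_map = None
    if inputs.get("duplicate_map"):
        df = pd.read_csv(inputs["duplicate_map"], sep="\t")
        dup_map = dict(zip(df["duplicate_id"], df["canonical_id"]))
    return matrix, samples, dup_map


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage in order, write all artifacts, return the manifest."""
    cfg = _resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # -- stage: simulate or load ---------------------------------------
    truth = None
    if "synthetic" in cfg:
        spec = SyntheticSpec.from_dict(cfg["synthetic"])
        matrix, samples, truth = generate_cohort(spec)
        dup_map = dict(truth.duplicate_groups)
        omio.write_matrix(matrix, out / "raw_matrix.tsv")
        omio.write_sample_table(samples, out / "samples.tsv")
        write_truth(truth, out / "truth")
    else:
        matrix, samples, dup_map = _load_inputs(cfg)
    counts["n_features_raw"] = matrix.n_features
    counts["n_samples"] = matrix.n_samples

    # -- stage: preprocess ---------------------------------------------
    pp = cfg["preprocess"]
    processed, qc = run_chain(
        matrix,
        max_missing_frac=pp["max_missing_frac"],
        knn_k=pp["knn_k"],
        duplicate_groups=dup_map,
    )
    omio.write_matrix(processed, out / "processed_matrix.tsv")
    qc["removed"].to_csv(out / "qc_removed_features.tsv", sep="\t", index=False)
    qc["quotient_medians"].rename_axis("sample_id").to_frame().to_csv(
        out / "qc_quotient_medians.tsv", sep="\t"
    )
    counts["n_features_removed_missingness"] = qc["n_features_removed"]
    counts["n_features_processed"] = processed.n_features
    labels = processed.omics.value_counts()
    counts["n_metabolites_processed"] = int(labels.get("metabolite", 0))
    counts["n_proteins_processed"] = int(labels.get("protein", 0))

    # -- stage: diagnosis contrast -------------------------------------
    fdr = cfg["differential"]["fdr"]
    diagnosis = fit_association(processed, samples, "group")
    omio.write_results(results_to_frame(diagnosis), out / "diagnosis_associations.tsv")
    hits = significant(diagnosis, fdr)
    counts["n_significant_diagnosis"] = len(hits)
    counts["n_significant_metabolites"] = sum(
        r.omics_label == "metabolite" for r in hits
    )
    counts["n_significant_proteins"] = sum(r.omics_label == "protein" for r in hits)

    # -- stage: pathways (needs an annotation table) --------------------
    if cfg.get("annotations"):
        annotations = omio.read_annotations(cfg["annotations"])
        retained, unannotated = annotate_and_filter(diagnosis, annotations, fdr=fdr)
        retained.to_csv(out / "pathways.tsv", sep="\t", index=False)
        counts["n_pathways_retained"] = len(retained)
        counts["n_unannotated_molecules"] = len(unannotated)

    # -- stage: network -------------------------------------------------
    net_cfg = cfg["network"]
    network, est = infer_network(
        processed, fdr=net_cfg["edge_fdr"], method=net_cfg["edge_fdr_method"]
    )
    network = annotate_network(network, diagnosis)
    omio.write_network(network, out / "network.graphml", "graphml")
    omio.write_network(network, out / "network_edges.tsv", "edge_tsv")
    node_rows = [
        {
            "molecule_id": n,
            "omics_label": network.nodes[n].get("omics_label"),
            "p_score": network.nodes[n].get("p_score"),
            "degree": network.degree[n],
        }
        for n in sorted(network.nodes)
    ]
    pd.DataFrame(node_rows).to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    counts["lambda_star"] = est.lambda_star
    counts["kappa"] = est.kappa
    counts["n_edges"] = network.number_of_edges()

    # -- stage: subnetwork (optional seeds) ------------------------------
    sub_cfg = cfg["subnetwork"]
    if sub_cfg.get("seeds"):
        sub = extract_subnetwork(network, sub_cfg["seeds"], sub_cfg["depth"])
        omio.write_network(sub, out / "subnetwork.graphml", "graphml")
        omio.write_network(sub, out / "subnetwork_edges.tsv", "edge_tsv")
        counts["subnetwork_nodes"] = sub.number_of_nodes()
        counts["subnetwork_edges"] = sub.number_of_edges()

    # -- stage: clinical panel + mortality signature ---------------------
    panel = run_clinical_panel(processed, samples)
    panel_frames = [
        results_to_frame(res).assign(group=group)
        for (group, _), res in sorted(panel.results.items())
        if res
    ]
    if panel_frames:
        pd.concat(panel_frames, ignore_index=True).to_csv(
            out / "clinical_associations.tsv", sep="\t", index=False
        )
    panel.hit_counts(fdr).to_csv(out / "clinical_hit_counts.tsv", sep="\t", index=False)
    counts["clinical_hits"] = {
        f"{g}/{o}": int(len(significant(res, fdr)))
        for (g, o), res in sorted(panel.results.items())
    }
    mortality = panel.results.get(("covid", "mortality"))
    if mortality is not None:
        sig = extract_signature(
            mortality, fdr=fdr, lfc_threshold=cfg["differential"]["lfc_threshold"]
        )
        omio.write_results(results_to_frame(sig), out / "mortality_signature.tsv")
        counts["n_signature_molecules"] = len(sig)

    manifest = {
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
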