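"""End-to-end orchestration: simulate/load -> class-aware QC -> aligned
clustering with merge validation -> markers -> cross-dataset correspondence
and label transfer -> enrichment -> two-phase DE, with a machine-readable
run manifest.

Every stage writes fresh TSV artifacts into the output directory and
echoes its parameters into ``manifest.json``; nothing mutates an upstream
artifact, and a fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import embed, enrichment as enr, io as cio, markers as mk, qc as qcmod
from . import simulate as sim, transfer as tr, twophase as tp
from .containers import ClusterAssignment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_CONFIG"]

STAGES = ("simulate", "qc", "cluster", "markers", "transfer", "enrich", "twophase")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "cortexmap_run",
    "input": {"path": None},
    "simulate": {},  # SimulationConfig overrides
    "qc": {
        "mito_max": 0.10,
        "doublet_pctile": 99.0,
        "min_genes_non_neuronal": 800,
        "min_genes_neuronal": 1500,
        "neuronal_markers": list(sim.NEURONAL_MARKERS),
        "broad_resolution": 1.0,
        "broad_n_vectors": 12,
    },
    "cluster": {
        "n_top_genes": 2000,
        "n_cc": 20,
        "bicor_threshold": 0.15,
        "k": 20,
        "resolution": 2.0,
        "n_vectors": 12,
        "conn_pctile": 0.90,
        "svm_acc": 0.90,
        "svm_n_genes": 100,
        "svm_n_pcs": 5,
    },
    "markers": {"enabled": True, "min_frac": 0.1, "adjust": "bonferroni",
                "gene_scope": "variable"},
    "transfer": {"enabled": True, "n_boot": 100, "gene_frac": 0.8,
                 "top_genes_per_cc": 100, "n_cc": 20, "assign_prob": 0.5,
                 "voting_k": 20},
    "enrich": {"catalog": None, "diseases": []},
    "twophase": {"enabled": True, "gene_scope": "variable", "fc": 1.5,
                 "fdr": 0.05, "min_cells": 5},
}


def _merge_config(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge_config(base[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


class RunConfig(dict):
    """Validated pipeline configuration (defaults + overrides).

    Unknown keys are rejected; ``simulate`` accepts any
    :class:`~cortexmap.simulate.SimulationConfig` field.
    """

    @classmethod
    def from_dict(cls, overrides: dict = None) -> "RunConfig":
        overrides = overrides or {}
        sim_over = overrides.pop("simulate", {}) if "simulate" in overrides else {}
        cfg = _merge_config(DEFAULT_CONFIG, overrides)
        valid_sim = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
        bad = set(sim_over) - valid_sim
        if bad:
            raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        cfg["simulate"] = sim_over
        return cls(cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _write(df: pd.DataFrame, outdir: Path, name: str, manifest: dict,
           index: bool = False):
    path = outdir / name
    df.to_csv(path, sep="\t", index=index)
    manifest["artifacts"].append(name)


def run_pipeline(config, stop_after: str = "twophase") -> dict:
    """Execute the pipeline; returns the manifest dict (also written to
    ``manifest.json``).  A stage failure aborts with the stage name after
    writing the partial manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(dict(config))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stop_idx = STAGES.index(stop_after)
    manifest = {"seed": seed, "stages": {}, "artifacts": [], "parameters": {}}
    state = {}

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, **extra}

    try:
        _run_stages(config, outdir, seed, stop_idx, manifest, state, record)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "_stage", "unknown")
        _dump_manifest(manifest, outdir)
        raise
    _dump_manifest(manifest, outdir)
    return manifest


def _dump_manifest(manifest: dict, outdir: Path):
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _stage_guard(stage):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                exc._stage = stage
                raise
        return wrapped
    return deco


def _run_stages(config, outdir, seed, stop_idx, manifest, state, record):
    # ---- simulate / load -------------------------------------------------
    @_stage_guard("simulate")
    def stage_simulate():
        if config["input"]["path"]:
            em = cio.read_10x_mtx(config["input"]["path"])
            record("simulate", "skipped", reason="external input provided")
        else:
            scfg = sim.SimulationConfig(**{"seed": seed, **config["simulate"]})
            em, gt = sim.generate_dataset(scfg)
            sim.write_dataset(em, gt, outdir / "data")
            state["truth"] = gt
            manifest["parameters"]["simulate"] = dataclasses.asdict(scfg)
            record("simulate", "done", n_genes=em.n_genes, n_cells=em.n_cells)
        state["raw"] = em

    stage_simulate()
    if stop_idx < 1:
        return

    # ---- QC --------------------------------------------------------------
    @_stage_guard("qc")
    def stage_qc():
        p = config["qc"]
        em = state["raw"]
        params = qcmod.QCParams(
            mito_max=p["mito_max"], doublet_pctile=p["doublet_pctile"],
            min_genes_non_neuronal=p["min_genes_non_neuronal"],
            min_genes_neuronal=p["min_genes_neuronal"],
        )
        qc1 = qcmod.compute_qc(em)
        # pass 1: class-agnostic floor (the non-neuronal one)
        em1, log1, thr1 = qcmod.filter_cells(em, qc1, params)
        norm1 = qcmod.normalize_log_cpm(qcmod.remove_gene_families(em1))
        # broad clustering to find the neuronal clusters
        cond = em1.cell_meta.get("condition")
        genes = embed.select_variable_genes(norm1, n_top=config["cluster"]["n_top_genes"])
        if genes.size < 10:
            genes = None
        if cond is not None and cond.nunique() == 2:
            conds = sorted(cond.unique())
            a = norm1.subset_cells((cond == conds[0]).to_numpy())
            b = norm1.subset_cells((cond == conds[1]).to_numpy())
            if genes is None:
                genes = embed.select_variable_genes(a, b, n_top=2000)
            space = embed.cca_align(a, b, genes,
                                    n_cc=max(p["broad_n_vectors"], 12),
                                    bicor_threshold=config["cluster"]["bicor_threshold"])
            order = np.concatenate([
                np.flatnonzero((cond == conds[0]).to_numpy()),
                np.flatnonzero((cond == conds[1]).to_numpy()),
            ])
        else:
            space = embed.pca_embed(norm1, n_pcs=max(p["broad_n_vectors"], 12),
                                    genes=genes, seed=seed)
            order = np.arange(norm1.n_cells)
        _, broad = embed.build_snn_and_cluster(
            space, k=config["cluster"]["k"], resolution=p["broad_resolution"],
            n_vectors=p["broad_n_vectors"], level="broad", seed=seed,
        )
        labels_orig = np.empty(norm1.n_cells, dtype=int)
        labels_orig[order] = broad.labels
        neuronal = qcmod.score_neuronal_clusters(norm1, labels_orig,
                                                 p["neuronal_markers"])
        broad_class = np.where(neuronal[labels_orig], "neuronal", "non_neuronal")
        # pass 2: class-specific floors
        qc2 = qcmod.compute_qc(em1)
        qc2["broad_class"] = broad_class
        em2, log2, thr2 = qcmod.filter_cells(em1, qc2, params)
        qc_final = qc2.loc[qc2.index.isin(em2.barcodes)]
        state["em"] = em2
        state["qc"] = qc_final
        state["broad_class"] = qc_final["broad_class"].to_numpy()
        log = pd.concat(
            [log1.assign(qc_pass=1), log2.assign(qc_pass=2)], ignore_index=True
        )
        _write(log, outdir, "qc_removed_cells.tsv", manifest)
        _write(qc_final.reset_index(), outdir, "qc_metrics.tsv", manifest)
        manifest["parameters"]["qc"] = {**p, **{f"pass1_{k}": v for k, v in thr1.items()},
                                        **{f"pass2_{k}": v for k, v in thr2.items()}}
        record("qc", "done", n_cells_retained=em2.n_cells,
               n_removed=int(len(log)))

    stage_qc()
    if stop_idx < 2:
        return

    # ---- embed + cluster + merge ------------------------------------------
    @_stage_guard("cluster")
    def stage_cluster():
        p = config["cluster"]
        em = qcmod.remove_gene_families(state["em"])
        norm = qcmod.normalize_log_cpm(em)
        cond = em.cell_meta.get("condition")
        if cond is not None and cond.nunique() == 2:
            conds = sorted(cond.unique())
            mask_a = (cond == conds[0]).to_numpy()
            a = norm.subset_cells(mask_a)
            b = norm.subset_cells(~mask_a)
            genes = embed.select_variable_genes(a, b, n_top=p["n_top_genes"])
            space = embed.cca_align(a, b, genes, n_cc=p["n_cc"],
                                    bicor_threshold=p["bicor_threshold"])
            order = np.concatenate([np.flatnonzero(mask_a),
                                    np.flatnonzero(~mask_a)])
        else:
            genes = embed.select_variable_genes(norm, n_top=p["n_top_genes"])
            space = embed.pca_embed(norm, n_pcs=p["n_cc"], genes=genes, seed=seed)
            order = np.arange(norm.n_cells)
        snn, assign = embed.build_snn_and_cluster(
            space, k=p["k"], resolution=p["resolution"],
            n_vectors=p["n_vectors"], level="high_res", seed=seed,
        )
        norm_ordered = norm.subset_cells(order)
        merged, decisions = embed.validate_and_merge(
            norm_ordered, assign, snn, conn_pctile=p["conn_pctile"],
            svm_acc=p["svm_acc"], n_genes=p["svm_n_genes"],
            n_pcs=p["svm_n_pcs"], seed=seed,
        )
        labels = np.empty(norm.n_cells, dtype=int)
        labels[order] = merged.labels
        state.update(norm=norm, labels=labels, space=space, order=order,
                     genes=genes, em_nofam=em)
        _write(
            pd.DataFrame({"barcode": em.barcodes, "level": "high_res",
                          "label": labels}),
            outdir, "cluster_assignments.tsv", manifest,
        )
        _write(
            pd.DataFrame([dataclasses.asdict(d) for d in decisions]),
            outdir, "merge_decisions.tsv", manifest,
        )
        manifest["parameters"]["cluster"] = {
            **{k: v for k, v in p.items()},
            "n_variable_genes": int(len(genes)),
            "cc_scores": [round(float(s), 4) for s in space.scores],
        }
        record("cluster", "done", n_clusters=int(labels.max() + 1),
               n_merges=sum(d.merged for d in decisions))

    stage_cluster()
    if stop_idx < 3:
        return

    # ---- markers ----------------------------------------------------------
    @_stage_guard("markers")
    def stage_markers():
        p = config["markers"]
        if not p["enabled"]:
            record("markers", "skipped", reason="disabled")
            return
        em = state["em_nofam"]
        labels = state["labels"]
        if labels.max() == 0:
            record("markers", "skipped", reason="single cluster")
            return
        if p["gene_scope"] == "variable":
            em_test = em.subset_genes(np.isin(em.gene_ids, state["genes"]))
        else:
            em_test = em
        cov = mk.default_covariates(
            em, pct_mito=state["qc"]["pct_mito"].to_numpy()
        )
        frames = []
        for k in np.unique(labels):
            res = mk.nb_glm_test(
                em_test, (labels == k).astype(int), covariates=cov,
                min_frac=p["min_frac"], adjust=p["adjust"],
            )
            res["cluster"] = int(k)
            frames.append(res[res["tested"]])
        tab = pd.concat(frames, ignore_index=True)
        _write(tab, outdir, "cluster_markers.tsv", manifest)
        manifest["parameters"]["markers"] = dict(p)
        record("markers", "done", n_tests=int(len(tab)))

    stage_markers()
    if stop_idx < 4:
        return

    # ---- cross-dataset correspondence + label transfer ---------------------
    @_stage_guard("transfer")
    def stage_transfer():
        p = config["transfer"]
        cond = state["em"].cell_meta.get("condition")
        if not p["enabled"] or cond is None or cond.nunique() != 2:
            record("transfer", "skipped", reason="needs two conditions")
            return
        space, order, labels = state["space"], state["order"], state["labels"]
        labels_ordered = labels[order]
        is_a = space.dataset == 0
        simmap = tr.neighbor_voting_similarity(
            space, labels_ordered[is_a], labels_ordered[~is_a],
            k=p["voting_k"], n_cc=p["n_cc"],
        )
        sim_df = pd.DataFrame(
            simmap.scores,
            index=[f"A:{i}" for i in range(simmap.scores.shape[0])],
            columns=[f"B:{j}" for j in range(simmap.scores.shape[1])],
        )
        _write(sim_df, outdir, "similarity_map.tsv", manifest, index=True)
        _write(
            pd.DataFrame(
                [{"cluster": c, "group": g} for c, g in simmap.groups.items()]
            ),
            outdir, "similarity_groups.tsv", manifest,
        )
        norm, order_inv = state["norm"], np.argsort(order)
        ref = norm.subset_cells(order[is_a])
        query = norm.subset_cells(order[~is_a])
        result, _ = tr.bootstrap_label_transfer(
            ref, ClusterAssignment(labels_ordered[is_a]), space, query,
            n_boot=p["n_boot"], gene_frac=p["gene_frac"],
            top_genes_per_cc=p["top_genes_per_cc"], n_cc=p["n_cc"],
            assign_prob=p["assign_prob"], seed=seed,
        )
        _write(result, outdir, "label_transfer.tsv", manifest)
        manifest["parameters"]["transfer"] = dict(p)
        record("transfer", "done",
               unassigned_fraction=float((~result["assigned"]).mean()))

    stage_transfer()
    if stop_idx < 5:
        return

    # ---- enrichment --------------------------------------------------------
    @_stage_guard("enrich")
    def stage_enrich():
        p = config["enrich"]
        if not p["catalog"]:
            record("enrich", "skipped", reason="no catalog configured")
            return
        catalog = cio.read_gwas_catalog(p["catalog"], p["diseases"])
        ee = enr.EntropyEnrichment().fit(state["norm"], state["labels"])
        _write(ee.stats_, outdir, "enrichment_stats.tsv", manifest)
        _write(ee.calls_, outdir, "enrichment_calls.tsv", manifest, index=True)
        per_cluster, per_disease = enr.disease_summary(ee.result_, catalog)
        _write(per_cluster, outdir, "disease_by_cluster.tsv", manifest)
        _write(per_disease, outdir, "disease_summary.tsv", manifest)
        manifest["parameters"]["enrich"] = {"diseases": list(p["diseases"]),
                                            "catalog": str(p["catalog"])}
        record("enrich", "done", n_catalog=len(catalog))

    stage_enrich()
    if stop_idx < 6:
        return

    # ---- two-phase DE -------------------------------------------------------
    @_stage_guard("twophase")
    def stage_twophase():
        p = config["twophase"]
        cond = state["em"].cell_meta.get("condition")
        if not p["enabled"] or cond is None or cond.nunique() != 2:
            record("twophase", "skipped", reason="needs two conditions")
            return
        em = state["em_nofam"]
        if p["gene_scope"] == "variable":
            em_fit = em.subset_genes(np.isin(em.gene_ids, state["genes"]))
        else:
            em_fit = em
        model = tp.fit_two_phase(em_fit)
        groups = (cond == sorted(cond.unique())[1]).to_numpy().astype(int)
        res = tp.phase2_de(em_fit, model, groups, state["labels"],
                           fc=p["fc"], fdr=p["fdr"], min_cells=p["min_cells"])
        _write(res.table, outdir, "phase2_de.tsv", manifest)
        _write(res.summary, outdir, "phase2_de_summary.tsv", manifest)
        _write(res.overlap, outdir, "phase2_de_overlap.tsv", manifest, index=True)
        manifest["parameters"]["twophase"] = dict(p)
        record("twophase", "done",
               n_passing=int(res.table["pass"].sum()) if len(res.table) else 0)

    stage_twophase()
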