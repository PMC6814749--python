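"""End-to-end orchestration: simulate -> QC -> normalize -> reduce/MNN ->
archetypal ladder -> cell network -> annotate -> markers, with optional
subtype and GWAS stages, under a single validated config and seed.

Every stage persists its artifacts under the output directory and the run
writes a manifest with SHA-256 checksums; identical config + seed reproduces
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import annotate as _annotate
from . import gwas as _gwas
from . import subtypes as _subtypes
from .archnet import build_kstar_nn, build_ladder, cell_profiles, layout, \
    reduce_profile
from .io_qc import depth_normalize, qc_filter, read_mtx_triplet, \
    write_mtx_triplet
from .markers import rank_top, signature_profiles, wilcoxon_markers
from .mnn import mnn_correct
from .synth import SimConfig, SubtypeSpec, generate_counts, generate_gwas_stats

__all__ = ["PipelineConfig", "run_all", "demo_config"]

log = logging.getLogger("retinet")
if not log.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(h)
    log.setLevel(logging.INFO)


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n_genes: int = Field(2000, gt=0)
    n_types: int = Field(8, gt=0)
    cells_per_type: int = Field(500, gt=0)
    markers_per_type: int = Field(20, ge=0)
    marker_fold: float = Field(8.0, gt=1.0)
    doublet_rate: float = Field(0.05, ge=0.0, lt=1.0)
    n_batches: int = Field(2, gt=0)
    batch_shift_sd: float = Field(0.15, ge=0.0)
    platforms: int = Field(1, ge=1, le=2)
    with_subtypes: bool = False


class PipelineConfig(BaseModel):
    """Validated run settings; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str | None = None          # triplet dir when not simulating
    output_dir: str = "retinet_out"
    seed: int = 0
    synth: SynthSection = SynthSection()
    min_genes_per_cell: int = Field(300, ge=0)
    min_cells_per_gene: int = Field(10, ge=0)
    reduced_dim: int = Field(50, gt=1)
    mnn_k: int = Field(20, gt=0)
    mnn_order: str = "by_size"
    k_min: int = Field(2, ge=2)
    k_max: int = Field(15, ge=2)
    restarts: int = Field(3, ge=1)
    diffusion_alpha: float = Field(0.85, ge=0.0, lt=1.0)
    n_perm: int = Field(1000, ge=100)
    sig_threshold: float = Field(0.05, gt=0.0, lt=1.0)
    marker_p: float = Field(0.001, gt=0.0, lt=1.0)
    marker_auc: float = Field(0.5, ge=0.0, le=1.0)
    marker_lfc: float = Field(0.0, ge=0.0)
    top_n: int = Field(10, gt=0)
    with_layout: bool = False
    run_subtypes: bool = False
    subtype_parent: str = "macroglia"
    subtype_k: int = 3
    run_gwas: bool = False
    gwas_stats: str | None = None         # TSV path; synthetic when absent
    gwas_effect: float = 0.5

    @field_validator("k_max")
    @classmethod
    def _k_order(cls, v, info):
        if "k_min" in info.data and v < info.data["k_min"]:
            raise ValueError("k_max must be >= k_min")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        if not self.synth.enabled and self.input_dir is None:
            raise ValueError("input_dir required when synthesis is disabled")
        if not self.synth.enabled and not os.path.isdir(self.input_dir):
            raise ValueError(f"input_dir {self.input_dir!r} does not exist")
        if self.gwas_stats is not None and not os.path.exists(self.gwas_stats):
            raise ValueError(f"gwas_stats {self.gwas_stats!r} does not exist")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    from .synth import CellTypeSpec

    names = ["rods", "cones", "bipolar", "amacrine", "horizontal", "RGC",
             "macroglia", "microglia", "vascular"]
    types = [
        CellTypeSpec(names[i % len(names)] if i < len(names) else f"type{i}",
                     n_cells=cfg.synth.cells_per_type,
                     n_exclusive_markers=cfg.synth.markers_per_type,
                     marker_fold=cfg.synth.marker_fold)
        for i in range(cfg.synth.n_types)
    ]
    return SimConfig(
        n_genes=cfg.synth.n_genes, cell_types=types,
        doublet_rate=cfg.synth.doublet_rate, n_batches=cfg.synth.n_batches,
        batch_shift_sd=cfg.synth.batch_shift_sd, platforms=cfg.synth.platforms,
        subtype_spec=SubtypeSpec(parent=cfg.subtype_parent)
        if cfg.synth.with_subtypes else None,
        seed=cfg.seed,
    )


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every configured stage; returns the manifest (artifact ->
    sha256) also written to ``manifest.json``."""
    cfg.validate_paths()
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    artifacts = []
    t0 = time.time()

    def stage(name):
        log.info("stage %-10s t=%.1fs", name, time.time() - t0)

    def save_tsv(df: pd.DataFrame, name: str, index=True):
        path = os.path.join(out, name)
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        artifacts.append(path)

    # -------- simulate / load
    stage("input")
    dataset = None
    if cfg.synth.enabled:
        dataset = generate_counts(_sim_config(cfg))
        counts = dataset.counts
        data_dir = os.path.join(out, "data")
        write_mtx_triplet(counts, data_dir)
        artifacts += [os.path.join(data_dir, f) for f in
                      ("matrix.mtx", "genes.tsv", "barcodes.tsv",
                       "cell_metadata.tsv")]
    else:
        counts = read_mtx_triplet(cfg.input_dir)

    # -------- QC + normalization
    stage("qc")
    log.info("qc thresholds: min_genes_per_cell=%d min_cells_per_gene=%d",
             cfg.min_genes_per_cell, cfg.min_cells_per_gene)
    filtered = qc_filter(counts, cfg.min_genes_per_cell, cfg.min_cells_per_gene)
    if filtered.n_cells == 0:
        raise RuntimeError("qc stage: empty matrix after filtering")
    nm = depth_normalize(filtered)
    save_tsv(pd.DataFrame({"barcode": nm.cell_ids,
                           "depth_factor": nm.depth_factors}),
             "depth_factors.tsv", index=False)

    # -------- reduce + MNN
    stage("reduce")
    rp = reduce_profile(nm, d=min(cfg.reduced_dim, min(nm.values.shape) - 1),
                        random_state=cfg.seed)
    if "batch" in nm.cell_meta.columns and nm.cell_meta["batch"].nunique() > 1:
        log.info("mnn: k=%d order=%s", cfg.mnn_k, cfg.mnn_order)
        rp.scores = mnn_correct(rp.scores, nm.cell_meta["batch"].to_numpy(),
                                k=cfg.mnn_k, order=cfg.mnn_order)
    save_tsv(pd.DataFrame(rp.scores, index=nm.cell_ids), "reduced_coords.tsv")

    # -------- ladder + network
    stage("network")
    ladder = build_ladder(rp, cfg.k_min, cfg.k_max, restarts=cfg.restarts,
                          seed=cfg.seed)
    save_tsv(pd.DataFrame({"k": ladder.depths,
                           "error": [ladder.errors[k] for k in ladder.depths]}),
             "ladder_errors.tsv", index=False)
    profiles = cell_profiles(ladder)
    net = build_kstar_nn(profiles, cell_ids=nm.cell_ids)
    coo = sp.triu(net.adjacency, k=1).tocoo()
    save_tsv(pd.DataFrame({"source": nm.cell_ids[coo.row],
                           "target": nm.cell_ids[coo.col],
                           "weight": coo.data}),
             "network_edges.tsv", index=False)
    if cfg.with_layout:
        coords = layout(net, seed=cfg.seed)
        save_tsv(pd.DataFrame(coords, index=nm.cell_ids, columns=["x", "y"]),
                 "layout.tsv")

    # -------- annotate
    stage("annotate")
    if dataset is not None:
        markers = {t: g for t, g in dataset.true_markers.items() if g}
    else:
        markers = dict(_annotate.RETINA_MARKERS)
    ann = _annotate.annotate_cells(
        net, nm, markers, alpha=cfg.diffusion_alpha, n_perm=cfg.n_perm,
        seed=cfg.seed, sig_threshold=cfg.sig_threshold,
    )
    best = ann.score.idxmax(axis=1)
    save_tsv(pd.DataFrame({
        "barcode": nm.cell_ids, "label": ann.label.to_numpy(),
        "best_score": ann.score.max(axis=1).to_numpy(),
        "p_best": [ann.perm_p.loc[c, b] for c, b in zip(ann.score.index, best)],
    }), "annotation.tsv", index=False)

    # -------- markers
    stage("markers")
    assigned = ~ann.label.isin(_annotate.FILTER_CODES)
    lab = ann.label[assigned]
    nm_assigned = type(nm)(nm.values[:, assigned.to_numpy()],
                           nm.depth_factors[assigned.to_numpy()],
                           nm.gene_ids, nm.cell_ids[assigned.to_numpy()],
                           nm.cell_meta.loc[assigned.to_numpy()])
    rp_assigned = type(rp)(rp.scores[assigned.to_numpy()], rp.basis,
                           rp.singular_values, rp.gene_means, rp.gene_ids,
                           nm_assigned.cell_ids)
    sig, base = signature_profiles(rp_assigned, lab.to_numpy())
    res = wilcoxon_markers(nm_assigned, lab.to_numpy(), p_thresh=cfg.marker_p,
                           auc_thresh=cfg.marker_auc, lfc_thresh=cfg.marker_lfc)
    save_tsv(res, "marker_tests.tsv", index=False)
    top = rank_top(sig, res, n=cfg.top_n)
    save_tsv(pd.DataFrame(
        [(t, i + 1, g) for t, gs in top.items() for i, g in enumerate(gs)],
        columns=["type", "rank", "gene"]), "top_markers.tsv", index=False)

    # -------- subtypes (optional)
    if cfg.run_subtypes:
        stage("subtypes")
        spec = _subtypes.SubsetSpec(parent=cfg.subtype_parent, k=cfg.subtype_k)
        sub = _subtypes.extract_and_clean(filtered, ann.label, spec,
                                          seed=cfg.seed)
        sub_labels, sub_net = _subtypes.subcluster(sub, spec, seed=cfg.seed,
                                                   return_network=True)
        save_tsv(pd.DataFrame({"barcode": sub.cell_ids,
                               "subtype": sub_labels}),
                 "subtypes.tsv", index=False)
        if "region" in sub.cell_meta.columns:
            enr = _subtypes.region_enrichment(
                sub_labels, sub.cell_meta["region"].to_numpy(),
                _subtypes.subtype_scores(sub_net, sub_labels))
            save_tsv(enr, "region_enrichment.tsv")

    # -------- gwas (optional)
    if cfg.run_gwas:
        stage("gwas")
        sets = _gwas.build_gene_sets(nm_assigned, filtered.subset(
            cell_mask=assigned.to_numpy()), lab.to_numpy())
        if cfg.gwas_stats is not None:
            stats = pd.read_csv(cfg.gwas_stats, sep="\t")
        else:
            planted = sorted(sets)[0] if sets else None
            stats = generate_gwas_stats(_sim_config(cfg),
                                        sets.get(planted, []),
                                        effect=cfg.gwas_effect)
        assoc = _gwas.negative_control_panel({"trait": stats}, sets)
        save_tsv(assoc, "gwas_association.tsv", index=False)

    # -------- manifest
    stage("manifest")
    manifest = {os.path.relpath(p, out): _sha256(p) for p in sorted(artifacts)}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def demo_config(output_dir: str, seed: int = 0) -> PipelineConfig:
    """Small, fast demonstration run (~1,200 cells) exercising every default
    stage plus the GWAS regression."""
    return PipelineConfig(
        output_dir=output_dir,
        seed=seed,
        synth=SynthSection(n_genes=1000, n_types=6, cells_per_type=200,
                           markers_per_type=15),
        min_genes_per_cell=100,
        min_cells_per_gene=5,
        reduced_dim=30,
        k_max=8,
        n_perm=250,
        run_gwas=True,
        gwas_effect=1.0,
    )
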