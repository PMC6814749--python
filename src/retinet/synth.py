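"""Synthetic scRNA-seq generator with planted structure.

Emulates the statistical features the downstream stages rely on: cell-type
structured negative-binomial counts with exclusive marker genes, log-normal
library-size variation, per-gene multiplicative batch (and platform) effects,
doublets formed by summing two singlet cells, optional macroglia-like subtypes
with region-biased frequencies, and gene-level GWAS summary statistics with one
planted enriched gene set.

Counts are drawn gamma-Poisson: NB with mean ``mu`` and size ``s`` has variance
``mu + mu^2/s``; the default size 2 gives scRNA-like overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import CountMatrix

__all__ = [
    "CellTypeSpec",
    "SubtypeSpec",
    "SimConfig",
    "SyntheticDataset",
    "generate_counts",
    "generate_gwas_stats",
    "default_config",
    "two_platform_config",
    "subtype_config",
]

# Macroglial subtype marker panels: immediate-early/astrocyte,
# angiogenic/metabolic, and iron-homeostasis programs.
DEFAULT_SUBTYPE_MARKERS = {
    "FOS_sub": ["FOS", "GFAP", "SPARCL1", "EGR1"],
    "COL4A3_sub": ["COL4A3", "VEGFA", "HTRA1", "SLC2A1"],
    "FTL_sub": ["FTL", "FTH1", "DBI"],
}
# macula fraction per subtype: astrocyte-like biased to periphery, COL4A3-like
# to the macula, FTL-like even
DEFAULT_SUBTYPE_MACULA_FRAC = {"FOS_sub": 0.3, "COL4A3_sub": 0.7, "FTL_sub": 0.5}


@dataclass
class CellTypeSpec:
    name: str
    n_cells: int = 500
    n_exclusive_markers: int = 20
    marker_fold: float = 8.0


@dataclass
class SubtypeSpec:
    """Subtype structure planted inside one parent type (macroglia use case)."""

    parent: str = "macroglia"
    markers: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MARKERS))
    macula_frac: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MACULA_FRAC))
    marker_fold: float = 8.0
    # abundant glial transcripts (FTL, GFAP, ...) sit well above the typical
    # gene; their baseline mean is pinned here
    marker_baseline_mean: float = 2.0


@dataclass
class SimConfig:
    """Generator settings; defaults are the desk-scale study conditions
    (2,000 genes x 4,000 cells, 8 types, 5% doublets, 2 batches)."""

    n_genes: int = 2000
    cell_types: list = field(
        default_factory=lambda: [
            CellTypeSpec(n)
            for n in (
                "rods",
                "cones",
                "bipolar",
                "amacrine",
                "horizontal",
                "RGC",
                "macroglia",
                "microglia",
            )
        ]
    )
    baseline_log_mean: float = float(np.log(0.3))
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    libsize_cv: float = 0.3
    n_batches: int = 2
    batch_shift_sd: float = 0.15
    doublet_rate: float = 0.05
    platforms: int = 1
    platform_shift_sd: float = 0.3
    subtype_spec: SubtypeSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must lie in [0, 1)")
        if self.platforms not in (1, 2):
            raise ValueError("platforms must be 1 or 2")
        total_markers = sum(t.n_exclusive_markers for t in self.cell_types)
        if total_markers > self.n_genes:
            raise ValueError("more exclusive markers requested than genes available")
        for t in self.cell_types:
            if t.n_cells <= 0 or t.n_exclusive_markers < 0:
                raise ValueError("cell counts positive, marker counts nonnegative")
        if self.subtype_spec is not None:
            names = [t.name for t in self.cell_types]
            if self.subtype_spec.parent not in names:
                raise ValueError("subtype parent is not a simulated cell type")
            seen = set()
            for genes in self.subtype_spec.markers.values():
                if seen & set(genes):
                    raise ValueError("subtype marker sets must be disjoint")
                seen |= set(genes)
            if total_markers + len(seen) > self.n_genes:
                raise ValueError("marker genes exceed gene universe")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    true_type: np.ndarray
    batch: np.ndarray
    platform: np.ndarray
    region: np.ndarray
    is_doublet: np.ndarray
    true_markers: dict
    true_subtype: np.ndarray | None = None
    true_subtype_markers: dict | None = None
    doublet_components: dict | None = None


def _nb_sample(rng, mean, size):
    """Gamma-Poisson draw of NB(mean, size) for an array of means."""
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def generate_counts(config: SimConfig) -> SyntheticDataset:
    """Draw a synthetic dataset under ``config``; byte-identical for a fixed seed.

    Counts follow NB(mean = baseline x marker_fold^[gene is marker of the
    cell's type] x depth_i x batch_factor x platform_factor, size =
    nb_dispersion).  Doublets then replace a random ``doublet_rate`` fraction
    of cells with the element-wise sum of two singlet cells from two distinct,
    uniformly chosen types.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    type_names = [t.name for t in config.cell_types]
    n_cells = sum(t.n_cells for t in config.cell_types)

    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    base_mean = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_genes)

    # assign exclusive marker genes, pairwise disjoint by construction
    order = rng.permutation(n_genes)
    cursor = 0
    true_markers: dict[str, list] = {}
    marker_rows: dict[str, np.ndarray] = {}
    for t in config.cell_types:
        rows = order[cursor : cursor + t.n_exclusive_markers]
        cursor += t.n_exclusive_markers
        marker_rows[t.name] = rows
        true_markers[t.name] = list(gene_ids[rows])

    # subtype marker genes: rename some non-marker genes to the given symbols
    subtype_rows: dict[str, np.ndarray] = {}
    if config.subtype_spec is not None:
        spec = config.subtype_spec
        for sub, genes in spec.markers.items():
            rows = order[cursor : cursor + len(genes)]
            cursor += len(genes)
            gene_ids[rows] = np.array(genes, dtype=object)
            base_mean[rows] = spec.marker_baseline_mean
            subtype_rows[sub] = rows

    # per-cell assignments
    true_type = np.repeat(type_names, [t.n_cells for t in config.cell_types])
    perm = rng.permutation(n_cells)
    true_type = np.asarray(true_type, dtype=object)[perm]
    batch = rng.integers(0, config.n_batches, n_cells)
    platform = (
        rng.integers(0, 2, n_cells) if config.platforms == 2 else np.zeros(n_cells, int)
    )
    region = np.where(rng.random(n_cells) < 0.5, "macula", "periphery").astype(object)

    # subtype assignment inside the parent type, region-biased
    true_subtype = None
    if config.subtype_spec is not None:
        spec = config.subtype_spec
        subs = list(spec.markers)
        true_subtype = np.array([""] * n_cells, dtype=object)
        parent_idx = np.where(true_type == spec.parent)[0]
        for i in parent_idx:
            # P(subtype | region) from the macula fractions, uniform marginal
            w = np.array(
                [
                    spec.macula_frac[s] if region[i] == "macula" else 1 - spec.macula_frac[s]
                    for s in subs
                ]
            )
            true_subtype[i] = subs[rng.choice(len(subs), p=w / w.sum())]

    sigma2 = np.log1p(config.libsize_cv**2)
    depth = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), n_cells)
    batch_fac = rng.lognormal(0.0, config.batch_shift_sd, (config.n_batches, n_genes))
    plat_fac = (
        rng.lognormal(0.0, config.platform_shift_sd, (2, n_genes))
        if config.platforms == 2
        else np.ones((1, n_genes))
    )

    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for tname in type_names:
        cols = np.where(true_type == tname)[0]
        mu_g = base_mean.copy()
        mu_g[marker_rows[tname]] *= next(
            t.marker_fold for t in config.cell_types if t.name == tname
        )
        mu = mu_g[:, None] * depth[cols][None, :]
        mu = mu * batch_fac[batch[cols]].T * plat_fac[platform[cols]].T
        if true_subtype is not None and tname == config.subtype_spec.parent:
            for sub, rows in subtype_rows.items():
                member = true_subtype[cols] == sub
                mu[np.ix_(rows, member)] *= config.subtype_spec.marker_fold
        counts[:, cols] = _nb_sample(rng, mu, config.nb_dispersion)

    # doublets: element-wise sums of two singlet cells of distinct types
    is_doublet = np.zeros(n_cells, dtype=bool)
    doublet_components: dict[int, tuple] = {}
    n_doublets = int(round(config.doublet_rate * n_cells))
    if n_doublets:
        slots = rng.choice(n_cells, n_doublets, replace=False)
        is_doublet[slots] = True
        singlets = np.where(~is_doublet)[0]
        by_type = {t: singlets[true_type[singlets] == t] for t in type_names}
        for s in slots:
            ta, tb = rng.choice(len(type_names), 2, replace=False)
            ca = rng.choice(by_type[type_names[ta]])
            cb = rng.choice(by_type[type_names[tb]])
            counts[:, s] = counts[:, ca] + counts[:, cb]
            true_type[s] = f"{type_names[ta]}+{type_names[tb]}"
            doublet_components[int(s)] = (type_names[ta], type_names[tb])
            if true_subtype is not None:
                true_subtype[s] = ""

    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {
            "true_type": true_type,
            "batch": [f"b{b}" for b in batch],
            "platform": [f"p{p}" for p in platform],
            "region": region,
            "is_doublet": is_doublet,
        },
        index=cell_ids,
    )
    if true_subtype is not None:
        meta["true_subtype"] = true_subtype
    cm = CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids, meta)
    return SyntheticDataset(
        counts=cm,
        true_type=true_type,
        batch=np.array([f"b{b}" for b in batch], dtype=object),
        platform=np.array([f"p{p}" for p in platform], dtype=object),
        region=region,
        is_doublet=is_doublet,
        true_markers=true_markers,
        true_subtype=true_subtype,
        true_subtype_markers=(
            dict(config.subtype_spec.markers) if config.subtype_spec else None
        ),
        doublet_components=doublet_components,
    )


def generate_gwas_stats(
    config: SimConfig,
    member_genes,
    effect: float = 0.5,
    enriched_set: str = "planted",
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-level association statistics with one planted enriched set.

    Non-members draw ``z ~ N(0, 1)``, members ``z ~ N(effect, 1)``; gene size
    (kb) is drawn independently of membership.  The member list must be a
    subset of the simulated gene universe.
    """
    if config.n_genes <= 0:
        raise ValueError("empty gene universe")
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    universe = set(gene_ids)
    if config.subtype_spec is not None:
        # symbols renamed by generate_counts remain resolvable
        for genes in config.subtype_spec.markers.values():
            universe |= set(genes)
    member = set(member_genes)
    if not member <= universe:
        raise ValueError("member genes outside the simulated gene universe")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    is_member = np.array([g in member for g in gene_ids])
    z = rng.normal(0.0, 1.0, config.n_genes) + effect * is_member
    gene_size = rng.lognormal(np.log(30.0), 0.8, config.n_genes)
    out = pd.DataFrame(
        {"gene": gene_ids, "z": z, "gene_size": gene_size, "member": is_member}
    )
    out.attrs["enriched_set"] = enriched_set
    out.attrs["effect"] = effect
    return out


def default_config(seed: int = 0) -> SimConfig:
    """The default 8-type, 2-batch, 5%-doublet study condition."""
    return SimConfig(seed=seed)


def two_platform_config(seed: int = 0) -> SimConfig:
    """Two platforms sharing the 8 planted types (cross-platform alignment)."""
    return SimConfig(platforms=2, seed=seed)


def subtype_config(seed: int = 0) -> SimConfig:
    """Adds the 3 macroglia-like subtypes with region-biased frequencies."""
    return SimConfig(subtype_spec=SubtypeSpec(), seed=seed)
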