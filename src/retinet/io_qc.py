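"""Count-matrix containers, 10x-style Matrix-Market I/O, QC filtering and depth
normalization.

The on-disk layout mirrors the 10x triplet convention: ``matrix.mtx`` (genes x
cells, 1-based indices), ``genes.tsv`` and ``barcodes.tsv`` sidecars, plus an
optional ``cell_metadata.tsv`` with one row per barcode.  In memory everything
is genes x cells with 0-based indexing.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "qc_filter",
    "depth_normalize",
]


@dataclass
class CountMatrix:
    """Sparse gene x cell count matrix with identifiers and per-cell metadata.

    Parameters
    ----------
    values : scipy.sparse matrix
        Nonnegative integer counts, rows = genes, columns = cells.
    gene_ids : array of str
        Unique gene symbols, one per row.
    cell_ids : array of str
        Unique cell barcodes, one per column.
    cell_meta : pandas.DataFrame, optional
        Per-cell table (e.g. sample, platform, region, batch) indexed like
        ``cell_ids``.
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != {n_cells} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene symbols (aggregate before constructing)")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="barcode"))
        else:
            self.cell_meta = self.cell_meta.copy()
            if len(self.cell_meta) != n_cells:
                raise ValueError("cell_meta row count does not match cell count")
            self.cell_meta.index = pd.Index(self.cell_ids, name="barcode")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new matrix restricted to the given boolean/index masks,
        preserving row/column order."""
        gm = np.arange(self.n_genes) if gene_mask is None else np.where(gene_mask)[0] \
            if np.asarray(gene_mask).dtype == bool else np.asarray(gene_mask)
        cm = np.arange(self.n_cells) if cell_mask is None else np.where(cell_mask)[0] \
            if np.asarray(cell_mask).dtype == bool else np.asarray(cell_mask)
        return CountMatrix(
            self.values[gm][:, cm],
            self.gene_ids[gm],
            self.cell_ids[cm],
            self.cell_meta.iloc[cm],
        )


@dataclass
class NormalizedMatrix:
    """log1p depth-normalized expression with the per-cell factors that produced it.

    ``values[g, c] = log1p(count[g, c] * depth_factors[c])`` so the raw counts
    are recoverable from the stored factors.
    """

    values: sp.spmatrix
    depth_factors: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.depth_factors = np.asarray(self.depth_factors, dtype=float)
        if np.any(self.depth_factors <= 0):
            raise ValueError("depth factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def write_mtx_triplet(m: CountMatrix, out_dir: str | os.PathLike) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` +
    ``cell_metadata.tsv`` under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    coo = sp.coo_matrix(m.values)
    # integer field keeps the round-trip exact
    mmwrite(os.path.join(out_dir, "matrix.mtx"), coo, field="integer")
    pd.Series(m.gene_ids).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(m.cell_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    m.cell_meta.to_csv(os.path.join(out_dir, "cell_metadata.tsv"), sep="\t")


def read_mtx_triplet(in_dir: str | os.PathLike) -> CountMatrix:
    """Read a triplet directory written by :func:`write_mtx_triplet` (or 10x-style
    exports).  Duplicate gene symbols are summed; duplicate barcodes are an error."""
    mtx_path = os.path.join(in_dir, "matrix.mtx")
    vals = sp.csr_matrix(mmread(mtx_path))
    genes = pd.read_csv(
        os.path.join(in_dir, "genes.tsv"), sep="\t", header=None
    )[0].astype(str).to_numpy()
    barcodes = pd.read_csv(
        os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str).to_numpy()
    if vals.shape[0] != len(genes):
        raise ValueError(
            f"matrix.mtx declares {vals.shape[0]} genes but genes.tsv has {len(genes)}"
        )
    if vals.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix.mtx declares {vals.shape[1]} cells but barcodes.tsv has "
            f"{len(barcodes)}"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcodes.tsv")
    if len(set(genes)) != len(genes):
        # 10x sidecars may repeat symbols; aggregate by summing rows
        frame = pd.DataFrame({"gene": genes})
        uniq, inv = np.unique(frame["gene"].to_numpy(), return_inverse=True)
        agg = sp.csr_matrix(
            (np.ones(len(genes)), (inv, np.arange(len(genes)))),
            shape=(len(uniq), len(genes)),
        )
        vals = agg @ vals
        genes = uniq.astype(object)
    meta_path = os.path.join(in_dir, "cell_metadata.tsv")
    meta = None
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(vals, genes, barcodes, meta)


def qc_filter(
    m: CountMatrix,
    min_genes_per_cell: int = 300,
    min_cells_per_gene: int = 10,
) -> CountMatrix:
    """Joint gene/cell detection filter, iterated to a fixed point.

    Every retained cell detects (count > 0) at least ``min_genes_per_cell`` of
    the retained genes, and every retained gene is detected in at least
    ``min_cells_per_gene`` of the retained cells.  The two rules are alternated
    until neither removes anything, because a single pass of either rule can
    re-violate the other; iteration makes the filter idempotent.  Row/column
    order is preserved.  An empty result is returned (with a warning), never
    raised.
    """
    binary = sp.csr_matrix(m.values, copy=True)
    binary.data = (binary.data > 0).astype(np.int64)
    gene_keep = np.ones(m.n_genes, dtype=bool)
    cell_keep = np.ones(m.n_cells, dtype=bool)
    binary_csc = binary.tocsc()
    while True:
        genes_per_cell = np.asarray(
            binary[gene_keep][:, cell_keep].sum(axis=0)
        ).ravel()
        new_cell = cell_keep.copy()
        new_cell[cell_keep] = genes_per_cell >= min_genes_per_cell
        cells_per_gene = np.asarray(
            binary_csc[:, new_cell][gene_keep].sum(axis=1)
        ).ravel()
        new_gene = gene_keep.copy()
        new_gene[gene_keep] = cells_per_gene >= min_cells_per_gene
        if new_cell.sum() == cell_keep.sum() and new_gene.sum() == gene_keep.sum():
            break
        cell_keep, gene_keep = new_cell, new_gene
        if not cell_keep.any() or not gene_keep.any():
            break
    if not cell_keep.any() or not gene_keep.any():
        warnings.warn("qc_filter removed every gene or cell; returning empty matrix")
        gene_keep = np.zeros(m.n_genes, dtype=bool)
        cell_keep = np.zeros(m.n_cells, dtype=bool)
    return m.subset(gene_keep, cell_keep)


def depth_normalize(
    m: CountMatrix, target_depth: str | float = "median"
) -> NormalizedMatrix:
    """Scale each cell to a common depth and log1p-transform.

    ``depth_factor_i = target / total_i`` with ``target`` the median library
    size by default.  Raises if any cell has zero total counts (cannot occur
    after :func:`qc_filter` with positive thresholds), naming the barcode.
    """
    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        bad = m.cell_ids[np.where(totals <= 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero total counts; run qc_filter first")
    target = float(np.median(totals)) if target_depth == "median" else float(target_depth)
    factors = target / totals
    scaled = sp.csr_matrix(m.values, dtype=float)
    scaled = scaled @ sp.diags(factors)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(scaled, factors, m.gene_ids, m.cell_ids, m.cell_meta)
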