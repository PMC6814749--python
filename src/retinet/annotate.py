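"""Marker-based cell annotation.

Each curated marker gene's normalized expression is imputed over the cell
network by a restart random walk, z-scaled across cells, and averaged within
each cell type to give a per-cell association score.  A permutation test with
expression-frequency-matched random gene sets turns scores into empirical
p-values; cells significant for no type or for more than one type are filtered
(the latter as doublet suspects), and a final neighborhood-coherence test flags
cells whose network neighbors are not enriched for the same label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.stats import hypergeom

from .archnet import CellNetwork
from .io_qc import NormalizedMatrix

__all__ = [
    "RETINA_MARKERS",
    "CellAnnotation",
    "diffuse",
    "score_cell_types",
    "permutation_test",
    "assign",
    "coherence_filter",
    "annotate_cells",
    "read_marker_tsv",
]

UNASSIGNED_NONE = "unassigned_none"
UNASSIGNED_MULTI = "unassigned_multi"
INCOHERENT = "incoherent_neighborhood"
FILTER_CODES = (UNASSIGNED_NONE, UNASSIGNED_MULTI, INCOHERENT)

#: Curated panel of known retinal cell-type markers.
RETINA_MARKERS = {
    "rods": ["PDE6A", "PPEF2", "NR2E3"],
    "cones": ["GNAT2", "OPN1SW", "OPN1MW", "OPN1LW"],
    "RGC": ["NEFM", "SLC17A6"],
    "bipolar": ["CAMK2B", "GRM6", "TMEM215", "TRPM1"],
    "amacrine": ["GAD1", "C1QL2"],
    "horizontal": ["ONECUT1", "ONECUT2", "LHX1"],
    "macroglia": ["GLUL", "CLU", "APOE"],
    "microglia": ["C1QA", "TMEM119", "AIF1", "CD163"],
    "vascular": ["CD34", "CDH5", "RGS5", "ADAMTS9"],
}


@dataclass
class CellAnnotation:
    score: pd.DataFrame    # cells x types association scores
    perm_p: pd.DataFrame   # cells x types BH-adjusted empirical p
    label: pd.Series       # assigned type or filter code


def read_marker_tsv(path) -> dict:
    """Two-column (cell_type, gene) TSV into a marker mapping."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "gene"])
    return {t: list(g["gene"]) for t, g in tab.groupby("cell_type", sort=False)}


class _Diffuser:
    """Factorized restart-random-walk operator ``(1-a)(I - a P)^{-1}`` for a
    fixed network; reusable across many right-hand sides."""

    def __init__(self, net: CellNetwork, alpha: float):
        if not 0 <= alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        self.alpha = alpha
        A = sp.csr_matrix(net.adjacency, dtype=float)
        deg = np.asarray(A.sum(axis=0)).ravel()
        isolated = deg == 0
        # isolated nodes keep their own value: transition column = self loop
        P = A @ sp.diags(np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, deg)))
        if isolated.any():
            P = P + sp.diags(isolated.astype(float))
        n = A.shape[0]
        self._lu = splu(sp.csc_matrix(sp.eye(n) - alpha * P))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.alpha == 0:
            return x.copy()
        one_d = x.ndim == 1
        X = x[:, None] if one_d else x
        out = (1 - self.alpha) * self._lu.solve(np.ascontiguousarray(X))
        return out[:, 0] if one_d else out


def diffuse(net: CellNetwork, x: np.ndarray, alpha: float = 0.85) -> np.ndarray:
    """Impute a per-cell nonnegative vector over the network.

    Solves ``s = (1 - alpha) (I - alpha P)^{-1} x`` with ``P`` the
    column-stochastic transition matrix; the total mass ``sum(s) == sum(x)``
    is conserved.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != net.n_cells:
        raise ValueError("vector not aligned with network nodes")
    if (x < 0).any():
        raise ValueError("diffusion input must be nonnegative")
    return _Diffuser(net, alpha)(x)


def _zscale_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    # sd at round-off scale is zero variance (e.g. a constant vector passed
    # through the linear solver), not signal
    ok = sd > 1e-10 * np.maximum(np.abs(mu), 1e-30)
    out = np.zeros_like(M)
    np.divide(M - mu, sd, out=out, where=ok)
    return out


def _match_markers(markers: dict, gene_ids) -> dict:
    index = {g: i for i, g in enumerate(gene_ids)}
    matched = {}
    for t, genes in markers.items():
        rows = [index[g] for g in genes if g in index]
        missing = [g for g in genes if g not in index]
        if missing:
            warnings.warn(f"markers not found for {t}: {missing}")
        if rows:
            matched[t] = np.array(rows)
        else:
            warnings.warn(f"cell type {t} has no matched markers; excluded")
    return matched


def _diffused_z(net, nm, alpha):
    """Diffuse every gene's normalized expression and z-scale across cells."""
    X = nm.dense()
    imputed = _Diffuser(net, alpha)(X.T).T
    return _zscale_rows(imputed)


def score_cell_types(net: CellNetwork, nm: NormalizedMatrix, markers: dict,
                     alpha: float = 0.85, _z: np.ndarray | None = None
                     ) -> pd.DataFrame:
    """Per-cell per-type association scores: the mean, over a type's matched
    markers, of the diffused and z-scaled marker expression."""
    matched = _match_markers(markers, nm.gene_ids)
    if not matched:
        raise ValueError("no cell type has any matched marker gene")
    Z = _diffused_z(net, nm, alpha) if _z is None else _z
    scores = {t: Z[rows].mean(axis=0) for t, rows in matched.items()}
    return pd.DataFrame(scores, index=nm.cell_ids)


def _bh_adjust_rows(P: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg along axis 1 (per cell, across types)."""
    n, m = P.shape
    order = np.argsort(P, axis=1)
    ranked = np.take_along_axis(P, order, axis=1)
    adj = ranked * m / np.arange(1, m + 1)[None, :]
    adj = np.minimum.accumulate(adj[:, ::-1], axis=1)[:, ::-1]
    out = np.empty_like(P)
    np.put_along_axis(out, order, np.clip(adj, 0, 1), axis=1)
    return out


def permutation_test(net: CellNetwork, nm: NormalizedMatrix, markers: dict,
                     alpha: float = 0.85, n_perm: int = 1000, seed: int = 0,
                     n_bins: int = 10):
    """Empirical significance of association scores against random gene sets.

    Null sets match each marker's expression frequency (genes binned into
    ``n_bins`` detection-rate bins); ``p = (1 + #{null >= obs}) / (1 + n_perm)``
    followed by per-cell BH adjustment across types.  Returns
    ``(scores, adjusted_p)`` as aligned DataFrames.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    matched = _match_markers(markers, nm.gene_ids)
    if not matched:
        raise ValueError("no cell type has any matched marker gene")
    rng = np.random.default_rng(seed)
    Z = _diffused_z(net, nm, alpha)
    detect = np.asarray((nm.values > 0).sum(axis=1)).ravel() / nm.n_cells
    edges = np.quantile(detect, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, detect, side="right")
    bin_members = {b: np.where(bins == b)[0] for b in np.unique(bins)}
    types = list(matched)
    n_cells = nm.n_cells
    obs = np.stack([Z[matched[t]].mean(axis=0) for t in types])
    exceed = np.zeros((len(types), n_cells))
    for ti, t in enumerate(types):
        rows = matched[t]
        if any(len(bin_members[b]) < 2 for b in np.unique(bins[rows])):
            raise ValueError("fewer eligible genes than marker-set size in a bin")
        draw = np.stack(
            [rng.choice(bin_members[bins[r]], size=n_perm) for r in rows]
        )  # markers x n_perm
        null = Z[draw].mean(axis=0)  # n_perm x cells
        exceed[ti] = (null >= obs[ti][None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p_adj = _bh_adjust_rows(p.T)
    scores = pd.DataFrame(obs.T, index=nm.cell_ids, columns=types)
    perm_p = pd.DataFrame(p_adj, index=nm.cell_ids, columns=types)
    return scores, perm_p


def assign(scores: pd.DataFrame, perm_p: pd.DataFrame,
           sig_threshold: float = 0.05) -> pd.Series:
    """Label each cell by its single significant type, or a filter code:
    no significant type -> ``unassigned_none``; more than one (doublet
    suspects) -> ``unassigned_multi``; exactly one -> that type."""
    sig = perm_p.to_numpy() < sig_threshold
    n_sig = sig.sum(axis=1)
    # among significant types the argmax score (with exactly one significant
    # type this is that type)
    masked = np.where(sig, scores.to_numpy(), -np.inf)
    best = np.asarray(scores.columns)[np.argmax(masked, axis=1)]
    labels = np.where(
        n_sig == 0, UNASSIGNED_NONE, np.where(n_sig > 1, UNASSIGNED_MULTI, best)
    )
    return pd.Series(labels, index=scores.index, name="label")


def coherence_filter(net: CellNetwork, labels: pd.Series,
                     alpha_test: float = 0.05) -> pd.Series:
    """Flag assigned cells whose network neighborhood is not enriched for
    their own label (one-sided hypergeometric, BH-adjusted across cells).

    Population: all assigned cells; success states: cells sharing the label;
    draws: the cell's assigned neighbors.  Cells with no assigned neighbor are
    flagged by convention.  A cell whose same-label neighbor fraction meets or
    exceeds the label's global frequency is never flagged: enrichment beyond
    chance is impossible to certify for saturated labels (e.g. a one-label
    graph), yet such neighborhoods are maximally coherent.
    """
    labels = labels.copy()
    lab = labels.to_numpy(dtype=object)
    assigned = ~np.isin(lab, FILTER_CODES)
    N = int(assigned.sum())
    A = net.adjacency
    counts = pd.Series(lab[assigned]).value_counts()
    pvals, idx = [], []
    flag_now = []
    for i in np.where(assigned)[0]:
        nbrs = A.indices[A.indptr[i]:A.indptr[i + 1]]
        nbrs = nbrs[assigned[nbrs]]
        if len(nbrs) == 0:
            flag_now.append(i)
            continue
        K = int(counts[lab[i]])
        k_same = int((lab[nbrs] == lab[i]).sum())
        if N > 1 and k_same / len(nbrs) >= (K - 1) / (N - 1):
            continue  # at or above the expected frequency: coherent
        pvals.append(hypergeom.sf(k_same - 1, N - 1, K - 1, len(nbrs)))
        idx.append(i)
    if pvals:
        pvals = np.asarray(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        adj = pvals[order] * m / np.arange(1, m + 1)
        adj = np.minimum(np.minimum.accumulate(adj[::-1])[::-1], 1.0)
        p_adj = np.empty(m)
        p_adj[order] = adj
        for j, i in enumerate(idx):
            if p_adj[j] >= alpha_test:
                labels.iloc[i] = INCOHERENT
    for i in flag_now:
        labels.iloc[i] = INCOHERENT
    return labels


def annotate_cells(net: CellNetwork, nm: NormalizedMatrix, markers: dict,
                   alpha: float = 0.85, n_perm: int = 1000, seed: int = 0,
                   sig_threshold: float = 0.05, coherence_alpha: float = 0.05
                   ) -> CellAnnotation:
    """Full annotation: scores, permutation p-values, assignment, and the
    neighborhood-coherence filter."""
    scores, perm_p = permutation_test(
        net, nm, markers, alpha=alpha, n_perm=n_perm, seed=seed
    )
    labels = assign(scores, perm_p, sig_threshold=sig_threshold)
    labels = coherence_filter(net, labels, alpha_test=coherence_alpha)
    return CellAnnotation(score=scores, perm_p=perm_p, label=labels)
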