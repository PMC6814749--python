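"""Multiresolution archetypal decomposition, the sqrt-Jensen-Shannon cell metric,
and the k*-adaptive nearest-neighbor cell network.

The decomposition approximates ``S ~= S C H`` where ``S`` is the reduced
(cells in d-dimensional SVD space) profile, ``C`` (cells x k, column
stochastic) mixes cells into k archetypes, and ``H`` (k x cells, column
stochastic) gives each cell's footprint over archetypes.  Decompositions at
increasing depth k are stacked into a ladder; concatenated, renormalized
footprints form per-cell probability vectors compared with the square root of
the base-2 Jensen-Shannon divergence (a metric bounded by 1), and the cell
network keeps, per cell, an adaptively chosen number of nearest neighbors.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd

from .io_qc import NormalizedMatrix

__all__ = [
    "ReducedProfile",
    "ArchetypeLadder",
    "CellNetwork",
    "reduce_profile",
    "ArchetypalAnalysis",
    "action_decompose",
    "build_ladder",
    "cell_profiles",
    "js_distance",
    "pairwise_js",
    "build_kstar_nn",
    "layout",
    "select_dimension",
    "leiden_cluster",
]


# ---------------------------------------------------------------- containers

@dataclass
class ReducedProfile:
    """Truncated SVD of the gene-centered expression: ``basis @ scores.T``
    approximates the centered matrix."""

    scores: np.ndarray          # cells x d  (V @ Sigma)
    basis: np.ndarray           # genes x d  (U), columns orthonormal
    singular_values: np.ndarray
    gene_means: np.ndarray
    gene_ids: np.ndarray = None
    cell_ids: np.ndarray = None


@dataclass
class ArchetypeLadder:
    """Per-depth decompositions: ``C[k]`` cells x k, ``H[k]`` k x cells, both
    column stochastic; ``errors[k]`` the Frobenius residual."""

    C: dict = field(default_factory=dict)
    H: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    @property
    def depths(self):
        return sorted(self.C)


@dataclass
class CellNetwork:
    adjacency: sp.csr_matrix      # symmetric, zero diagonal, weights in (0, 1]
    cell_ids: np.ndarray = None
    coords: np.ndarray = None     # optional 2-D layout

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray((self.adjacency > 0).sum(axis=1)).ravel()

    def to_igraph(self) -> ig.Graph:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        g = ig.Graph(
            n=self.n_cells,
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        return g


# ------------------------------------------------------------------- reduce

def reduce_profile(nm: NormalizedMatrix | np.ndarray, d: int = 50,
                   random_state: int = 0) -> ReducedProfile:
    """Rank-d truncated SVD of the gene-centered normalized matrix."""
    if isinstance(nm, NormalizedMatrix):
        X = nm.dense()
        gene_ids, cell_ids = nm.gene_ids, nm.cell_ids
    else:
        X = np.asarray(nm, dtype=float)
        gene_ids = cell_ids = None
    n_genes, n_cells = X.shape
    if d > min(n_genes, n_cells):
        raise ValueError(f"d={d} exceeds min(n_genes, n_cells)={min(n_genes, n_cells)}")
    means = X.mean(axis=1)
    U, S, Vt = randomized_svd(
        X - means[:, None], n_components=d, n_iter=7, random_state=random_state
    )
    return ReducedProfile(
        scores=(Vt.T * S), basis=U, singular_values=S,
        gene_means=means, gene_ids=gene_ids, cell_ids=cell_ids,
    )


# ------------------------------------------------------- archetypal analysis

def _project_simplex_cols(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of every column of V onto the probability simplex."""
    m = V.shape[0]
    U = -np.sort(-V, axis=0)
    css = np.cumsum(U, axis=0) - 1.0
    ind = np.arange(1, m + 1)[:, None]
    cond = U - css / ind > 0
    rho = np.maximum(cond.sum(axis=0), 1)
    theta = css[rho - 1, np.arange(V.shape[1])] / rho
    return np.maximum(V - theta, 0.0)


def _fps_indices(X: np.ndarray, k: int, start: int) -> np.ndarray:
    """Furthest-point sampling over rows of X, beginning at ``start``."""
    n = X.shape[0]
    chosen = [start]
    dmin = np.linalg.norm(X - X[start], axis=1)
    for _ in range(1, min(k, n)):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(X - X[nxt], axis=1))
    return np.array(chosen[:k])


class ArchetypalAnalysis(BaseEstimator, TransformerMixin):
    """Archetypal analysis with simplex-constrained block projected gradient.

    Fits ``X.T ~= (X.T @ C) @ H`` for cell matrix ``X`` (cells x d), with C and
    H column stochastic.  Initialization spreads candidate archetypes by
    furthest-point sampling; ``n_restarts`` independent starts are run and the
    best kept (ties broken by lowest restart index).  Updates use 1/L gradient
    steps with exact simplex projection, so the objective is non-increasing.

    Attributes
    ----------
    archetypes_ : (n_archetypes, d) archetype coordinates ``(X.T @ C_).T``
    C_ : (cells, n_archetypes) column-stochastic cell weights
    H_ : (n_archetypes, cells) column-stochastic footprints
    reconstruction_err_ : Frobenius residual of the best restart
    converged_ : False when the iteration cap was hit before the tolerance
    """

    def __init__(self, n_archetypes=8, max_iter=60, n_inner=20, tol=1e-5,
                 n_restarts=3, random_state=None):
        self.n_archetypes = n_archetypes
        self.max_iter = max_iter
        self.n_inner = n_inner
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # S is d x n internally
    def _solve_H(self, Z, S, H):
        G = Z.T @ Z
        L = max(np.linalg.norm(G, 2), 1e-12)
        ZtS = Z.T @ S
        for _ in range(self.n_inner):
            H = _project_simplex_cols(H - (G @ H - ZtS) / L)
        return H

    def _fit_single(self, S, k, C, H, s1sq):
        prev = np.inf
        err = prev
        converged = False
        for _ in range(self.max_iter):
            Z = S @ C
            H = self._solve_H(Z, S, H)
            HHt = H @ H.T
            L_C = max(s1sq * np.linalg.norm(HHt, 2), 1e-12)
            SHt = S @ H.T
            for _ in range(self.n_inner):
                W = S @ C
                grad = S.T @ (W @ HHt - SHt)
                C = _project_simplex_cols(C - grad / L_C)
            R = S - (S @ C) @ H
            err = np.linalg.norm(R)
            if prev - err <= self.tol * max(prev, 1.0):
                converged = True
                break
            prev = err
        return C, H, err, converged

    def _init(self, S, k, start):
        n = S.shape[1]
        idx = _fps_indices(S.T, k, start)
        C = np.zeros((n, k))
        C[idx, np.arange(len(idx))] = 1.0
        Z = S @ C
        d2 = ((S.T[:, None, :] - Z.T[None, :, :]) ** 2).sum(-1) if n * k <= 2_000_000 \
            else None
        H = np.zeros((k, n))
        if d2 is not None:
            H[np.argmin(d2, axis=1), np.arange(n)] = 1.0
        else:
            # memory-light nearest archetype
            nn = np.argmin(
                (S.T @ Z) * -2 + (Z * Z).sum(0)[None, :], axis=1
            )
            H[nn, np.arange(n)] = 1.0
        return C, H

    def fit(self, X, y=None, warm_start=None):
        """Fit on cells-x-d matrix ``X``.  ``warm_start=(C0, H0)`` adds one
        extra candidate initialization (used by the ladder)."""
        X = np.asarray(X, dtype=float)
        S = X.T
        k = int(self.n_archetypes)
        if k < 1:
            raise ValueError("n_archetypes must be >= 1")
        n = S.shape[1]
        rng = np.random.default_rng(self.random_state)
        s1sq = np.linalg.norm(S, 2) ** 2
        best = None
        starts = []
        centroid_far = int(np.argmax(np.linalg.norm(S.T - S.T.mean(0), axis=1)))
        for r in range(max(self.n_restarts, 1)):
            starts.append(centroid_far if r == 0 else int(rng.integers(n)))
        inits = [self._init(S, k, s) for s in starts]
        if warm_start is not None:
            C0, H0 = warm_start
            inits.append((C0.copy(), H0.copy()))
        for C0, H0 in inits:
            C, H, err, conv = self._fit_single(S, k, C0, H0, s1sq)
            if best is None or err < best[2] - 1e-12:
                best = (C, H, err, conv)
        C, H, err, conv = best
        self.C_, self.H_ = C, H
        self.archetypes_ = (S @ C).T
        self.reconstruction_err_ = float(err)
        self.converged_ = bool(conv)
        return self

    def transform(self, X):
        """Footprints (cells x k) of new cells over the fitted archetypes."""
        S = np.asarray(X, dtype=float).T
        Z = self.archetypes_.T
        n = S.shape[1]
        H = np.full((self.n_archetypes, n), 1.0 / self.n_archetypes)
        G = Z.T @ Z
        L = max(np.linalg.norm(G, 2), 1e-12)
        ZtS = Z.T @ S
        for _ in range(200):
            H_new = _project_simplex_cols(H - (G @ H - ZtS) / L)
            if np.abs(H_new - H).max() < 1e-10:
                H = H_new
                break
            H = H_new
        return H.T


def action_decompose(rp: ReducedProfile, k: int, restarts: int = 3,
                     seed: int | None = 0, warm_start=None):
    """Best-of-restarts archetypal decomposition at depth ``k``; returns
    ``(C, H)`` with C cells x k and H k x cells, both column stochastic."""
    if k < 2:
        raise ValueError("k must be >= 2")
    aa = ArchetypalAnalysis(n_archetypes=k, n_restarts=restarts, random_state=seed)
    aa.fit(rp.scores, warm_start=warm_start)
    return aa.C_, aa.H_, aa.reconstruction_err_


def build_ladder(rp: ReducedProfile, k_min: int = 2, k_max: int = 30,
                 restarts: int = 3, seed: int = 0) -> ArchetypeLadder:
    """Independent decompositions for every depth k in [k_min, k_max].

    Besides fresh spread-out restarts, depth k warm-starts from the depth k-1
    solution extended by one indicator archetype (the worst-reconstructed
    cell), which reproduces the previous residual exactly before optimization;
    together with monotone updates this makes the recorded reconstruction
    error non-increasing in k.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    ladder = ArchetypeLadder()
    prev = None
    S = rp.scores.T
    for k in range(k_min, k_max + 1):
        warm = None
        if prev is not None:
            C0, H0 = prev
            resid = S - (S @ C0) @ H0
            worst = int(np.argmax((resid**2).sum(axis=0)))
            C_ext = np.hstack([C0, np.zeros((C0.shape[0], 1))])
            C_ext[worst, -1] = 1.0
            H_ext = np.vstack([H0, np.zeros((1, H0.shape[1]))])
            warm = (C_ext, H_ext)
        C, H, err = action_decompose(rp, k, restarts=restarts, seed=seed + k,
                                     warm_start=warm)
        ladder.C[k], ladder.H[k], ladder.errors[k] = C, H, err
        prev = (C, H)
    return ladder


def cell_profiles(ladder: ArchetypeLadder) -> np.ndarray:
    """Concatenate every depth's footprints per cell and renormalize to a
    probability vector (cells x total_archetypes)."""
    if not ladder.C:
        raise ValueError("empty ladder")
    P = np.vstack([ladder.H[k] for k in ladder.depths]).T
    s = P.sum(axis=1, keepdims=True)
    assert np.all(s > 0), "column-stochastic footprints cannot be all-zero"
    return P / s


# ------------------------------------------------------------------- metric

_LN2 = float(np.log(2.0))


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def js_distance(p, q) -> float:
    """Square root of the base-2 Jensen-Shannon divergence; a metric in [0, 1].

    ``JSD(p, q) = H((p+q)/2) - (H(p) + H(q)) / 2`` in bits, with 0 log 0 := 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries in probability vector")
    jsd = _entropy2((p + q) / 2) - 0.5 * (_entropy2(p) + _entropy2(q))
    return float(np.sqrt(max(jsd, 0.0)))


def pairwise_js(P: np.ndarray, Q: np.ndarray | None = None) -> np.ndarray:
    """All-pairs sqrt-JS distances (base 2) between rows of probability
    matrices, via the compiled nat-log kernel rescaled by 1/sqrt(ln 2)."""
    Q = P if Q is None else Q
    D = cdist(P, Q, metric="jensenshannon") / np.sqrt(_LN2)
    return np.clip(np.nan_to_num(D, nan=0.0), 0.0, 1.0)


# ------------------------------------------------------------------ network

def _kstar_counts(dist_sorted: np.ndarray, lam: float) -> np.ndarray:
    """Per-row adaptive neighbor counts from ascending sorted distances.

    Row by row, neighbors are admitted while the next distance stays below the
    running threshold beta_j = (sum_j + sqrt(j*lam + sum_j^2 - j*sumsq_j)) / j.
    """
    n, m = dist_sorted.shape
    cs = np.cumsum(dist_sorted, axis=1)
    cs2 = np.cumsum(dist_sorted**2, axis=1)
    j = np.arange(1, m + 1)[None, :]
    arg = j * lam + cs**2 - j * cs2
    with np.errstate(invalid="ignore"):
        beta = (cs + np.sqrt(np.maximum(arg, 0.0))) / j
    beta[arg < 0] = -np.inf
    # neighbor j+1 admitted iff d_{j+1} <= beta_j
    admit = dist_sorted[:, 1:] <= beta[:, :-1]
    stop = np.argmin(admit, axis=1)  # first rejection
    k = np.where(admit.all(axis=1), m, stop + 1)
    return k


def build_kstar_nn(profiles: np.ndarray, max_k: int | None = None,
                   lam: float = 1.0, dist: np.ndarray | None = None,
                   cell_ids=None) -> CellNetwork:
    """k*-adaptive nearest-neighbor network in the sqrt-JS metric space.

    Each cell keeps its nearest neighbors up to the adaptive cutoff (at most
    ``max_k``, default ``2 * ceil(sqrt(n))``); the directed graph is
    symmetrized by union and edges are weighted ``1 - distance`` (edges with
    nonpositive weight are dropped).
    """
    if dist is None:
        profiles = np.asarray(profiles, dtype=float)
        n = profiles.shape[0]
        if n < 2:
            raise ValueError("need at least 2 cells")
        dist = pairwise_js(profiles)
    else:
        n = dist.shape[0]
    if max_k is None:
        max_k = int(2 * np.ceil(np.sqrt(n)))
    max_k = int(min(max(max_k, 1), n - 1))
    D = dist.copy()
    np.fill_diagonal(D, np.inf)
    nbr = np.argpartition(D, max_k - 1, axis=1)[:, :max_k]
    nbr_d = np.take_along_axis(D, nbr, axis=1)
    order = np.argsort(nbr_d, axis=1, kind="stable")
    nbr = np.take_along_axis(nbr, order, axis=1)
    nbr_d = np.take_along_axis(nbr_d, order, axis=1)
    kcounts = _kstar_counts(nbr_d, lam)
    rows, cols, vals = [], [], []
    for i in range(n):
        k = kcounts[i]
        rows.append(np.full(k, i))
        cols.append(nbr[i, :k])
        vals.append(1.0 - nbr_d[i, :k])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    keep = vals > 0
    A = sp.csr_matrix((vals[keep], (rows[keep], cols[keep])), shape=(n, n))
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    return CellNetwork(adjacency=A.tocsr(), cell_ids=cell_ids)


def layout(net: CellNetwork, seed: int = 0, n_iter: int = 500) -> np.ndarray:
    """Force-directed 2-D embedding of the cell network (cosmetic only)."""
    if net.n_cells == 0:
        return np.zeros((0, 2))
    g = net.to_igraph()
    _pyrandom.seed(seed)
    lay = g.layout_fruchterman_reingold(
        niter=n_iter, weights=g.es["weight"] if g.ecount() else None
    )
    coords = np.asarray(lay.coords, dtype=float)
    net.coords = coords
    return coords


def select_dimension(nm, d_max: int = 30, n_perm: int = 2, seed: int = 0,
                     margin: float = 1.02, d_min: int = 2) -> int:
    """Permutation (parallel-analysis) choice of the reduced dimension.

    Keeps components whose singular value exceeds the top singular value of
    the same matrix with every gene's values independently permuted (times a
    small ``margin``), i.e. dimensions not explainable by unstructured noise.
    """
    from .io_qc import NormalizedMatrix as _NM

    X = nm.dense() if isinstance(nm, _NM) else np.asarray(nm, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    d_max = min(d_max, min(Xc.shape) - 1)
    _, S, _ = randomized_svd(Xc, n_components=d_max, n_iter=7, random_state=seed)
    rng = np.random.default_rng(seed)
    tops = []
    for _ in range(n_perm):
        idx = rng.permuted(
            np.tile(np.arange(Xc.shape[1]), (Xc.shape[0], 1)), axis=1
        )
        Xp = np.take_along_axis(Xc, idx, axis=1)
        tops.append(randomized_svd(Xp, n_components=1, n_iter=4,
                                   random_state=seed)[1][0])
    thr = float(np.mean(tops)) * margin
    return int(min(max((S > thr).sum(), d_min), d_max))


def leiden_cluster(net: CellNetwork, resolution: float | None = None,
                   n_clusters: int | None = None, seed: int = 0) -> np.ndarray:
    """Leiden clustering of the cell network; returns integer labels ordered
    by decreasing cluster size.

    With ``n_clusters`` given, the resolution parameter is bisected until the
    partition has that many clusters (best effort); otherwise plain modularity
    (optionally at a fixed ``resolution``) is used.
    """
    g = net.to_igraph()
    weights = "weight" if g.ecount() else None
    if n_clusters is not None:
        if n_clusters == 1:
            return np.zeros(net.n_cells, dtype=int)
        lo, hi = 1e-4, 50.0
        part = None
        for _ in range(40):
            mid = float(np.sqrt(lo * hi))
            part = leidenalg.find_partition(
                g, leidenalg.RBConfigurationVertexPartition, weights=weights,
                resolution_parameter=mid, seed=seed,
            )
            nc = len(set(part.membership))
            if nc == n_clusters:
                break
            if nc < n_clusters:
                lo = mid
            else:
                hi = mid
    elif resolution is not None:
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, weights=weights,
            resolution_parameter=resolution, seed=seed,
        )
    else:
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights=weights, seed=seed
        )
    labels = np.asarray(part.membership)
    order = np.argsort([-np.sum(labels == c) for c in range(labels.max() + 1)],
                       kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(c)] for c in labels])
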