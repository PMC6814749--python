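"""Mutual-nearest-neighbor batch correction in reduced space.

Batches are merged one at a time (largest first by default).  Mutual k-NN
pairs between the current reference and the incoming batch define per-pair
correction vectors (reference minus incoming); each incoming cell is shifted
by the Gaussian-kernel-weighted average of those vectors, with the bandwidth
set adaptively to the batch's mean distance to its k-th within-batch neighbor.
Coordinates are cosine-normalized internally by default, as in the original
method.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

__all__ = ["mnn_correct", "mutual_pairs"]


def _cosine_norm(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def mutual_pairs(ref: np.ndarray, new: np.ndarray, k: int):
    """Indices (i_ref, j_new) of mutual k-nearest-neighbor pairs."""
    k_ref = min(k, len(ref))
    k_new = min(k, len(new))
    nn_in_ref = NearestNeighbors(n_neighbors=k_ref).fit(ref).kneighbors(
        new, return_distance=False
    )
    nn_in_new = NearestNeighbors(n_neighbors=k_new).fit(new).kneighbors(
        ref, return_distance=False
    )
    in_new_sets = [set(row) for row in nn_in_new]
    pairs = [
        (int(i), int(j))
        for j, row in enumerate(nn_in_ref)
        for i in row
        if j in in_new_sets[i]
    ]
    if not pairs:
        return np.empty(0, int), np.empty(0, int)
    arr = np.asarray(pairs)
    return arr[:, 0], arr[:, 1]


def mnn_correct(coords: np.ndarray, batch, k: int = 20, sigma: float | None = None,
                order="by_size", cosine_norm: bool = True,
                seed: int | None = None) -> np.ndarray:
    """Batch-corrected coordinates (cells x d), reference batch unchanged.

    ``order`` is either ``"by_size"`` (descending batch size, the largest
    batch as reference) or an explicit sequence of batch labels.  A batch with
    no mutual pairs is appended uncorrected with a warning.  A single batch is
    returned exactly as given.
    """
    coords = np.asarray(coords, dtype=float)
    batch = np.asarray(batch)
    levels = list(dict.fromkeys(batch.tolist()))
    if len(levels) <= 1:
        return coords.copy()
    if coords.shape[1] < 2:
        raise ValueError("need at least 2 dimensions")
    if order == "by_size":
        sizes = {b: int((batch == b).sum()) for b in levels}
        # descending size; stable tie-break on first appearance
        levels = sorted(levels, key=lambda b: (-sizes[b], levels.index(b)))
    else:
        if set(order) != set(levels):
            raise ValueError("order must enumerate every batch label")
        levels = list(order)
    X = _cosine_norm(coords) if cosine_norm else coords.copy()
    out = X.copy()
    ref_idx = np.where(batch == levels[0])[0]
    for b in levels[1:]:
        new_idx = np.where(batch == b)[0]
        ref = out[ref_idx]
        new = out[new_idx]
        i_ref, j_new = mutual_pairs(ref, new, k)
        if len(i_ref) == 0:
            warnings.warn(f"batch {b!r}: no mutual pairs; appended uncorrected")
            ref_idx = np.concatenate([ref_idx, new_idx])
            continue
        vecs = ref[i_ref] - new[j_new]
        if sigma is None:
            kk = min(k, len(new) - 1)
            if kk >= 1:
                d = NearestNeighbors(n_neighbors=kk + 1).fit(new).kneighbors(new)[0]
                sig = float(d[:, -1].mean())
            else:
                sig = 1.0
        else:
            sig = float(sigma)
        sig = max(sig, 1e-12)
        anchors = new[j_new]
        shift = np.empty_like(new)
        for s in range(0, len(new), 2048):
            d2 = cdist(new[s:s + 2048], anchors, metric="sqeuclidean")
            w = np.exp(-d2 / (2 * sig**2))
            w_sum = w.sum(axis=1, keepdims=True)
            w_sum[w_sum == 0] = 1.0
            shift[s:s + 2048] = (w / w_sum) @ vecs
        out[new_idx] = new + shift
        ref_idx = np.concatenate([ref_idx, new_idx])
    return out
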