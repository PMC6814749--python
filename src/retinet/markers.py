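"""Discriminating-power signatures, one-sided Wilcoxon marker selection with an
exclusivity rule, top-N ranking, and cross-platform partial-correlation
alignment of cell-type signatures.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .archnet import ReducedProfile
from .io_qc import NormalizedMatrix

__all__ = [
    "signature_profiles",
    "ranksum_one_sided",
    "ranksum_exact_p",
    "wilcoxon_markers",
    "rank_top",
    "partial_correlation",
    "cross_platform_alignment",
]

# exact enumeration range for the one-sided rank-sum test
_EXACT_MIN = 8
_EXACT_TOTAL = 25


# ------------------------------------------------------------- rank-sum core

def ranksum_exact_p(x, y) -> tuple[float, float]:
    """Exact one-sided (x > y) rank-sum p by enumerating every assignment of
    the pooled observations into the two groups.  Handles ties through
    midranks.  Returns ``(p, auc)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n2 = len(x), len(y)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    total = comb(n1 + n2, n1)
    idx = np.array(list(combinations(range(n1 + n2), n1)))
    u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2
    p = float((u_all >= u_obs - 1e-9).sum() / total)
    return p, float(u_obs / (n1 * n2))


def _tie_terms(X: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over tied groups (for the variance correction)."""
    Xs = np.sort(X, axis=1)
    n = X.shape[1]
    same = np.hstack([np.zeros((X.shape[0], 1), bool), Xs[:, 1:] == Xs[:, :-1]])
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        # run lengths of tied values
        boundaries = np.flatnonzero(~same[i])
        t = np.diff(np.append(boundaries, n))
        out[i] = float((t**3 - t).sum())
    return out


def ranksum_one_sided(X: np.ndarray, mask: np.ndarray,
                      ranks: np.ndarray | None = None,
                      tie_term: np.ndarray | None = None):
    """Vectorized one-sided (group > rest) rank-sum over the rows of ``X``.

    ``mask`` selects the group columns.  Uses the normal approximation with
    midranks, tie and continuity corrections; for small groups
    (min(n1, n2) <= 8 and n1 + n2 <= 25) each row falls back to exact
    enumeration.  Constant rows get p = 1.  Returns ``(p, auc, u)`` arrays.
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n1 = int(mask.sum())
    n2 = X.shape[1] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    N = n1 + n2
    if ranks is None:
        ranks = rankdata(X, axis=1)
    if min(n1, n2) <= _EXACT_MIN and N <= _EXACT_TOTAL:
        out = np.array([ranksum_exact_p(row[mask], row[~mask]) for row in X])
        p, auc = out[:, 0], out[:, 1]
        u = auc * n1 * n2
        const = X.max(axis=1) == X.min(axis=1)
        p[const] = 1.0
        return p, auc, u
    if tie_term is None:
        tie_term = _tie_terms(X)
    r1 = ranks[:, mask].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    const = var <= 0
    sd = np.sqrt(np.where(const, 1.0, var))
    z = (u - mu - 0.5) / sd
    p = norm.sf(z)
    p[const] = 1.0
    auc = u / (n1 * n2)
    return p, auc, u


# ---------------------------------------------------------------- signatures

def signature_profiles(rp: ReducedProfile, labels, min_cells: int = 3,
                       center: bool = True):
    """Gene x type discriminating-power matrix.

    Per type, member cells' reduced scores are averaged into a metagene vector
    and back-transformed to gene space with the left-singular vectors
    (``basis @ metagene``); per-gene centering across types (the default)
    exposes type-relative power.  Returns ``(signature DataFrame, baseline
    Series)`` where the baseline is the per-gene mean across types before
    centering.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    types = []
    for t, cnt in labels.value_counts().items():
        if cnt < min_cells:
            warnings.warn(f"type {t!r} has {cnt} < {min_cells} cells; excluded")
        else:
            types.append(t)
    types = sorted(types)
    if len(types) < 2:
        raise ValueError("need at least 2 labeled types")
    meta = np.stack(
        [rp.scores[(labels == t).to_numpy()].mean(axis=0) for t in types], axis=1
    )
    sig = rp.basis @ meta  # genes x types
    baseline = sig.mean(axis=1)
    if center:
        sig = sig - baseline[:, None]
    index = rp.gene_ids if rp.gene_ids is not None else np.arange(sig.shape[0])
    return (
        pd.DataFrame(sig, index=index, columns=types),
        pd.Series(baseline, index=index, name="baseline"),
    )


# -------------------------------------------------------------- marker tests

def wilcoxon_markers(nm: NormalizedMatrix, labels, p_thresh: float = 0.001,
                     auc_thresh: float = 0.5, lfc_thresh: float = 0.0,
                     min_detect_frac: float = 0.1) -> pd.DataFrame:
    """One-vs-rest marker test per (gene, type) under the selection criteria
    adjusted p < ``p_thresh``, AUC > ``auc_thresh`` and log fold change >
    ``lfc_thresh``; BH adjustment is joint over all (gene, type) tests and a
    gene is flagged *exclusive* when it passes in exactly one type.

    A candidate must additionally be detected (value > 0) in at least
    ``min_detect_frac`` of the in-group cells — the usual minimum-detection
    prefilter that keeps near-zero-expression genes, whose rank statistics
    are driven by a handful of cells, out of the marker lists.  Set it to 0
    to disable.  The log fold change is the difference of mean
    log1p-normalized expression (in-group minus rest).
    """
    labels = np.asarray(labels, dtype=object)
    types = sorted(pd.unique(labels))
    for t in types:
        if (labels == t).sum() < 3:
            raise ValueError(f"type {t!r} has fewer than 3 cells")
    X = nm.dense()
    n1_small = min(
        min((labels == t).sum(), (labels != t).sum()) for t in types
    )
    precompute = not (n1_small <= _EXACT_MIN and X.shape[1] <= _EXACT_TOTAL)
    ranks = rankdata(X, axis=1) if precompute else None
    ties = _tie_terms(X) if precompute else None
    frames = []
    for t in types:
        mask = labels == t
        p, auc, u = ranksum_one_sided(X, mask, ranks=ranks, tie_term=ties)
        lfc = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
        detect = (X[:, mask] > 0).mean(axis=1)
        frames.append(pd.DataFrame({
            "gene": nm.gene_ids, "type": t, "u": u, "auc": auc, "lfc": lfc,
            "p": p, "detect_frac": detect,
        }))
    res = pd.concat(frames, ignore_index=True)
    res["p_adj"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    res["passes"] = (
        (res["p_adj"] < p_thresh) & (res["auc"] > auc_thresh)
        & (res["lfc"] > lfc_thresh) & (res["detect_frac"] >= min_detect_frac)
    )
    n_pass = res.groupby("gene")["passes"].transform("sum")
    res["exclusive"] = res["passes"] & (n_pass == 1)
    return res


def rank_top(sig: pd.DataFrame, res: pd.DataFrame, n: int = 10) -> dict:
    """Top-n exclusive passing genes per type, ordered by descending
    discriminating power with lexicographic tie-breaking on the symbol."""
    out = {}
    for t in sig.columns:
        sel = res[(res["type"] == t) & res["exclusive"]]
        genes = [g for g in sel["gene"] if g in sig.index]
        power = sig.loc[genes, t]
        ordered = sorted(genes, key=lambda g: (-power[g], g))
        out[t] = ordered[:n]
    return out


# ------------------------------------------------------- platform alignment

def partial_correlation(x, y, controls) -> float:
    """Partial Pearson correlation of x and y given control vectors, via
    residuals of least-squares fits on [1, controls]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(len(x))] + [np.asarray(c, float) for c in controls])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx <= 1e-12 * max(1.0, np.linalg.norm(x)) or \
       sy <= 1e-12 * max(1.0, np.linalg.norm(y)):
        return np.nan
    return float(rx @ ry / (sx * sy))


def cross_platform_alignment(sig_a: pd.DataFrame, base_a: pd.Series,
                             sig_b: pd.DataFrame, base_b: pd.Series,
                             min_shared: int = 50):
    """Type x type partial Pearson correlations of signatures across two
    platforms, controlling simultaneously for both platforms' per-gene
    baseline discriminating power; plus the best match per row type.

    Returns ``(corr DataFrame [a-types x b-types], best_match Series)``.
    """
    shared = sig_a.index.intersection(sig_b.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes (< {min_shared})")
    A = sig_a.loc[shared]
    B = sig_b.loc[shared]
    controls = [base_a.loc[shared].to_numpy(), base_b.loc[shared].to_numpy()]
    corr = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    for ta in A.columns:
        for tb in B.columns:
            corr.loc[ta, tb] = partial_correlation(
                A[ta].to_numpy(), B[tb].to_numpy(), controls
            )
    best = corr.astype(float).idxmax(axis=1)
    best.name = "best_match"
    return corr, best
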