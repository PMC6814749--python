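"""Sub-network analysis of one annotated cell class (macroglia in the retina
use case): contamination filtering, re-reduction, archetype-based subtype
discovery, subtype markers, and macula/periphery enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.proportion import proportions_ztest

from . import annotate as _annotate
from . import markers as _markers
from .archnet import build_kstar_nn, build_ladder, cell_profiles, \
    leiden_cluster, reduce_profile, select_dimension
from .io_qc import CountMatrix, NormalizedMatrix, depth_normalize, qc_filter
from .mnn import mnn_correct

__all__ = [
    "SubsetSpec",
    "extract_and_clean",
    "subcluster",
    "subtype_scores",
    "subtype_markers",
    "region_enrichment",
    "gene_region_test",
]


@dataclass
class SubsetSpec:
    parent: str = "macroglia"
    contamination_markers: list = field(default_factory=list)  # e.g. rod markers
    k: int | str = 3  # subtype resolution, or "auto"


def extract_and_clean(counts: CountMatrix, labels: pd.Series, spec: SubsetSpec,
                      alpha: float = 0.85, n_perm: int = 1000, seed: int = 0,
                      sig_threshold: float = 0.05) -> CountMatrix:
    """Extract the parent-labeled cells and drop contamination doublets.

    Cells whose contamination-marker association score (the annotation
    machinery run on the subset's own network) is significant are removed;
    with an empty contamination list this is a pure extraction.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=counts.cell_ids)
    mask = (labels == spec.parent).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no cells labeled {spec.parent!r}")
    if mask.sum() < 50:
        raise ValueError("parent class has fewer than 50 cells")
    sub = counts.subset(cell_mask=mask)
    if not spec.contamination_markers:
        return sub
    nm, rp, ladder, net = _sub_network(sub, seed, k_max_ladder=6)
    scores, perm_p = _annotate.permutation_test(
        net, nm, {"contamination": spec.contamination_markers},
        alpha=alpha, n_perm=n_perm, seed=seed,
    )
    contaminated = (perm_p["contamination"] < sig_threshold).to_numpy()
    # never remove a cell with zero counts across every contamination marker
    marker_rows = [i for i, g in enumerate(nm.gene_ids)
                   if g in set(spec.contamination_markers)]
    raw = np.asarray(nm.values[marker_rows].sum(axis=0)).ravel()
    contaminated &= raw > 0
    removed = nm.cell_ids[contaminated]
    warnings.warn(f"removed {len(removed)} putative contamination doublets")
    keep = ~np.isin(sub.cell_ids.astype(str), removed.astype(str))
    return sub.subset(cell_mask=keep)


def _sub_network(subset: CountMatrix, seed: int, k_max_ladder: int = 8):
    """Renormalize, pick the reduced dimension by parallel analysis, correct
    batches, and rebuild the multiresolution archetypal network on the subset."""
    nm = depth_normalize(qc_filter(subset, 1, 1))
    d = select_dimension(nm, d_max=min(30, min(nm.values.shape) - 1), seed=seed)
    rp = reduce_profile(nm, d=d, random_state=seed)
    if "batch" in nm.cell_meta.columns and nm.cell_meta["batch"].nunique() > 1:
        rp.scores = mnn_correct(rp.scores, nm.cell_meta["batch"].to_numpy())
    ladder = build_ladder(rp, 2, k_max_ladder, seed=seed)
    net = build_kstar_nn(cell_profiles(ladder), cell_ids=nm.cell_ids)
    return nm, rp, ladder, net


def subcluster(subset: CountMatrix, spec: SubsetSpec | None = None,
               seed: int = 0, auto_range=(2, 6), auto_restarts: int = 5,
               return_network: bool = False):
    """Subtype labels from partitioning the subset's own archetypal network.

    The subset is renormalized, batch-corrected (when a ``batch`` metadata
    column with >1 level is present), reduced to the parallel-analysis
    dimension, and its multiresolution network rebuilt; Leiden partitioning at
    the resolution yielding k clusters gives the subtypes.  With
    ``spec.k="auto"`` the k in ``auto_range`` maximizing the mean pairwise ARI
    of labelings across ``auto_restarts`` differently seeded partitions is
    chosen.  Labels are reindexed by decreasing cluster size.
    """
    spec = spec or SubsetSpec()
    if subset.n_cells < 50:
        raise ValueError("need at least 50 cells to subcluster")
    if spec.k == 1:
        labels = np.zeros(subset.n_cells, dtype=int)
        if return_network:
            nm, rp, ladder, net = _sub_network(subset, seed)
            return labels, net
        return labels
    nm, rp, ladder, net = _sub_network(subset, seed)
    if spec.k == "auto":
        best_k, best_score = None, -np.inf
        for k in range(auto_range[0], auto_range[1] + 1):
            labs = [leiden_cluster(net, n_clusters=k, seed=seed + 97 * r)
                    for r in range(auto_restarts)]
            agreement = np.mean([
                adjusted_rand_score(a, b) for a, b in combinations(labs, 2)
            ])
            if agreement > best_score + 1e-9:
                best_k, best_score = k, agreement
        k = best_k
    else:
        k = int(spec.k)
    labels = leiden_cluster(net, n_clusters=k, seed=seed)
    return (labels, net) if return_network else labels


def subtype_scores(net, labels) -> np.ndarray:
    """Per-cell subtype-association scores: the one-hot label matrix diffused
    over the sub-network (cells x subtypes, ordered by label value)."""
    labels = np.asarray(labels)
    subs = sorted(pd.unique(labels))
    onehot = np.stack([(labels == s).astype(float) for s in subs], axis=1)
    return _annotate._Diffuser(net, 0.85)(onehot)


def subtype_markers(subset: CountMatrix, labels, **kwargs) -> pd.DataFrame:
    """Wilcoxon marker test (with exclusivity) on the subset; delegates to the
    marker module after depth normalization."""
    nm = depth_normalize(qc_filter(subset, 1, 1))
    return _markers.wilcoxon_markers(nm, labels, **kwargs)


def region_enrichment(labels, region, scores: np.ndarray) -> pd.DataFrame:
    """Per-subtype macula/periphery enrichment.

    ``scores`` is the cells x subtypes association matrix (e.g. archetype
    footprints).  The primary test is a one-sided Wilcoxon rank-sum on
    per-cell subtype scores between regions, reported in both fixed
    directions (``p_macula``: macula > periphery, ``p_periphery``: the
    reverse) plus the smaller-p direction; a two-proportion z-test on subtype
    frequencies is the companion.  Subtype frequencies within each region sum
    to 1 across subtypes.
    """
    labels = np.asarray(labels)
    region = np.asarray(region, dtype=object)
    scores = np.asarray(scores, dtype=float)
    in_mac = region == "macula"
    in_per = region == "periphery"
    if not in_mac.any() or not in_per.any():
        raise ValueError("both regions must be represented")
    subtypes = sorted(pd.unique(labels))
    rows = []
    for j, s in enumerate(subtypes):
        member = labels == s
        freq_mac = member[in_mac].mean()
        freq_per = member[in_per].mean()
        if len(subtypes) == 1:
            rows.append({"subtype": s, "freq_macula": 1.0, "freq_periphery": 1.0,
                         "p_macula": np.nan, "p_periphery": np.nan,
                         "p": np.nan, "direction": "none", "p_freq": np.nan})
            continue
        col = scores[:, j] if scores.ndim == 2 else scores
        p_mac = mannwhitneyu(col[in_mac], col[in_per], alternative="greater",
                             method="asymptotic").pvalue
        p_per = mannwhitneyu(col[in_per], col[in_mac], alternative="greater",
                             method="asymptotic").pvalue
        direction = "macula" if p_mac <= p_per else "periphery"
        count = np.array([member[in_mac].sum(), member[in_per].sum()])
        nobs = np.array([in_mac.sum(), in_per.sum()])
        p_freq = proportions_ztest(count, nobs)[1] if 0 < member.sum() < len(member) \
            else np.nan
        rows.append({
            "subtype": s, "freq_macula": freq_mac, "freq_periphery": freq_per,
            "p_macula": float(p_mac), "p_periphery": float(p_per),
            "p": float(min(p_mac, p_per)), "direction": direction,
            "p_freq": p_freq,
        })
    return pd.DataFrame(rows).set_index("subtype")


def gene_region_test(nm: NormalizedMatrix, gene: str, region,
                     direction: str = "macula") -> float:
    """One-sided Wilcoxon on a single gene's normalized expression between
    regions (e.g. COL4A3 within macroglia); returns the p-value for
    ``direction``-greater."""
    region = np.asarray(region, dtype=object)
    row = np.where(nm.gene_ids == gene)[0]
    if len(row) == 0:
        raise KeyError(gene)
    x = np.asarray(nm.values[row[0]].todense()).ravel()
    a = x[region == direction]
    b = x[region != direction]
    return float(mannwhitneyu(a, b, alternative="greater",
                              method="asymptotic").pvalue)
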