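"""Cell-type specificity of GWAS locus genes and competitive gene-set
regression for cell-type-trait association.

Gene-level association statistics (Z-scores, e.g. from a MAGMA gene analysis)
are taken as input; the competitive test regresses gene Z on gene-set
membership plus covariates and tests the membership coefficient one-sided
positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy import stats as _stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io_qc import CountMatrix, NormalizedMatrix
from .markers import _tie_terms, ranksum_one_sided

__all__ = [
    "specificity_scores",
    "build_gene_sets",
    "geneset_regression",
    "negative_control_panel",
]

P_FLOOR = 1e-300          # p-values below this are clipped (finite log-scores)
SIG_THRESHOLD = 1e-10     # stringent specificity significance threshold


def specificity_scores(nm: NormalizedMatrix, labels, genes,
                       sig_threshold: float = SIG_THRESHOLD) -> pd.DataFrame:
    """Per (locus gene, cell type) specificity from the one-sided rank-sum
    test, BH-adjusted across all tested pairs.

    ``score = -log10(adjusted p)`` with p clipped below at 1e-300, and the
    significance flag applies the stringent ``sig_threshold``.  Genes absent
    from the matrix are skipped and listed in ``DataFrame.attrs['missing']``.
    """
    labels = np.asarray(labels, dtype=object)
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    index = {g: i for i, g in enumerate(nm.gene_ids)}
    present = [g for g in genes if g in index]
    missing = [g for g in genes if g not in index]
    if not present:
        raise ValueError("no locus gene found in the expression matrix")
    X = nm.dense()[[index[g] for g in present]]
    ranks = rankdata(X, axis=1)
    ties = _tie_terms(X)
    frames = []
    for t in types:
        p, auc, _ = ranksum_one_sided(X, labels == t, ranks=ranks, tie_term=ties)
        frames.append(pd.DataFrame({"gene": present, "type": t, "p": p,
                                    "auc": auc}))
    res = pd.concat(frames, ignore_index=True)
    res["p_adj"] = np.clip(
        multipletests(res["p"].to_numpy(), method="fdr_bh")[1], P_FLOOR, 1.0
    )
    res["score"] = -np.log10(res["p_adj"])
    res["significant"] = res["p_adj"] < sig_threshold
    res.attrs["missing"] = missing
    return res


def build_gene_sets(nm: NormalizedMatrix, raw: CountMatrix, labels,
                    fdr: float = 0.01, min_detect: float = 0.25) -> dict:
    """Per cell type, genes preferentially expressed there: one-sided rank-sum
    FDR < ``fdr`` and raw detection (count > 0) in >= ``min_detect`` of the
    type's cells.  Sets may overlap across types; empty sets are reported but
    retained as empty lists."""
    labels = np.asarray(labels, dtype=object)
    types = sorted(pd.unique(labels))
    X = nm.dense()
    ranks = rankdata(X, axis=1)
    ties = _tie_terms(X)
    binary = raw.values.copy()
    binary.data = (binary.data > 0).astype(float)
    pmat = {}
    for t in types:
        pmat[t], _, _ = ranksum_one_sided(X, labels == t, ranks=ranks,
                                          tie_term=ties)
    all_p = np.concatenate([pmat[t] for t in types])
    all_adj = multipletests(all_p, method="fdr_bh")[1].reshape(len(types), -1)
    sets = {}
    for i, t in enumerate(types):
        mask = labels == t
        det = np.asarray(binary[:, mask].sum(axis=1)).ravel() / mask.sum()
        keep = (all_adj[i] < fdr) & (det >= min_detect)
        sets[t] = list(np.asarray(nm.gene_ids)[keep])
    return sets


def geneset_regression(stats: pd.DataFrame, gene_set, covariates=("gene_size",)
                       ) -> dict:
    """Competitive gene-set test: OLS of gene Z on intercept + membership +
    covariates, one-sided t on a positive membership coefficient.

    ``stats`` needs columns ``gene`` and ``z`` plus any covariate columns.
    Refuses when the set is empty, covers the whole universe, or the design is
    collinear.
    """
    if len(stats) < 50:
        raise ValueError("need at least 50 genes")
    genes = stats["gene"].to_numpy()
    member = np.isin(genes, list(gene_set)).astype(float)
    if member.sum() == 0:
        raise ValueError("gene set has no overlap with the statistics table")
    if member.sum() == len(member):
        raise ValueError("gene set equals the gene universe (collinear design)")
    cols = [np.ones(len(stats)), member]
    used = []
    for c in covariates:
        if c in stats.columns:
            cols.append(stats[c].to_numpy(dtype=float))
            used.append(c)
    Xd = np.column_stack(cols)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("membership collinear with covariates")
    fit = sm.OLS(stats["z"].to_numpy(dtype=float), Xd).fit()
    beta, se, tval = fit.params[1], fit.bse[1], fit.tvalues[1]
    p = float(_stats.t.sf(tval, fit.df_resid))
    return {
        "beta": float(beta), "se": float(se), "t": float(tval), "p": p,
        "neglog10p": float(-np.log10(max(p, P_FLOOR))),
        "n_members": int(member.sum()), "covariates": used,
    }


def negative_control_panel(trait_stats: dict, gene_sets: dict,
                           covariates=("gene_size",), alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Gene-set regression of every (trait, cell type) pair; a tidy table of
    -log10 p with significance marks at p < ``alpha``.  Traits with zero
    overlapping genes yield missing values for every set."""
    if len(trait_stats) < 1:
        raise ValueError("at least one trait statistics table required")
    rows = []
    for trait, stats in trait_stats.items():
        for t, genes in gene_sets.items():
            try:
                res = geneset_regression(stats, genes, covariates=covariates)
                rows.append({"trait": trait, "type": t, "beta": res["beta"],
                             "se": res["se"], "p": res["p"],
                             "neglog10p": res["neglog10p"],
                             "significant": res["p"] < alpha})
            except ValueError:
                rows.append({"trait": trait, "type": t, "beta": np.nan,
                             "se": np.nan, "p": np.nan, "neglog10p": np.nan,
                             "significant": False})
    return pd.DataFrame(rows)
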