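"""Rank-sum marker selection against enumeration oracles, signatures, ranking
and partial-correlation alignment."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from retinet.archnet import ReducedProfile, reduce_profile
from retinet.io_qc import NormalizedMatrix
from retinet.markers import (
    cross_platform_alignment,
    partial_correlation,
    rank_top,
    ranksum_one_sided,
    signature_profiles,
    wilcoxon_markers,
)


def brute_force_ranksum(x, y):
    """Independent oracle: exhaustively reassign the pooled observations to
    the two groups and count assignments with rank-sum statistic at least as
    large as observed."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        hits += u >= u_obs - 1e-9
        total += 1
    return hits / total


def test_worked_exact_case():
    """A = {5,6,7} vs B = {1,2,3}: U = 9, AUC = 1, exact one-sided
    p = 1/C(6,3) = 0.05."""
    X = np.array([[5.0, 6.0, 7.0, 1.0, 2.0, 3.0]])
    mask = np.array([True, True, True, False, False, False])
    p, auc, u = ranksum_one_sided(X, mask)
    assert u[0] == 9 and auc[0] == 1.0
    assert abs(p[0] - 0.05) < 1e-12


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 8), (8, 8)])
def test_exact_matches_enumeration_with_and_without_ties(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    for trial in range(4):
        x = rng.integers(0, 4, n1).astype(float)  # heavy ties
        y = rng.integers(0, 4, n2).astype(float)
        X = np.concatenate([x, y])[None, :]
        mask = np.array([True] * n1 + [False] * n2)
        p, _, _ = ranksum_one_sided(X, mask)
        if np.ptp(X) == 0:
            assert p[0] == 1.0
            continue
        assert abs(p[0] - brute_force_ranksum(x, y)) <= 1e-12


def test_normal_approximation_close_to_exact_at_boundary():
    rng = np.random.default_rng(0)
    x = rng.normal(1.0, 1.0, 12)
    y = rng.normal(0.0, 1.0, 14)
    X = np.concatenate([x, y])[None, :]
    mask = np.array([True] * 12 + [False] * 14)
    p_approx, _, _ = ranksum_one_sided(X, mask)  # n=26 > exact bound
    p_exact = brute_force_ranksum(x, y)
    assert abs(p_approx[0] - p_exact) <= 0.01


def test_auc_complement_property(small_normalized):
    nm, truth, doublet = small_normalized
    X = nm.dense()[:40]
    mask = truth == "rods"
    _, auc_in, _ = ranksum_one_sided(X, mask)
    _, auc_out, _ = ranksum_one_sided(X, ~mask)
    assert np.allclose(auc_in + auc_out, 1.0, atol=1e-9)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=40))
def test_bh_adjustment_monotone(pvals):
    p = np.asarray(pvals)
    adj = multipletests(p, method="fdr_bh")[1]
    assert np.all(adj >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def _toy_nm(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    cells = [f"c{i}" for i in range(X.shape[1])]
    import scipy.sparse as sp
    return NormalizedMatrix(sp.csr_matrix(X), np.ones(X.shape[1]),
                            np.array(genes, dtype=object),
                            np.array(cells, dtype=object),
                            pd.DataFrame(index=cells))


def test_signature_identity_basis_limiting_case():
    """With basis = I the signature equals per-type mean expression, centered
    per gene across types."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(6, 30))
    labels = np.array(["a"] * 15 + ["b"] * 15)
    rp = ReducedProfile(scores=X.T.copy(), basis=np.eye(6),
                        singular_values=np.ones(6), gene_means=np.zeros(6),
                        gene_ids=np.array([f"g{i}" for i in range(6)]))
    sig, base = signature_profiles(rp, labels)
    mean_a = X[:, :15].mean(axis=1)
    mean_b = X[:, 15:].mean(axis=1)
    expect = np.stack([mean_a, mean_b], axis=1)
    expect = expect - expect.mean(axis=1, keepdims=True)
    assert np.allclose(sig.to_numpy(), expect, atol=1e-12)
    assert np.allclose(base.to_numpy(), (mean_a + mean_b) / 2, atol=1e-12)


def test_signature_highlights_planted_discriminative_gene():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 80)) * 0.2
    X[7, :40] += 3.0  # gene 7 separates type a from type b
    labels = np.array(["a"] * 40 + ["b"] * 40)
    rp = reduce_profile(X, d=10)
    sig, _ = signature_profiles(rp, labels)
    diff = np.abs(sig["a"].to_numpy() - sig["b"].to_numpy())
    assert np.argmax(diff) == 7
    with pytest.warns(UserWarning, match="excluded"):
        sig2, _ = signature_profiles(rp, np.array(["a"] * 40 + ["b"] * 38
                                                  + ["c"] * 2))
    assert list(sig2.columns) == ["a", "b"]


def test_wilcoxon_markers_flags_and_exclusivity():
    rng = np.random.default_rng(3)
    X = rng.poisson(1.0, size=(30, 90)).astype(float)
    labels = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
    X[0, :30] += 5.0          # exclusive to a
    X[1, :60] += 5.0          # shared by a and b -> not exclusive
    nm = _toy_nm(X)
    res = wilcoxon_markers(nm, labels, p_thresh=0.01)
    r0 = res[res.gene == "g0"]
    assert r0[r0.type == "a"].exclusive.item()
    r1 = res[(res.gene == "g1") & res.passes]
    assert set(r1.type) == {"a", "b"}
    assert not res[res.gene == "g1"].exclusive.any()
    # constant gene gets p = 1
    Xc = X.copy(); Xc[2] = 1.0
    resc = wilcoxon_markers(_toy_nm(Xc), labels)
    assert (resc[resc.gene == "g2"].p == 1.0).all()


def test_rank_top_orders_by_power_with_lexicographic_ties():
    sig = pd.DataFrame({"a": [3.0, 1.0, 2.0, 2.0], "b": [0, 0, 0, 0]},
                       index=["gW", "gX", "gB", "gA"])
    res = pd.DataFrame({
        "gene": ["gW", "gX", "gB", "gA"], "type": ["a"] * 4,
        "exclusive": [True, True, True, True],
    })
    top = rank_top(sig, res, n=3)
    assert top["a"] == ["gW", "gA", "gB"]  # tie between gA/gB broken by name
    single = rank_top(sig, res[res.gene == "gX"], n=10)
    assert single["a"] == ["gX"]


def test_partial_correlation_formula_and_oracle():
    """Single control with r_xy = r_xz = r_yz = 0.5 gives
    (0.5 - 0.25)/0.75 = 1/3; and the residual-based computation matches the
    correlation-matrix-inversion oracle to 1e-10 on random data."""
    rng = np.random.default_rng(4)
    n = 60
    G = rng.normal(size=(n, 3))
    G = G - G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    e1, e2, e3 = Q[:, 0], Q[:, 1], Q[:, 2]
    x = e1
    y = 0.5 * e1 + np.sqrt(0.75) * e2
    z = 0.5 * e1 + (0.5 - 0.25) / np.sqrt(0.75) * e2
    z = z + np.sqrt(max(1 - z @ z, 0)) * e3
    assert abs(np.corrcoef(x, y)[0, 1] - 0.5) < 1e-10
    assert abs(partial_correlation(x, y, [z]) - 1 / 3) < 1e-10
    # no confounding: controls orthogonal to both leave r unchanged
    assert abs(partial_correlation(x, x.copy(), [e3]) - 1.0) < 1e-10
    # dual-route check on random data, two controls
    x, y, z1, z2 = rng.normal(size=(4, 200))
    x = x + 0.3 * z1; y = y + 0.5 * z2
    R = np.corrcoef(np.stack([x, y, z1, z2]))
    Om = np.linalg.inv(R)
    oracle = -Om[0, 1] / np.sqrt(Om[0, 0] * Om[1, 1])
    assert abs(partial_correlation(x, y, [z1, z2]) - oracle) < 1e-10


def test_cross_platform_requires_shared_genes():
    idx_a = [f"g{i}" for i in range(30)]
    sig = pd.DataFrame(np.random.default_rng(5).normal(size=(30, 2)),
                       index=idx_a, columns=["a", "b"])
    base = pd.Series(np.zeros(30), index=idx_a)
    with pytest.raises(ValueError, match="shared genes"):
        cross_platform_alignment(sig, base, sig, base, min_shared=50)
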