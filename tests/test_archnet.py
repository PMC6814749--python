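"""Reduction, archetypal analysis, the sqrt-JS metric, the k*-NN network and
the layout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from retinet.archnet import (
    ArchetypalAnalysis,
    CellNetwork,
    _project_simplex_cols,
    build_kstar_nn,
    build_ladder,
    cell_profiles,
    js_distance,
    layout,
    leiden_cluster,
    pairwise_js,
    reduce_profile,
)


# ------------------------------------------------------------------- reduce

def test_reduce_recovers_low_rank_exactly():
    rng = np.random.default_rng(0)
    # build a matrix whose gene-centered part has rank 2
    U = rng.normal(size=(40, 2))
    V = rng.normal(size=(2, 60))
    X = U @ V
    X = X - X.mean(axis=1, keepdims=True) + rng.normal(size=(40, 1))
    rp = reduce_profile(X, d=2)
    recon = rp.basis @ rp.scores.T + rp.gene_means[:, None]
    assert np.linalg.norm(recon - X) <= 1e-8
    assert np.max(np.abs(rp.basis.T @ rp.basis - np.eye(2))) <= 1e-8


def test_reduce_error_monotone_in_d():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 80))
    errs = []
    for d in (5, 10):
        rp = reduce_profile(X, d=d)
        recon = rp.basis @ rp.scores.T + rp.gene_means[:, None]
        errs.append(np.linalg.norm(recon - X))
    assert errs[1] <= errs[0] + 1e-9
    with pytest.raises(ValueError):
        reduce_profile(X, d=60)


# ------------------------------------------------------- archetypal analysis

@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                min_size=3, max_size=12))
def test_simplex_projection_feasible_and_idempotent(vals):
    V = np.asarray(vals, dtype=float).reshape(-1, 2)
    P = _project_simplex_cols(V)
    assert np.all(P >= 0)
    assert np.allclose(P.sum(axis=0), 1.0, atol=1e-9)
    assert np.allclose(_project_simplex_cols(P), P, atol=1e-9)


def test_archetypes_land_on_separated_clusters():
    """Three tight clusters in 2-D: each archetype sits within a fraction of a
    cluster s.d. of that cluster's outermost point, and footprints give >=90%
    of each cluster's cells majority weight on its own archetype."""
    rng = np.random.default_rng(2)
    sd = 0.05
    centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
    X = np.vstack([rng.normal(c, sd, size=(60, 2)) for c in centers])
    aa = ArchetypalAnalysis(n_archetypes=3, random_state=0).fit(X)
    overall = X.mean(axis=0)
    matched = set()
    for z in aa.archetypes_:
        cl = int(np.argmin(np.linalg.norm(centers - z, axis=1)))
        matched.add(cl)
        pts = X[60 * cl: 60 * (cl + 1)]
        d = np.linalg.norm(pts - z, axis=1)
        near = pts[np.argmin(d)]
        assert d.min() <= 0.1 * sd
        # and that nearest point lies on the cluster's outward hull side
        direction = centers[cl] - overall
        proj = pts @ direction
        assert near @ direction >= np.quantile(proj, 0.75)
    assert matched == {0, 1, 2}
    dominant = np.argmax(aa.H_, axis=0)
    for cl in range(3):
        votes = dominant[60 * cl: 60 * (cl + 1)]
        assert (votes == np.bincount(votes).argmax()).mean() >= 0.9


def test_full_depth_reconstruction_is_exact():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(25, 4))
    aa = ArchetypalAnalysis(n_archetypes=25, random_state=0).fit(X)
    assert aa.reconstruction_err_ <= 1e-6


def test_simplex_feasibility_of_fitted_factors():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(70, 5))
    aa = ArchetypalAnalysis(n_archetypes=4, random_state=1).fit(X)
    for M in (aa.C_, aa.H_):
        assert M.min() >= -1e-12
        assert np.allclose(M.sum(axis=0), 1.0, atol=1e-6)


def test_ladder_monotone_and_deterministic():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 6))
    rp = reduce_profile(X.T, d=5)
    lad1 = build_ladder(rp, 2, 6, seed=0)
    lad2 = build_ladder(rp, 2, 6, seed=0)
    errs = [lad1.errors[k] for k in lad1.depths]
    assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))
    for k in lad1.depths:
        assert np.allclose(lad1.H[k], lad2.H[k])


def test_cell_profiles_concatenate_and_renormalize():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 4))
    rp = reduce_profile(X.T, d=3)
    lad = build_ladder(rp, 2, 3, seed=0)
    prof = cell_profiles(lad)
    assert prof.shape == (30, 5)
    assert np.allclose(prof.sum(axis=1), 1.0)
    # a single depth reproduces that depth's footprints
    lad.C = {2: lad.C[2]}; lad.H = {2: lad.H[2]}
    single = cell_profiles(lad)
    assert np.allclose(single, lad.H[2].T, atol=1e-12)


# ------------------------------------------------------------------- metric

def test_js_distance_worked_values():
    assert js_distance([0.2, 0.8], [0.2, 0.8]) == 0.0
    assert abs(js_distance([1, 0], [0, 1]) - 1.0) <= 1e-9
    # H([0.75, 0.25]) - H([0.5, 0.5])/2 = 0.31128 bits; sqrt = 0.55792
    assert abs(js_distance([0.5, 0.5], [1, 0]) - 0.5579230452841438) <= 1e-9


def test_js_distance_metric_on_random_triples():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        p, q, r = rng.dirichlet(np.ones(6), size=3)
        dpq, dqr, dpr = js_distance(p, q), js_distance(q, r), js_distance(p, r)
        assert dpq >= 0 and abs(dpq - js_distance(q, p)) <= 1e-12
        assert dpr <= dpq + dqr + 1e-9


def test_js_distance_agrees_with_reference_kernel():
    rng = np.random.default_rng(8)
    P = rng.dirichlet(np.ones(8), size=20)
    D = pairwise_js(P)
    for i in range(0, 20, 5):
        for j in range(0, 20, 7):
            ref = jensenshannon(P[i], P[j], base=2)
            assert abs(D[i, j] - ref) <= 1e-9
    with pytest.raises(ValueError):
        js_distance([0.5, 0.5], [-0.1, 1.1])


# ------------------------------------------------------------------ network

def test_kstar_rule_on_constructed_distances():
    """10 coincident cells + 1 distant outlier: twins connect to all 9 twins
    and reject the outlier (threshold after 9 zero-distances is
    sqrt(9 lambda)/9 = 1/3 < 0.9); the outlier admits its equidistant
    neighbors, so union symmetrization restores outlier-twin edges."""
    n = 11
    D = np.zeros((n, n))
    D[:10, 10] = 0.9
    D[10, :10] = 0.9
    net = build_kstar_nn(np.empty((n, 1)), dist=D, max_k=10, lam=1.0)
    A = net.adjacency.toarray()
    # twin clique complete at weight 1 - 0 = 1
    assert np.allclose(A[:10, :10] + np.eye(10), np.ones((10, 10)))
    # union keeps outlier edges at weight 1 - 0.9
    assert np.allclose(A[10, :10], 0.1)


def test_equal_distances_give_max_k_neighbors():
    n = 8
    D = np.full((n, n), 0.4)
    np.fill_diagonal(D, 0.0)
    net = build_kstar_nn(np.empty((n, 1)), dist=D, max_k=5)
    assert (net.degrees() >= 5).all()


def test_network_symmetric_zero_diagonal(small_normalized):
    nm, truth, doublet = small_normalized
    rp = reduce_profile(nm, d=20)
    lad = build_ladder(rp, 2, 5, seed=0)
    net = build_kstar_nn(cell_profiles(lad))
    A = net.adjacency
    assert (A != A.T).nnz == 0
    assert np.all(A.diagonal() == 0)
    assert A.data.min() > 0 and A.data.max() <= 1.0


def test_leiden_recovers_types_on_small_data(small_normalized):
    from sklearn.metrics import adjusted_rand_score

    nm, truth, doublet = small_normalized
    rp = reduce_profile(nm, d=20)
    lad = build_ladder(rp, 2, 8, seed=0)
    net = build_kstar_nn(cell_profiles(lad))
    labels = leiden_cluster(net, seed=0)
    assert adjusted_rand_score(truth[~doublet], labels[~doublet]) >= 0.9


def test_layout_separates_components_and_is_deterministic():
    import scipy.sparse as sp

    blocks = sp.block_diag([np.ones((5, 5)) - np.eye(5)] * 2).tocsr()
    net = CellNetwork(adjacency=blocks)
    c1 = layout(net, seed=0)
    c2 = layout(net, seed=0)
    assert np.allclose(c1, c2)
    gap = np.linalg.norm(c1[:5].mean(0) - c1[5:].mean(0))
    spread = max(np.linalg.norm(c1[:5] - c1[:5].mean(0), axis=1).max(),
                 np.linalg.norm(c1[5:] - c1[5:].mean(0), axis=1).max())
    assert gap >= spread
    empty = CellNetwork(adjacency=sp.csr_matrix((0, 0)))
    assert layout(empty).shape == (0, 2)
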