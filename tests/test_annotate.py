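"""Diffusion imputation, marker scoring, permutation significance, label
assignment and the neighborhood-coherence filter."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import kstest

from retinet.annotate import (
    FILTER_CODES,
    INCOHERENT,
    UNASSIGNED_MULTI,
    UNASSIGNED_NONE,
    assign,
    coherence_filter,
    diffuse,
    permutation_test,
    read_marker_tsv,
    score_cell_types,
)
from retinet.archnet import CellNetwork, build_kstar_nn, build_ladder, \
    cell_profiles, reduce_profile
from retinet.io_qc import NormalizedMatrix


def _net_from_dense(A):
    return CellNetwork(adjacency=sp.csr_matrix(np.asarray(A, dtype=float)))


@pytest.fixture(scope="module")
def small_net(small_normalized):
    nm, truth, doublet = small_normalized
    rp = reduce_profile(nm, d=20)
    lad = build_ladder(rp, 2, 6, seed=0)
    return build_kstar_nn(cell_profiles(lad))


def test_diffuse_alpha_zero_identity():
    net = _net_from_dense([[0, 1], [1, 0]])
    x = np.array([3.0, 1.0])
    assert np.allclose(diffuse(net, x, alpha=0.0), x)


def test_diffuse_two_node_closed_form():
    """Symmetric two-node graph: s = 0.5 (I - 0.5 P)^-1 x solved by hand."""
    net = _net_from_dense([[0, 1], [1, 0]])
    x = np.array([1.0, 0.0])
    alpha = 0.5
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    expected = (1 - alpha) * np.linalg.solve(np.eye(2) - alpha * P, x)
    assert np.allclose(diffuse(net, x, alpha=alpha), expected, atol=1e-10)


def test_diffuse_conserves_mass_and_isolated_nodes():
    rng = np.random.default_rng(0)
    A = (rng.random((30, 30)) < 0.15).astype(float)
    A = np.triu(A, 1); A = A + A.T
    A[5, :] = 0; A[:, 5] = 0  # isolated node
    net = _net_from_dense(A)
    x = rng.random(30)
    s = diffuse(net, x, alpha=0.85)
    assert abs(s.sum() - x.sum()) <= 1e-8
    with pytest.raises(ValueError):
        diffuse(net, -x, alpha=0.85)


def test_marker_score_peaks_on_expressing_clique():
    # two 6-cliques; marker expressed only in the first
    A = np.zeros((12, 12))
    A[:6, :6] = 1; A[6:, 6:] = 1
    np.fill_diagonal(A, 0)
    net = _net_from_dense(A)
    expr = np.zeros((1, 12)); expr[0, :6] = 2.0
    nm = NormalizedMatrix(sp.csr_matrix(expr), np.ones(12),
                          np.array(["M"], dtype=object),
                          np.array([f"c{i}" for i in range(12)], dtype=object),
                          pd.DataFrame(index=[f"c{i}" for i in range(12)]))
    scores = score_cell_types(net, nm, {"t": ["M"]}, alpha=0.85)
    assert scores["t"][:6].min() > scores["t"][6:].max()
    # duplicated marker lists give identical columns
    two = score_cell_types(net, nm, {"t1": ["M"], "t2": ["M"]}, alpha=0.85)
    assert np.allclose(two["t1"], two["t2"])
    # constant expression -> zero-variance guard -> all-zero scores
    flat = NormalizedMatrix(sp.csr_matrix(np.ones((1, 12))), np.ones(12),
                            np.array(["M"], dtype=object), nm.cell_ids,
                            nm.cell_meta)
    zero = score_cell_types(net, flat, {"t": ["M"]}, alpha=0.85)
    assert np.allclose(zero["t"], 0.0)


def test_missing_markers_warn_and_empty_panel_raises(small_normalized, small_net):
    nm, _, _ = small_normalized
    with pytest.warns(UserWarning, match="not found"):
        score_cell_types(small_net, nm, {"t": [nm.gene_ids[0], "NOPE"]})
    with pytest.raises(ValueError):
        score_cell_types(small_net, nm, {"t": ["NOPE"]})


def test_permutation_p_floor_and_null_rate(small_normalized, small_net):
    nm, truth, doublet = small_normalized
    rng = np.random.default_rng(1)
    random_panel = {
        f"t{j}": list(rng.choice(nm.gene_ids, 8, replace=False)) for j in range(3)
    }
    scores, perm_p = permutation_test(small_net, nm, random_panel,
                                      n_perm=200, seed=0)
    assert perm_p.to_numpy().min() >= 1 / 201
    assert (perm_p.to_numpy() < 0.05).mean() <= 0.07


def test_permutation_p_superuniform_under_random_panel(small_normalized, small_net):
    """Null permutation p-values should stochastically dominate uniform
    (one-sided KS against 'smaller than uniform' does not reject)."""
    nm, truth, doublet = small_normalized
    rng = np.random.default_rng(2)
    panel = {"t0": list(rng.choice(nm.gene_ids, 10, replace=False))}
    _, perm_p = permutation_test(small_net, nm, panel, n_perm=1000, seed=1)
    p = perm_p.to_numpy().ravel()
    # 'greater' puts the alternative at "p-values stochastically smaller than
    # uniform", the direction that would indicate an anti-conservative null
    stat = kstest(p, "uniform", alternative="greater")
    assert stat.pvalue > 0.01


def test_assignment_rules():
    cells = ["a", "b", "c"]
    scores = pd.DataFrame({"rods": [2.0, 1.0, 0.1], "cones": [0.1, 0.9, 0.0]},
                          index=cells)
    perm_p = pd.DataFrame({"rods": [0.01, 0.01, 1.0], "cones": [0.9, 0.01, 1.0]},
                          index=cells)
    labels = assign(scores, perm_p)
    assert labels.tolist() == ["rods", UNASSIGNED_MULTI, UNASSIGNED_NONE]


def test_coherence_filter_hand_hypergeometric():
    """Star of 11 same-label cells inside a 100-cell population where the
    label has global frequency 10%: the exact tail probability (direct
    summation) is far below 0.05, so the center is retained; a cell with 0
    same-label neighbors is flagged."""
    from math import comb

    n = 100
    A = np.zeros((n, n))
    A[0, 1:11] = A[1:11, 0] = 1      # center 0 with 10 neighbors, all label L
    A[11, 12:22] = A[12:22, 11] = 1  # center 11 with 10 neighbors, none label L
    net = _net_from_dense(A)
    lab = np.array(["other"] * n, dtype=object)
    lab[:11] = "L"
    lab[11] = "L"                    # 12 L-cells total among 100
    labels = pd.Series(lab)
    out = coherence_filter(net, labels, alpha_test=0.05)
    # direct tail sum for center 0: P[X >= 10], X ~ Hypergeom(N=99, K=11, n=10)
    tail = comb(11, 10) * comb(88, 0) / comb(99, 10)
    assert tail < 1e-10
    assert out.iloc[0] == "L"
    assert out.iloc[11] == INCOHERENT


def test_coherence_homogeneous_graph_keeps_everyone():
    A = np.ones((8, 8)) - np.eye(8)
    net = _net_from_dense(A)
    labels = pd.Series(["t"] * 8)
    out = coherence_filter(net, labels)
    assert (out == "t").all()
    # degree-0 node flagged by convention
    A2 = np.zeros((3, 3)); A2[0, 1] = A2[1, 0] = 1
    out2 = coherence_filter(_net_from_dense(A2), pd.Series(["t", "t", "t"]))
    assert out2.iloc[2] == INCOHERENT


def test_marker_tsv_roundtrip(tmp_path):
    path = tmp_path / "markers.tsv"
    path.write_text("rods\tPDE6A\nrods\tNR2E3\ncones\tGNAT2\n")
    table = read_marker_tsv(path)
    assert table == {"rods": ["PDE6A", "NR2E3"], "cones": ["GNAT2"]}
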