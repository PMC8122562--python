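"""QC, normalization, HVG selection, PCA and clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from sccmap.containers import CountMatrix
from sccmap.preprocess import (joint_cluster, log_normalize, pca_embed,
                               qc_filter, select_hvg, snn_louvain,
                               vst_standardized_variance)
from sccmap.synthetic import simulate_counts

from conftest import toy_matrix


# ------------------------------------------------------------------- QC
def test_qc_thresholds_are_strict_inequalities():
    # cell0: 499 detected genes, no mito -> removed (below 500)
    # cell1: 500 detected genes, mito exactly 10% -> retained (at thresholds)
    # cell2: zero detected genes -> removed
    n_genes = 600
    counts = np.zeros((n_genes, 3), dtype=int)
    counts[1:500, 0] = 1
    counts[0, 1] = 56                       # the mito gene: 56 of 560 = 10%
    counts[1:495, 1] = 1                    # 494 non-mito singletons
    counts[495:500, 1] = 2                  # 5 doublets -> non-mito total 504
    m = toy_matrix(counts, mito=1)
    stats_total = counts[:, 1].sum()
    assert stats_total == 560 and (counts[:, 1] > 0).sum() == 500
    kept = qc_filter(m, min_genes=500, max_mito_frac=0.10)
    assert list(kept.cell_ids) == ["cell1"]


def test_qc_matches_bruteforce_tally(small_sample):
    m, _ = small_sample
    kept = qc_filter(m)
    dense = np.asarray(m.counts.todense())
    keep = []
    for j in range(m.n_cells):
        col = dense[:, j]
        detected = int((col > 0).sum())
        mito = col[m.mito_mask].sum() / max(col.sum(), 1)
        if detected >= 500 and mito <= 0.10:
            keep.append(m.cell_ids[j])
    assert list(kept.cell_ids) == keep


def test_qc_idempotent(small_sample):
    m, _ = small_sample
    once = qc_filter(m)
    twice = qc_filter(once)
    assert list(once.cell_ids) == list(twice.cell_ids)


def test_qc_all_removed_raises():
    m = toy_matrix(np.zeros((10, 4), dtype=int))
    with pytest.raises(ValueError, match="all"):
        qc_filter(m)


# ---------------------------------------------------------- LogNormalize
def test_log_normalize_formula_and_zero_pattern():
    counts = np.array([[0, 2], [1, 0], [3, 5]])
    m = toy_matrix(counts)
    normed = np.asarray(log_normalize(m, scale_factor=100).todense())
    totals = counts.sum(axis=0)
    expected = np.log1p(100.0 * counts / totals)
    np.testing.assert_allclose(normed, expected, rtol=1e-12)
    assert (normed == 0).all() == (counts == 0).all()
    assert np.isfinite(normed).all() and (normed >= 0).all()


def test_log_normalize_identity_case():
    # cell total equals the scale factor -> a count of 1 maps to ln 2
    counts = np.zeros((5, 1), dtype=int)
    counts[0, 0] = 1
    counts[1, 0] = 9
    m = toy_matrix(counts)
    normed = np.asarray(log_normalize(m, scale_factor=10).todense())
    assert normed[0, 0] == pytest.approx(np.log(2.0))


def test_log_normalize_rejects_empty_cell():
    counts = np.array([[1, 0], [2, 0]])
    with pytest.raises(ValueError, match="zero total"):
        log_normalize(toy_matrix(counts))


# ------------------------------------------------------------------ HVG
def _vst_oracle(counts: np.ndarray) -> np.ndarray:
    """Independent dense re-implementation of the vst ranking."""
    n = counts.shape[1]
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    score = np.zeros(len(mean))
    pos = var > 0
    fit = lowess(np.log10(var[pos]), np.log10(mean[pos]), frac=0.3,
                 return_sorted=False)
    sd = np.sqrt(10.0 ** fit)
    clip = np.sqrt(n)
    z = (counts[pos] - mean[pos, None]) / sd[:, None]
    z = np.clip(z, -clip, clip)
    score[pos] = z.var(axis=1, ddof=1)
    return score


def test_vst_selection_matches_dense_oracle(small_sample):
    m, _ = small_sample
    sub = m.subset_genes(np.arange(0, m.n_genes, 2))  # keep it small
    got = vst_standardized_variance(sub)
    want = _vst_oracle(np.asarray(sub.counts.todense(), dtype=float))
    np.testing.assert_allclose(got.to_numpy(), want, rtol=1e-8, atol=1e-10)
    top = select_hvg(sub, n_top=50)
    oracle_top = sub.gene_ids[np.argsort(-want, kind="stable")[:50]]
    # same selected set (ordering within ties may differ)
    assert set(top) == set(oracle_top)


def test_zero_variance_gene_never_beats_variable_gene():
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(30, 80))
    counts[0] = 5  # constant gene
    m = toy_matrix(counts)
    score = vst_standardized_variance(m)
    assert score.iloc[0] == 0.0
    top = select_hvg(m, n_top=29)
    assert "g0" not in set(top)


def test_fewer_genes_than_requested_warns_and_returns_all():
    m = toy_matrix(np.random.default_rng(1).poisson(1.0, size=(10, 40)))
    with pytest.warns(UserWarning, match="returning all"):
        got = select_hvg(m, n_top=2000)
    assert len(got) == 10


# ------------------------------------------------------------------ PCA
def test_pca_matches_eigendecomposition_and_ordering():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(12, 200))  # genes x cells
    scores = pca_embed(sp.csr_matrix(x), n_pcs=5, clip=1e9)
    var = scores.var(axis=0, ddof=1)
    assert (np.diff(var) <= 1e-9).all()  # non-increasing
    # oracle: full eigendecomposition of the covariance of scaled data
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    z -= z.mean(axis=1, keepdims=True)
    cov = z @ z.T / (z.shape[1] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:5]
    expected = np.abs(z.T @ v[:, order])
    np.testing.assert_allclose(np.abs(scores), expected, rtol=1e-7, atol=1e-8)


def test_pca_rank_deficient_data_has_zero_trailing_variance():
    rng = np.random.default_rng(3)
    basis = rng.normal(size=(2, 6))
    coords = rng.normal(size=(100, 2))
    x = (coords @ basis).T  # 6 "genes", rank 2
    scores = pca_embed(sp.csr_matrix(x), n_pcs=4, clip=1e9)
    var = scores.var(axis=0)
    assert var[2] < 1e-10 * var[0] and var[3] < 1e-10 * var[0]


def test_pca_rejects_too_many_components():
    with pytest.raises(ValueError, match="n_pcs"):
        pca_embed(sp.csr_matrix(np.ones((4, 10))), n_pcs=11)


# ----------------------------------------------------------- clustering
def _blobs(seed=0):
    rng = np.random.default_rng(seed)
    emb = np.vstack([rng.normal(0, 1, (150, 5)), rng.normal(20, 1, (120, 5))])
    ids = np.array([f"c{i}" for i in range(270)], dtype=object)
    truth = np.array([0] * 150 + [1] * 120)
    return emb, ids, truth


def test_two_separated_blobs_give_two_matching_clusters():
    emb, ids, truth = _blobs()
    ca = snn_louvain(emb, ids, seed=0)
    assert ca.n_clusters == 2
    assert adjusted_rand_score(truth, ca.labels.to_numpy()) == 1.0


def test_louvain_deterministic_under_seed():
    emb, ids, _ = _blobs(seed=5)
    a = snn_louvain(emb, ids, seed=3)
    b = snn_louvain(emb, ids, seed=3)
    assert a.labels.equals(b.labels)


def test_clustering_invariant_to_cell_order():
    emb, ids, _ = _blobs(seed=6)
    perm = np.random.default_rng(9).permutation(len(ids))
    a = snn_louvain(emb, ids, seed=0)
    b = snn_louvain(emb[perm], ids[perm], seed=0)
    aligned = pd.concat([a.labels.rename("a"), b.labels.rename("b")], axis=1)
    assert adjusted_rand_score(aligned["a"], aligned["b"]) == 1.0


def test_cluster_labels_ordered_by_size():
    emb, ids, truth = _blobs()
    ca = snn_louvain(emb, ids, seed=0)
    sizes = ca.sizes()
    assert sizes.iloc[0] >= sizes.iloc[1]
    assert list(sizes.index) == [0, 1]


# --------------------------------------------------------- joint cluster
def _tiny_counts(seed, label, n_types=2):
    from sccmap.synthetic import SimScenario
    s = SimScenario(n_cell_types=n_types, cells_per_type=(150, 120)[:n_types],
                    n_genes=600, disease_cluster_size=0, program_size=30,
                    type_de_genes=50, qc_fail_fraction=0.0, seed=7)
    m, _ = simulate_counts(s, disease=False, sample_label=label,
                           sampling_seed=seed)
    return m


def test_joint_cluster_duplicated_sample_is_symmetric():
    m1 = _tiny_counts(1, "a")
    m2 = _tiny_counts(1, "b")  # identical counts, different cell ids
    clusters, comp = joint_cluster(m1, m2, resolution=0.4, seed=0, qc=False)
    # each cluster holds both copies of its cells in equal number
    assert (comp["a"] == comp["b"]).all()
    lab = clusters.labels
    for c1, c2 in zip(m1.cell_ids, m2.cell_ids):
        assert lab[c1] == lab[c2]


def test_joint_cluster_resolution_limit_gives_single_cluster():
    # one shared cell type: the SNN graph is connected, so the zero-
    # resolution limit of modularity merges everything
    m1 = _tiny_counts(1, "a", n_types=1)
    m2 = _tiny_counts(2, "b", n_types=1)
    clusters, _ = joint_cluster(m1, m2, resolution=1e-6, seed=0, qc=False)
    assert clusters.n_clusters == 1


def test_joint_cluster_requires_shared_genes():
    m1 = _tiny_counts(1, "a")
    counts = np.ones((4, 30), dtype=int)
    other = CountMatrix(sp.csr_matrix(counts),
                        np.array([f"x{i}" for i in range(4)], dtype=object),
                        np.array([f"z{i}" for i in range(30)], dtype=object),
                        "c")
    with pytest.raises(ValueError, match="intersection"):
        joint_cluster(m1, other, qc=False)
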