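"""Pairwise DE, pi-scores, signature combination and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as st

from sccmap.containers import ClusterAssignment
from sccmap.de import de_between
from sccmap.preprocess import log_normalize
from sccmap.signatures import (PiScoreTable, build_pi_table,
                               combine_cluster_signature, pi_score)
from sccmap.stats import bh_adjust

from conftest import toy_matrix


# ----------------------------------------------------------------- DE
def _nb_counts(rng, g, n, scale=1.0):
    mu = np.exp(rng.normal(0, 1, g))[:, None] * scale
    return rng.negative_binomial(5, 5 / (5 + mu), size=(g, n))


def test_null_pvalues_approximately_uniform():
    """Permuted labels on identical distributions: KS distance from
    U(0,1) below 0.1 for the hurdle engine."""
    rng = np.random.default_rng(11)
    counts = _nb_counts(rng, 500, 200)
    m = toy_matrix(counts)
    normed = log_normalize(m)
    p = de_between(normed, m.gene_ids, np.arange(100),
                   np.arange(100, 200)).table["p_value"]
    assert st.kstest(p, "uniform").statistic < 0.1


def test_gene_exclusive_to_target_has_positive_lfc():
    rng = np.random.default_rng(1)
    counts = _nb_counts(rng, 40, 60, scale=2.0)
    counts[0, :30] = 5   # expressed only in the target group
    counts[0, 30:] = 0
    m = toy_matrix(counts)
    normed = log_normalize(m)
    res = de_between(normed, m.gene_ids, np.arange(30), np.arange(30, 60))
    assert res.table.loc["g0", "lfc"] > 0
    assert res.table.loc["g0", "p_value"] < 0.01


def test_welch_engine_matches_textbook_formula():
    a = np.array([3.1, 2.9, 3.4, 3.8, 2.7])
    b = np.array([2.0, 2.2, 1.8, 2.4])
    counts = np.zeros((2, 9))
    counts[0] = np.concatenate([a, b])
    counts[1] = 1.0  # keeps totals positive
    # bypass normalization: feed values directly
    res = de_between(sp.csr_matrix(counts), np.array(["g0", "g1"], dtype=object),
                     np.arange(5), np.arange(5, 9), engine="welch")
    # hand Welch computation on the normalized values the engine saw
    normed = counts.copy()
    va, vb = normed[0, :5], normed[0, 5:]
    se2 = va.var(ddof=1) / 5 + vb.var(ddof=1) / 4
    t = (va.mean() - vb.mean()) / np.sqrt(se2)
    df = se2**2 / ((va.var(ddof=1) / 5) ** 2 / 4 + (vb.var(ddof=1) / 4) ** 2 / 3)
    p_expected = 2 * st.t.sf(abs(t), df)
    assert res.table.loc["g0", "p_value"] == pytest.approx(p_expected, rel=1e-9)


def test_sparsely_expressed_genes_are_dropped():
    counts = np.zeros((3, 20), dtype=int)
    counts[0] = 1
    counts[1, 0] = 1            # expressed in 1 cell < 3 -> dropped
    counts[2, :5] = 2
    m = toy_matrix(counts)
    normed = log_normalize(m)
    res = de_between(normed, m.gene_ids, np.arange(10), np.arange(10, 20))
    assert "g1" not in res.table.index and "g0" in res.table.index


def test_tiny_cluster_rejected():
    m = toy_matrix(np.ones((5, 10), dtype=int))
    normed = log_normalize(m)
    with pytest.raises(ValueError, match="fewer than"):
        de_between(normed, m.gene_ids, np.arange(2), np.arange(2, 10))


# ------------------------------------------------------------ pi-score
def test_pi_score_null_constant_is_two():
    assert pi_score(1.0, 0.01) == pytest.approx(2.0)


@pytest.mark.parametrize("lfc,fdr,expected", [
    (1.0, 0.01, 2.0),
    (0.5, 1.0, 0.0),
    (-3.0, 1.0, 0.0),
    (-2.0, 1e-3, -6.0),
])
def test_pi_score_examples(lfc, fdr, expected):
    assert pi_score(lfc, fdr) == pytest.approx(expected, abs=1e-12)


def test_pi_score_floors_zero_fdr():
    assert pi_score(1.0, 0.0) == pytest.approx(300.0)
    with pytest.raises(ValueError):
        pi_score(1.0, 1.5)


# ----------------------------------------------------- combine signature
def _table(values: dict) -> PiScoreTable:
    return PiScoreTable("c", pd.DataFrame(values))


def test_all_pi_at_null_gives_p_half():
    tab = _table({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [2.0, 2.0]})
    tab.values.index = ["g1", "g2"]
    sig = combine_cluster_signature(tab)
    assert (sig.table["t"] == 0).all()
    assert (sig.table["p_value"] == 0.5).all()
    assert sig.table["flagged"].all()  # zero sd, mean == mu0


def test_t_statistic_matches_numerical_integration_oracle():
    """pi = (4, 5, 6) against mu0 = 2: t = 3 sqrt(3), p from the upper-tail
    Student-t integral with 2 df."""
    tab = _table({"a": [4.0], "b": [5.0], "c": [6.0]})
    tab.values.index = ["g1"]
    sig = combine_cluster_signature(tab, mu0=2.0)
    t = sig.table.loc["g1", "t"]
    assert t == pytest.approx(3 * np.sqrt(3), rel=1e-12)
    from scipy.integrate import quad
    dens = st.t(df=2).pdf
    p_oracle, _ = quad(dens, t, np.inf)
    assert sig.table.loc["g1", "p_value"] == pytest.approx(p_oracle, rel=1e-6)
    assert p_oracle == pytest.approx(0.0175, abs=5e-4)


def test_cas_truncates_to_requested_size():
    rng = np.random.default_rng(0)
    n = 400  # > 200 genes pass FDR
    vals = {c: 40 + rng.normal(0, 1, n) for c in "abcd"}
    tab = _table(vals)
    tab.values.index = [f"g{i}" for i in range(n)]
    sig = combine_cluster_signature(tab, cas_size=200)
    assert (sig.table["fdr"] < 0.05).sum() > 200
    assert len(sig.cas_genes) == 200
    # the retained genes are the most significant ones
    fdrs = sig.table.loc[sig.cas_genes, "fdr"]
    others = sig.table.loc[~sig.table.index.isin(sig.cas_genes), "fdr"]
    assert fdrs.max() <= others.min() + 1e-15


def test_combination_invariant_to_comparison_order():
    rng = np.random.default_rng(4)
    vals = rng.normal(3, 2, size=(50, 4))
    idx = [f"g{i}" for i in range(50)]
    t1 = PiScoreTable("c", pd.DataFrame(vals, index=idx, columns=list("abcd")))
    t2 = PiScoreTable("c", pd.DataFrame(vals[:, ::-1], index=idx,
                                        columns=list("dcba")))
    s1 = combine_cluster_signature(t1)
    s2 = combine_cluster_signature(t2)
    pd.testing.assert_frame_equal(s1.table, s2.table)
    assert s1.cas_genes == s2.cas_genes


def test_missing_comparisons_handled():
    tab = _table({"a": [4.0, np.nan, np.nan], "b": [5.0, 3.0, np.nan],
                  "c": [6.0, 4.0, 9.0]})
    tab.values.index = ["g1", "g2", "g3"]
    sig = combine_cluster_signature(tab)
    assert sig.table.loc["g1", "n_comparisons"] == 3
    assert sig.table.loc["g2", "n_comparisons"] == 2
    assert np.isnan(sig.table.loc["g3", "p_value"])  # r < 2: untested


def test_degenerate_zero_sd_above_null_flagged_significant():
    tab = _table({"a": [7.0], "b": [7.0]})
    tab.values.index = ["g1"]
    sig = combine_cluster_signature(tab)
    assert sig.table.loc["g1", "p_value"] == 0.0
    assert bool(sig.table.loc["g1", "flagged"])


# ------------------------------------------------------------------- BH
def test_bh_stepup_hand_example():
    np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                               [0.03, 0.03, 0.03])


def test_bh_identities():
    assert bh_adjust(np.array([0.2])) == pytest.approx([0.2])
    np.testing.assert_allclose(bh_adjust(np.full(5, 0.07)), np.full(5, 0.07))


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.1, np.nan]))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=40),
       hst.randoms(use_true_random=False))
def test_bh_matches_stepup_oracle_and_is_order_invariant(ps, rnd):
    p = np.array(ps)
    got = bh_adjust(p)
    # independent step-up oracle
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        q[i] = running
    np.testing.assert_allclose(got, q, rtol=1e-12, atol=1e-15)
    perm = list(range(n))
    rnd.shuffle(perm)
    got_perm = bh_adjust(p[perm])
    np.testing.assert_allclose(got_perm, got[perm], rtol=1e-12, atol=1e-15)


def test_build_pi_table_collects_cluster_comparisons():
    rng = np.random.default_rng(2)
    counts = _nb_counts(rng, 60, 160, scale=2.0)
    counts[:10, :40] *= 6   # cluster 0 over-expresses the first 10 genes
    m = toy_matrix(counts)
    normed = log_normalize(m)
    labels = pd.Series(np.repeat([0, 1, 2, 3], 40), index=m.cell_ids)
    clusters = ClusterAssignment(labels)
    from sccmap.de import all_pairwise_de
    de = all_pairwise_de(normed, m.gene_ids, clusters)
    tab = build_pi_table(de, 0)
    assert tab.n_comparisons == 3
    sig = combine_cluster_signature(tab)
    hits = set(sig.cas_genes)
    assert len(hits & {f"g{i}" for i in range(10)}) >= 8
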