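"""Per-sample scRNA-seq preprocessing and graph-based clustering.

The recipe follows the standard droplet-data workflow: filter low-quality
cells (too few detected genes or excess mitochondrial UMIs), LogNormalize to
a fixed scale factor, select highly variable genes by vst-style standardized
variance, embed with PCA on the scaled/clipped HVG submatrix, build a
shared-nearest-neighbor (SNN) graph with Jaccard edge weights, and run
Louvain modularity optimisation at a chosen resolution.

Cluster labels are contiguous integers from 0, ordered by decreasing
cluster size. All stochastic steps take an explicit seed.
"""

from __future__ import annotations

import logging
import random as _random
import warnings

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ClusterAssignment, CountMatrix, relabel_by_size

logger = logging.getLogger(__name__)

SNN_PRUNE = 1.0 / 15.0  # Jaccard cutoff below which SNN edges are dropped


# ------------------------------------------------------------------ QC
def qc_cell_stats(m: CountMatrix) -> pd.DataFrame:
    """Per-cell detected-gene counts and mitochondrial UMI fraction."""
    counts = m.counts.tocsc()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(counts[m.mito_mask, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1.0), 0.0)
    return pd.DataFrame(
        {"n_genes_detected": detected, "total_umi": total, "mito_frac": frac},
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def qc_filter(m: CountMatrix, min_genes: int = 500,
              max_mito_frac: float = 0.10) -> CountMatrix:
    """Remove cells detected in fewer than ``min_genes`` genes or with more
    than ``max_mito_frac`` mitochondrial UMIs.

    Both thresholds are strict on the failing side: a cell with exactly
    ``min_genes`` detected genes and exactly ``max_mito_frac`` mitochondrial
    content is retained. The gene set is unchanged.
    """
    stats = qc_cell_stats(m)
    keep = (stats["n_genes_detected"].to_numpy() >= min_genes) & (
        stats["mito_frac"].to_numpy() <= max_mito_frac)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"qc_filter removed all {m.n_cells} cells "
            f"(min detected {stats['n_genes_detected'].min()}, "
            f"max mito {stats['mito_frac'].max():.3f})")
    logger.info("qc_filter(%s): removed %d of %d cells",
                m.sample_label, n_removed, m.n_cells)
    out = m.subset_cells(np.flatnonzero(keep))
    return out


# ------------------------------------------------------------- normalization
def log_normalize(m: CountMatrix, scale_factor: float = 1e4) -> sp.csr_matrix:
    """LogNormalize: value(g,c) = ln(1 + scale_factor * count / cell_total).

    Returns a sparse genes x cells matrix with the sparsity pattern of the
    input counts.
    """
    counts = m.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = int((totals == 0).sum())
        raise ValueError(f"{bad} cells have zero total UMI; run qc_filter first")
    out = counts.copy()
    # scale columns by scale_factor / total, then log1p the stored values
    scale = scale_factor / totals
    out.data *= np.repeat(scale, np.diff(out.indptr))
    np.log1p(out.data, out=out.data)
    return out.tocsr()


# ----------------------------------------------------------------- HVG (vst)
def _sparse_row_moments(counts: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and unbiased variance of a genes x cells sparse matrix."""
    n = counts.shape[1]
    s1 = np.asarray(counts.sum(axis=1)).ravel()
    s2 = np.asarray(counts.multiply(counts).sum(axis=1)).ravel()
    mean = s1 / n
    var = (s2 - n * mean**2) / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def vst_standardized_variance(m: CountMatrix, loess_span: float = 0.3
                              ) -> pd.Series:
    """vst-style standardized variance per gene, computed on raw counts.

    A local regression of log10(variance) on log10(mean) predicts each
    gene's expected standard deviation; counts are standardized against it,
    clipped at sqrt(n_cells), and the variance of the clipped values is the
    gene's score. Genes with zero variance score 0.
    """
    counts = m.counts.tocsr().astype(float)
    n = m.n_cells
    mean, var = _sparse_row_moments(counts)
    score = np.zeros(m.n_genes)
    pos = var > 0
    if pos.sum() >= 3:
        x = np.log10(mean[pos])
        y = np.log10(var[pos])
        fit = lowess(y, x, frac=loess_span, return_sorted=False)
        exp_sd = np.sqrt(10.0 ** fit)
        clip = np.sqrt(n)
        mu = mean[pos]
        # variance of clipped z-scores, exploiting sparsity: zeros all map to
        # the (clipped) value -mu/sd
        sub = counts[np.flatnonzero(pos), :]
        z_zero = np.clip((0.0 - mu) / exp_sd, -clip, clip)
        s1 = np.zeros(pos.sum())
        s2 = np.zeros(pos.sum())
        sub = sub.tocsr()
        row_nnz = np.diff(sub.indptr)
        rows = np.repeat(np.arange(sub.shape[0]), row_nnz)
        z = (sub.data - mu[rows]) / exp_sd[rows]
        np.clip(z, -clip, clip, out=z)
        np.add.at(s1, rows, z)
        np.add.at(s2, rows, z * z)
        n_zero = n - row_nnz
        s1 += n_zero * z_zero
        s2 += n_zero * z_zero**2
        zbar = s1 / n
        score[pos] = (s2 - n * zbar**2) / (n - 1)
    return pd.Series(score, index=pd.Index(m.gene_ids, name="gene"))


def select_hvg(m: CountMatrix, n_top: int = 2000,
               loess_span: float = 0.3) -> np.ndarray:
    """Return the ``n_top`` genes with highest vst standardized variance.

    Ties are broken by gene id for determinism. If the universe holds fewer
    than ``n_top`` genes, all are returned with a warning.
    """
    score = vst_standardized_variance(m, loess_span=loess_span)
    if m.n_genes <= n_top:
        warnings.warn(
            f"only {m.n_genes} genes available; returning all", stacklevel=2)
        n_top = m.n_genes
    order = sorted(range(m.n_genes),
                   key=lambda i: (-score.iloc[i], str(m.gene_ids[i])))
    return m.gene_ids[np.array(order[:n_top])]


# ---------------------------------------------------------------------- PCA
def scale_and_clip(normed: sp.spmatrix, clip: float = 10.0) -> np.ndarray:
    """Center and unit-scale each gene (row), clipping values at ``clip``."""
    x = np.asarray(normed.todense() if sp.issparse(normed) else normed,
                   dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    np.clip(z, -clip, clip, out=z)
    return z


def pca_embed(normed_hvg: sp.spmatrix, n_pcs: int = 30,
              clip: float = 10.0) -> np.ndarray:
    """Principal-component scores (cells x n_pcs) of the scaled HVG matrix.

    The decomposition is an exact symmetric eigendecomposition of the
    gene-gene covariance, so the result is deterministic and invariant to
    cell order. Each component's sign is fixed so that its largest-magnitude
    gene loading is positive.
    """
    n_genes, n_cells = normed_hvg.shape
    if n_pcs > min(n_genes, n_cells):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(genes, cells)="
                         f"{min(n_genes, n_cells)}")
    z = scale_and_clip(normed_hvg, clip=clip)
    z -= z.mean(axis=1, keepdims=True)
    cov = (z @ z.T) / max(n_cells - 1, 1)
    # deterministic Lanczos: fixed start vector, symmetric input
    v0 = np.ones(n_genes)
    k = min(n_pcs, n_genes - 1)
    vals, vecs = eigsh(cov, k=k, which="LA", v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # sign convention: largest-|loading| entry positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = z.T @ vecs
    if k < n_pcs:  # rank-limited edge case: pad with zeros
        scores = np.hstack([scores, np.zeros((n_cells, n_pcs - k))])
    return scores


# ----------------------------------------------------------- SNN + Louvain
def snn_graph(embedding: np.ndarray, k_neighbors: int = 20,
              prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighbor set is itself plus its ``k_neighbors - 1`` nearest
    neighbors (Euclidean); edge weight between two cells is the Jaccard
    overlap of their neighbor sets, and edges below ``prune`` are removed.
    """
    n = embedding.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least {k_neighbors + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())), shape=(n, n))
    adj.data[:] = 1.0
    shared = adj @ adj.T  # |A intersect B|
    shared = shared.tocoo()
    union = 2.0 * k_neighbors - shared.data
    jacc = shared.data / union
    keep = (jacc >= prune) & (shared.row != shared.col)
    g = sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])),
                      shape=(n, n))
    return g


def _louvain(graph: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(n=graph.shape[0],
                 edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                 edge_attrs={"weight": coo.data.tolist()})
    state = ig.set_random_number_generator
    state(_random.Random(seed))
    try:
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        state(_random)
    return np.asarray(part.membership)


def snn_louvain(embedding: np.ndarray, cell_ids: np.ndarray,
                k_neighbors: int = 20, resolution: float = 0.8,
                seed: int = 0, prune: float = SNN_PRUNE) -> ClusterAssignment:
    """Cluster cells by Louvain community detection on the SNN graph."""
    if embedding.shape[0] == 0:
        raise ValueError("empty embedding")
    graph = snn_graph(embedding, k_neighbors=k_neighbors, prune=prune)
    membership = _louvain(graph, resolution=resolution, seed=seed)
    params = {"n_pcs": embedding.shape[1], "resolution": resolution,
              "k_neighbors": k_neighbors, "seed": seed}
    return relabel_by_size(membership, cell_ids, params)


# ------------------------------------------------------------ full pipeline
def cluster_sample(m: CountMatrix, min_genes: int = 500,
                   max_mito_frac: float = 0.10, n_hvg: int = 2000,
                   n_pcs: int = 30, k_neighbors: int = 20,
                   resolution: float = 0.8, seed: int = 0,
                   scale_factor: float = 1e4,
                   qc: bool = True) -> tuple[CountMatrix, sp.csr_matrix,
                                             ClusterAssignment]:
    """QC -> LogNormalize -> HVG -> PCA -> SNN/Louvain for one sample.

    Returns the QC-filtered counts, the normalized matrix over all genes,
    and the cluster assignment.
    """
    filtered = qc_filter(m, min_genes, max_mito_frac) if qc else m
    normed = log_normalize(filtered, scale_factor)
    hvg = select_hvg(filtered, n_top=n_hvg)
    gpos = pd.Index(filtered.gene_ids).get_indexer(hvg)
    emb = pca_embed(normed[gpos, :], n_pcs=n_pcs)
    clusters = snn_louvain(emb, filtered.cell_ids, k_neighbors=k_neighbors,
                           resolution=resolution, seed=seed)
    return filtered, normed, clusters


def concatenate(m1: CountMatrix, m2: CountMatrix) -> CountMatrix:
    """Concatenate two samples over their shared gene universe.

    Cell ids are prefixed with the sample label when the two samples share
    ids. Genes outside the intersection are dropped with a warning.
    """
    shared = pd.Index(m1.gene_ids).intersection(pd.Index(m2.gene_ids))
    if len(shared) == 0:
        raise ValueError("empty gene intersection between samples")
    lost = (m1.n_genes - len(shared)) + (m2.n_genes - len(shared))
    if lost:
        warnings.warn(f"dropping {lost} genes outside the shared universe",
                      stacklevel=2)
    i1 = pd.Index(m1.gene_ids).get_indexer(shared)
    i2 = pd.Index(m2.gene_ids).get_indexer(shared)
    c1, c2 = m1.subset_genes(i1), m2.subset_genes(i2)
    ids1, ids2 = c1.cell_ids, c2.cell_ids
    if set(ids1) & set(ids2):
        ids1 = np.array([f"{m1.sample_label}:{c}" for c in ids1], dtype=object)
        ids2 = np.array([f"{m2.sample_label}:{c}" for c in ids2], dtype=object)
    return CountMatrix(sp.hstack([c1.counts, c2.counts], format="csr"),
                       shared.to_numpy(dtype=object),
                       np.concatenate([ids1, ids2]),
                       sample_label=f"{m1.sample_label}+{m2.sample_label}")


def joint_cluster(m1: CountMatrix, m2: CountMatrix, resolution: float = 0.4,
                  seed: int = 0, n_hvg: int = 2000, n_pcs: int = 30,
                  k_neighbors: int = 20, qc: bool = True
                  ) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Joint clustering of two samples by naive concatenation.

    The samples are merged over their shared genes and processed as one
    (joint normalization, HVG selection, PCA, Louvain at the given
    resolution). No batch-effect correction is applied, so sample-specific
    technical structure may split clusters by sample; the per-cluster sample
    composition table returned alongside makes this visible.
    """
    merged = concatenate(m1, m2)
    _, _, clusters = cluster_sample(merged, resolution=resolution, seed=seed,
                                    n_hvg=n_hvg, n_pcs=n_pcs,
                                    k_neighbors=k_neighbors, qc=qc)
    n1 = m1.n_cells
    origin = pd.Series(
        [m1.sample_label] * n1 + [m2.sample_label] * m2.n_cells,
        index=pd.Index(merged.cell_ids, name="cell_id"), name="sample")
    origin = origin.loc[clusters.labels.index]
    comp = (pd.crosstab(clusters.labels, origin)
            .rename_axis(index="cluster"))
    return clusters, comp
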