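"""Cluster-annotating signatures by pi-score combination of pairwise DE.

For a cluster c among n_t clusters, each of the n_t - 1 pairwise
comparisons yields, per gene, a log2 fold change phi and a BH-adjusted
p-value P. The pi-score

    pi = phi * (-log10 P)

weights the effect size by the evidence against the null; a positive score
indicates up-regulation. The n_t - 1 scores per gene are combined by a
one-sided one-sample Student t-test of

    H0: mean pi = mu0   vs   H1: mean pi > mu0,

with mu0 = 2, the score of a gene exactly at the conventional
differential-up-regulation cutoff (LFC 1 at adjusted p 0.01). BH-adjusted
t-test p-values below alpha define the cluster's up-regulated signature,
truncated to the ``cas_size`` most significant genes (the CAS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as st

from .containers import ClusterAssignment
from .de import DEResult, all_pairwise_de
from .stats import P_FLOOR, bh_adjust

MU0 = 2.0
CAS_SIZE = 200
CAS_ALPHA = 0.05


def pi_score(lfc, fdr):
    """pi = lfc * (-log10 fdr); fdr floored at 1e-300.

    Scalar or vectorised. Raises on adjusted p-values outside (0, 1]
    (zeros are floored rather than rejected).
    """
    lfc = np.asarray(lfc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if (fdr < 0).any() or (fdr > 1).any():
        raise ValueError("fdr values must lie in [0, 1]")
    out = lfc * (-np.log10(np.clip(fdr, P_FLOOR, 1.0)))
    return float(out) if out.ndim == 0 else out


@dataclass
class PiScoreTable:
    """Genes x comparisons pi-scores for one cluster (NaN where a gene was
    not tested in a comparison)."""

    cluster_label: object
    values: pd.DataFrame  # index gene, one column per comparison

    @property
    def n_comparisons(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterSignature:
    """Combined DE evidence for one cluster and its CAS gene list."""

    cluster_label: object
    table: pd.DataFrame  # index gene; mean_pi, n_comparisons, t, p_value, fdr, flagged
    cas_genes: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> list:
        """All genes with FDR below the signature alpha (up-regulated by
        construction of the one-sided test)."""
        alpha = self.parameters.get("alpha", CAS_ALPHA)
        tested = self.table.dropna(subset=["fdr"])
        return list(tested.index[tested["fdr"] < alpha])

    @property
    def universe(self) -> list:
        """Genes the signature construction tested."""
        return list(self.table.index[self.table["p_value"].notna()])

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, cluster_label=None,
                 cas_size: int = CAS_SIZE, alpha: float = CAS_ALPHA
                 ) -> "ClusterSignature":
        df = pd.read_csv(path, sep="\t", index_col=0)
        label = cluster_label if cluster_label is not None else Path(path).stem
        sig = cls(label, df, parameters={"cas_size": cas_size, "alpha": alpha})
        sig.cas_genes = _cas_list(df, cas_size, alpha)
        return sig


def build_pi_table(de_results: dict[tuple, DEResult], cluster_label
                   ) -> PiScoreTable:
    """Assemble the pi-score table of one cluster from pairwise DE results."""
    cols = {}
    for (a, b), res in de_results.items():
        if a != cluster_label:
            continue
        cols[f"{a}_vs_{b}"] = pd.Series(
            pi_score(res.table["lfc"].to_numpy(), res.table["fdr"].to_numpy()),
            index=res.table.index)
    if not cols:
        raise ValueError(f"no comparisons for cluster {cluster_label!r}")
    return PiScoreTable(cluster_label, pd.DataFrame(cols))


def _cas_list(table: pd.DataFrame, cas_size: int, alpha: float) -> list:
    sig = table.dropna(subset=["fdr"])
    sig = sig[sig["fdr"] < alpha]
    # total deterministic order: fdr asc, p asc, mean_pi desc, gene id asc
    key = pd.DataFrame({
        "fdr": sig["fdr"].to_numpy(), "p": sig["p_value"].to_numpy(),
        "mpi": -sig["mean_pi"].to_numpy(), "g": sig.index.astype(str)})
    order = key.sort_values(["fdr", "p", "mpi", "g"]).index.to_numpy()
    genes = sig.index.to_numpy(dtype=object)[order]
    return list(genes[:cas_size])


def combine_cluster_signature(pi_table: PiScoreTable, mu0: float = MU0,
                              cas_size: int = CAS_SIZE,
                              alpha: float = CAS_ALPHA) -> ClusterSignature:
    """One-sided one-sample t-test of mean pi against mu0, per gene.

    Genes observed in fewer than two comparisons are reported untested
    (NaN p). Zero within-gene variance is degenerate for the t statistic;
    such genes are flagged and get p = 0 (mean above mu0), 1 (below) or
    0.5 (equal).
    """
    vals = pi_table.values.to_numpy(dtype=float)
    r = np.sum(~np.isnan(vals), axis=1).astype(float)
    mean = np.where(r > 0, np.nansum(np.nan_to_num(vals), axis=1)
                    / np.maximum(r, 1.0), np.nan)
    sd = np.full_like(mean, np.nan)
    ok2 = r >= 2
    if ok2.any():
        sd[ok2] = np.nanstd(vals[ok2], axis=1, ddof=1)

    t = np.full_like(mean, np.nan)
    p = np.full_like(mean, np.nan)
    flagged = np.zeros(mean.shape, dtype=bool)
    tested = ok2
    pos_sd = tested & (sd > 0)
    t[pos_sd] = (mean[pos_sd] - mu0) / (sd[pos_sd] / np.sqrt(r[pos_sd]))
    p[pos_sd] = st.t.sf(t[pos_sd], r[pos_sd] - 1)
    zero_sd = tested & (sd == 0)
    flagged |= zero_sd
    with np.errstate(invalid="ignore"):
        t[zero_sd] = np.where(mean[zero_sd] == mu0, 0.0,
                              np.sign(mean[zero_sd] - mu0) * np.inf)
    p[zero_sd] = np.where(mean[zero_sd] > mu0, 0.0,
                          np.where(mean[zero_sd] < mu0, 1.0, 0.5))

    table = pd.DataFrame({
        "mean_pi": mean, "n_comparisons": r.astype(int), "t": t,
        "p_value": p, "fdr": np.nan, "flagged": flagged,
    }, index=pi_table.values.index)
    idx = table.index[tested]
    table.loc[idx, "fdr"] = bh_adjust(table.loc[idx, "p_value"].to_numpy())
    params = {"mu0": mu0, "cas_size": cas_size, "alpha": alpha}
    return ClusterSignature(pi_table.cluster_label, table,
                            _cas_list(table, cas_size, alpha), params)


def build_cluster_signatures(normed: sp.csr_matrix, gene_ids: np.ndarray,
                             clusters: ClusterAssignment,
                             engine: str = "hurdle", mu0: float = MU0,
                             cas_size: int = CAS_SIZE,
                             alpha: float = CAS_ALPHA
                             ) -> dict[object, ClusterSignature]:
    """CAS for every cluster of one sample (all pairwise DE, pi-combined)."""
    if clusters.n_clusters < 2:
        raise ValueError("need at least two clusters to build signatures")
    de = all_pairwise_de(normed, gene_ids, clusters, engine=engine)
    out = {}
    for label in sorted(clusters.labels.unique()):
        pi_tab = build_pi_table(de, label)
        out[label] = combine_cluster_signature(pi_tab, mu0=mu0,
                                               cas_size=cas_size, alpha=alpha)
    return out
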