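"""Identify the disease-critical cluster and match it to control clusters.

The disease cluster is the one whose significantly up-regulated signature
genes are most enriched for a literature-derived marker panel (one-sided
Fisher's exact test). It is then matched to control-sample clusters by the
overlap of top-200 up-regulated gene lists: matches are control clusters
with log10 odds ratio >= 1 and FDR < alpha, the highlight rule of the
overlap heat map; a complete-linkage/Euclidean hierarchical-clustering
ordering of the overlap matrix is emitted for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .signatures import ClusterSignature
from .stats import bh_adjust


@dataclass
class EnrichmentRow:
    """One 2x2 over-representation test."""

    unit_label: object
    overlap_count: int
    odds_ratio: float
    log10_odds_ratio: float
    p_value: float
    fdr: float = np.nan
    table: tuple = ()  # (a, b, c, d)


def fisher_enrichment(set_a, set_b, universe) -> EnrichmentRow:
    """One-sided (over-representation) Fisher's exact test of two gene sets.

    The 2x2 table partitions the universe by membership in ``set_a`` and
    ``set_b``; the p-value is the upper hypergeometric tail P(X >= a). The
    odds ratio (ad)/(bc) uses the Haldane-Anscombe 0.5 correction when any
    cell is zero; the p-value is always from the exact test, uncorrected.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sa, sb = set(set_a) & universe, set(set_b) & universe
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(universe) - a - b - c
    n = len(universe)
    # P(X >= a) for X ~ Hypergeom(N=n, K=|A|, draws=|B|)
    p = float(st.hypergeom.sf(a - 1, n, a + b, a + c))
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    return EnrichmentRow(None, a, odds, float(np.log10(odds)),
                         min(p, 1.0), table=(a, b, c, d))


def _enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    df = pd.DataFrame({
        "unit_label": pd.array([r.unit_label for r in rows], dtype=object),
        "overlap_count": [r.overlap_count for r in rows],
        "odds_ratio": [r.odds_ratio for r in rows],
        "log10_odds_ratio": [r.log10_odds_ratio for r in rows],
        "p_value": [r.p_value for r in rows],
    })
    df["fdr"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    return df


@dataclass
class IdentificationResult:
    status: str                       # "identified" | "not_identified"
    cluster_label: object | None
    table: pd.DataFrame

    @property
    def identified(self) -> bool:
        return self.status == "identified"


def identify_disease_cluster(signatures: dict[object, ClusterSignature],
                             markers, universe=None, alpha: float = 0.05
                             ) -> IdentificationResult:
    """Marker-panel enrichment over every cluster's significant gene set.

    Each cluster's FDR-significant up-regulated genes are tested against
    the marker panel by one-sided Fisher's exact test over the tested gene
    universe; per-cluster p-values are BH-adjusted. The disease cluster is
    the smallest-p cluster (ties: larger overlap, then larger odds ratio)
    provided its marker enrichment reaches FDR < alpha; otherwise the
    status is "not_identified".
    """
    markers = list(dict.fromkeys(markers))
    if not markers:
        raise ValueError("empty marker panel")
    if not signatures:
        raise ValueError("no cluster signatures supplied")
    rows = []
    for label, sig in sorted(signatures.items(), key=lambda kv: str(kv[0])):
        uni = set(universe) if universe is not None else set(sig.universe)
        row = fisher_enrichment(sig.significant_genes, markers, uni)
        row.unit_label = label
        rows.append(row)
    table = _enrichment_table(rows).sort_values(
        by=["p_value", "overlap_count", "odds_ratio"],
        ascending=[True, False, False], kind="mergesort").reset_index(drop=True)
    best = table.iloc[0]
    if best["fdr"] < alpha and best["overlap_count"] > 0:
        return IdentificationResult("identified", best["unit_label"], table)
    return IdentificationResult("not_identified", None, table)


@dataclass
class MatchResult:
    disease_cluster_label: object
    table: pd.DataFrame               # per control cluster: overlap, OR, p, fdr
    selected_control_clusters: list
    linkage_order: list               # leaf order of the overlap-matrix clustering
    criterion: dict = field(default_factory=dict)


def match_control_clusters(disease_sig: ClusterSignature,
                           control_sigs: dict[object, ClusterSignature],
                           universe=None, or_log10_threshold: float = 1.0,
                           alpha: float = 0.05) -> MatchResult:
    """Match the disease cluster to control clusters by CAS overlap.

    Overlaps of top-200 up-regulated gene lists are tested by one-sided
    Fisher's exact test over the shared tested universe; control clusters
    with log10 OR >= ``or_log10_threshold`` and FDR < ``alpha`` are
    selected (their cells are pooled downstream). A complete-linkage,
    Euclidean-distance hierarchical clustering of the pairwise
    overlap-count matrix of all top-200 lists provides the reporting order.
    """
    if not control_sigs:
        raise ValueError("no control signatures supplied")
    if universe is None:
        uni = set(disease_sig.universe)
        for sig in control_sigs.values():
            uni &= set(sig.universe)
    else:
        uni = set(universe)
    rows = []
    items = sorted(control_sigs.items(), key=lambda kv: str(kv[0]))
    for label, sig in items:
        row = fisher_enrichment(disease_sig.cas_genes, sig.cas_genes, uni)
        row.unit_label = label
        rows.append(row)
    table = _enrichment_table(rows)
    selected = [x.item() if isinstance(x, np.generic) else x
                for x in table.loc[
                    (table["log10_odds_ratio"] >= or_log10_threshold)
                    & (table["fdr"] < alpha), "unit_label"]]
    if not selected:
        raise ValueError(
            "no control cluster matched the disease cluster (best log10 OR "
            f"{table['log10_odds_ratio'].max():.2f}, best FDR "
            f"{table['fdr'].min():.3g}); consider relaxing or_log10_threshold")

    # overlap-count matrix over [disease] + control clusters for reporting
    names = [f"disease:{disease_sig.cluster_label}"] + [
        f"control:{label}" for label, _ in items]
    gene_lists = [set(disease_sig.cas_genes) & uni] + [
        set(sig.cas_genes) & uni for _, sig in items]
    k = len(gene_lists)
    overlap = np.array([[len(gene_lists[i] & gene_lists[j]) for j in range(k)]
                        for i in range(k)], dtype=float)
    if k > 2:
        lk = linkage(pdist(overlap, metric="euclidean"), method="complete")
        order = [names[i] for i in leaves_list(lk)]
    else:
        order = names
    return MatchResult(disease_sig.cluster_label, table, selected, order,
                       {"or_log10_threshold": or_log10_threshold,
                        "alpha": alpha})
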