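"""Correlate a disease signature against a landmark-gene signature library.

The query is built from the disease-characterizing signature's most
significant genes — 125 up-regulated and 125 down-regulated at FDR < 0.05
by default — matched against the library's landmark genes. Pearson
correlation with every perturbation signature yields, per signature, a
one-sided negative-correlation p-value (H1: rho < 0): small p marks
perturbations whose transcriptional effect opposes the disease state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .disease import DiseaseSignature
from .synthetic import SignatureLibrary  # canonical library container

QUERY_N_UP = 125
QUERY_N_DOWN = 125
MIN_MATCHED_GENES = 10
_EPS = 1e-12


@dataclass
class QueryVector:
    """Signed disease-signature values over landmark-matched genes."""

    values: pd.Series           # index: matched genes
    n_selected_up: int
    n_selected_down: int
    n_selected: int             # before landmark matching
    value_kind: str

    @property
    def n_matched(self) -> int:
        return len(self.values)


def select_query_genes(dcs: DiseaseSignature, landmark_genes,
                       n_up: int = QUERY_N_UP, n_down: int = QUERY_N_DOWN,
                       alpha: float = 0.05, value: str = "lfc",
                       select_within_landmarks: bool = False) -> QueryVector:
    """Build the query vector from the DCS.

    The ``n_up`` most significant up-regulated and ``n_down`` most
    significant down-regulated genes (FDR < ``alpha``) are selected first
    and then intersected with the landmark panel (set
    ``select_within_landmarks`` to restrict the candidate pool to landmarks
    before ranking instead). Query values are the genes' log2 fold changes
    by default; ``value`` may also be ``"pi"`` or ``"signed_logfdr"``.
    """
    table = dcs.table
    if select_within_landmarks:
        table = table.loc[table.index.isin(set(landmark_genes))]
    probe = DiseaseSignature(table, dcs.provenance)
    up = probe.top_up_genes(n=n_up, alpha=alpha)
    down = probe.top_down_genes(n=n_down, alpha=alpha)
    if len(up) < n_up:
        warnings.warn(f"only {len(up)} significant up-regulated genes "
                      f"available (requested {n_up})", stacklevel=2)
    if len(down) < n_down:
        warnings.warn(f"only {len(down)} significant down-regulated genes "
                      f"available (requested {n_down})", stacklevel=2)
    selected = list(up) + list(down)
    landmarks = set(landmark_genes)
    matched = [g for g in selected if g in landmarks]
    if not matched:
        raise ValueError("no selected gene matches the landmark panel")
    sub = dcs.table.loc[matched]
    if value == "lfc":
        vals = sub["lfc"]
    elif value == "pi":
        vals = sub["pi"]
    elif value == "signed_logfdr":
        vals = np.sign(sub["lfc"]) * (-np.log10(np.clip(sub["fdr"], 1e-300, 1)))
    else:
        raise ValueError(f"unknown query value kind {value!r}")
    return QueryVector(pd.Series(vals.to_numpy(dtype=float), index=sub.index),
                       len(up), len(down), len(selected), value)


def correlate_library(q: QueryVector | pd.Series, lib: SignatureLibrary,
                      min_genes: int = MIN_MATCHED_GENES) -> pd.DataFrame:
    """Pearson correlation of the query with every library signature.

    Returns a table (index signature_id) with columns ``r``,
    ``n_matched_genes``, ``p_neg`` (one-sided lower-tail p from the exact
    t transform r * sqrt(n-2) / sqrt(1-r^2)) and ``flag`` marking
    signatures skipped for zero variance or too few matched genes.
    """
    qs = q.values if isinstance(q, QueryVector) else pd.Series(q, dtype=float)
    genes = [g for g in qs.index if g in set(lib.values.index)]
    if len(genes) < min_genes:
        raise ValueError(f"only {len(genes)} query genes match the library "
                         f"(min_genes={min_genes})")
    qv = qs.loc[genes].to_numpy(dtype=float)
    lv = lib.values.loc[genes].to_numpy(dtype=float)  # genes x signatures
    missing = np.isnan(lv)

    n = (~missing).sum(axis=0).astype(float)
    x = np.where(missing, 0.0, lv)
    qcol = qv[:, None]
    # per-signature moments of q restricted to that signature's present genes
    sum_q = (~missing).T @ qv
    sum_q2 = (~missing).T @ (qv * qv)
    sum_x = x.sum(axis=0)
    sum_x2 = (x * x).sum(axis=0)
    sum_xq = (x * qcol).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sum_xq - sum_x * sum_q / n
        var_x = sum_x2 - sum_x**2 / n
        var_q = sum_q2 - sum_q**2 / n
        r = cov / np.sqrt(var_x * var_q)

    flag = np.full(len(n), "", dtype=object)
    flag[n < min_genes] = "too_few_genes"
    zero_var = (var_x <= 0) | (var_q <= 0)
    flag[zero_var & (flag == "")] = "zero_variance"
    ok = flag == ""
    r = np.where(ok, np.clip(r, -1.0, 1.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - r**2, _EPS))
    p_neg = np.full_like(t, np.nan)
    valid = ok & (n > 2)
    p_neg[valid] = st.t.cdf(t[valid], n[valid] - 2)
    out = pd.DataFrame({
        "r": r, "n_matched_genes": n.astype(int), "p_neg": p_neg,
        "flag": flag,
    }, index=pd.Index(lib.values.columns, name="signature_id"))
    return out.sort_values("r", kind="mergesort")
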