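"""Shared statistical primitives: BH adjustment and Welch's t-test helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-300  # floor applied before taking logs of p-values


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min_{j >= i} p_(j) * n / j, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("bh_adjust: NaN p-values present")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("bh_adjust: p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t_from_moments(mean1, var1, n1, mean2, var2, n2):
    """Vectorised Welch t statistic, degrees of freedom and two-sided p.

    Degenerate cells (both variances zero, or a group with fewer than two
    observations) get p = 1 when the means agree and p ~ 0 otherwise.
    """
    mean1, var1 = np.asarray(mean1, float), np.asarray(var1, float)
    mean2, var2 = np.asarray(mean2, float), np.asarray(var2, float)
    n1 = np.broadcast_to(np.asarray(n1, float), mean1.shape)
    n2 = np.broadcast_to(np.asarray(n2, float), mean2.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = var1 / n1 + var2 / n2
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2**2 / (var1**2 / (n1**2 * (n1 - 1)) + var2**2 / (n2**2 * (n2 - 1)))
    p = np.ones_like(t)
    ok = np.isfinite(t) & np.isfinite(df) & (df > 0)
    p[ok] = 2.0 * st.t.sf(np.abs(t[ok]), df[ok])
    # zero pooled variance: identical constants -> 1, different -> ~0
    degen = ~ok
    diff = np.abs(mean1 - mean2) > 0
    p[degen & diff] = P_FLOOR
    with np.errstate(invalid="ignore"):
        t = np.where(np.isfinite(t), t,
                     np.where(diff, np.sign(mean1 - mean2) * np.inf, 0.0))
    return t, df, np.clip(p, P_FLOOR, 1.0)


def fisher_combine(p_parts: list[np.ndarray], available: list[np.ndarray]) -> np.ndarray:
    """Fisher's method over per-gene available test parts (2 df per part)."""
    x2 = np.zeros_like(np.asarray(p_parts[0], float))
    df = np.zeros_like(x2)
    for p, avail in zip(p_parts, available):
        p = np.clip(np.asarray(p, float), P_FLOOR, 1.0)
        x2 = x2 + np.where(avail, -2.0 * np.log(p), 0.0)
        df = df + np.where(avail, 2.0, 0.0)
    out = np.ones_like(x2)
    ok = df > 0
    out[ok] = st.chi2.sf(x2[ok], df[ok])
    return np.clip(out, P_FLOOR, 1.0)
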