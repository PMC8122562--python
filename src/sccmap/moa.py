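"""Mechanism-of-action enrichment by Firth-penalized logistic regression.

For each MOA category k, membership m_k of every library signature is
regressed on x = -log10 of that signature's negative-correlation p-value:

    logit Pr(m_k = 1) = beta0 + beta1 * x.

beta1 > 0 means signatures strongly anti-correlated with the disease
signature are over-represented in the MOA — the drug class is "connected"
to the disease. Because MOA categories are small relative to the library,
ordinary maximum likelihood is biased and diverges under separation; the
fit maximizes the Jeffreys-prior penalized likelihood

    l(beta) + 1/2 log det I(beta)

(Firth's correction), which is finite even under complete separation.
Inference is a penalized likelihood-ratio test, halved and signed for the
one-sided alternative beta1 > 0; BH correction is applied across MOAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .stats import P_FLOOR, bh_adjust

MIN_MOA_COUNT = 5


@dataclass
class FirthFit:
    beta: np.ndarray          # (p,) coefficients, intercept first
    covariance: np.ndarray    # inverse penalized information at the optimum
    penalized_loglik: float
    converged: bool
    n_iter: int

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[1]) if len(self.beta) > 1 else np.nan


def _penalized_loglik(y, X, beta):
    eta = X @ beta
    # log-likelihood via logaddexp for numerical stability
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(y, X, free, tol=1e-8, max_iter=50):
    """Newton iteration on the Firth-modified score for the coordinates in
    ``free``; fixed coordinates stay at 0. The penalty uses the information
    of the full design, so constrained fits are profile penalized
    likelihoods (as required by the penalized LRT)."""
    n, k = X.shape
    beta = np.zeros(k)
    pl = _penalized_loglik(y, X, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix (collinear or "
                             "constant covariate)") from exc
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        score_f = score[free]
        if np.max(np.abs(score_f)) < 1e-7:
            converged = True
            break
        info_ff = info[np.ix_(free, free)]
        step = np.linalg.solve(info_ff, score_f)
        # step-halving: never accept a decrease of the penalized likelihood
        new_pl = -np.inf
        factor = 1.0
        for _ in range(25):
            cand = beta.copy()
            cand[free] += factor * step
            new_pl = _penalized_loglik(y, X, cand)
            if new_pl >= pl - 1e-12:
                break
            factor *= 0.5
        beta_new = beta.copy()
        beta_new[free] += factor * step
        delta = np.max(np.abs(beta_new - beta))
        beta, pl = beta_new, new_pl
        if delta < tol:
            converged = True
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return FirthFit(beta, cov, pl, converged, it)


def firth_logistic_fit(y, x, tol: float = 1e-8, max_iter: int = 50
                       ) -> FirthFit:
    """Firth-penalized logistic regression of binary ``y`` on covariate ``x``
    (with intercept)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("y has a single class")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate x")
    X = np.column_stack([np.ones_like(x), x])
    return _firth_newton(y, X, free=np.array([0, 1]), tol=tol,
                         max_iter=max_iter)


def firth_intercept_fit(y, tol: float = 1e-8, max_iter: int = 50) -> FirthFit:
    """Intercept-only Firth fit (closed form: p = (k + 1/2) / (n + 1))."""
    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    return _firth_newton(y, X, free=np.array([0]), tol=tol, max_iter=max_iter)


def moa_test(y, x, fit: FirthFit | None = None, direction: str = "greater",
             method: str = "plrt") -> tuple[float, FirthFit]:
    """One-sided test of beta1 = 0 for the Firth logistic fit.

    ``plrt`` (default): penalized likelihood-ratio statistic against the
    profile fit with beta1 fixed at 0, chi-square(1) halved and sided by
    the sign of beta1 (p = pLRT/2 if beta1 favors the alternative, else
    1 - pLRT/2). ``wald`` uses the penalized-information standard error.
    """
    if direction not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown direction {direction!r}")
    if fit is None:
        fit = firth_logistic_fit(y, x)
    if not fit.converged:
        return float("nan"), fit
    if method == "plrt":
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        reduced = _firth_newton(y, X, free=np.array([0]))
        lrt = max(2.0 * (fit.penalized_loglik - reduced.penalized_loglik), 0.0)
        p_two = float(st.chi2.sf(lrt, 1))
    elif method == "wald":
        se = float(np.sqrt(fit.covariance[1, 1]))
        z = fit.beta1 / se
        p_two = float(2.0 * st.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    if direction == "two-sided":
        return p_two, fit
    favors = fit.beta1 > 0 if direction == "greater" else fit.beta1 < 0
    p = p_two / 2.0 if favors else 1.0 - p_two / 2.0
    return float(p), fit


def enrich_all_moas(conn: pd.DataFrame, metadata: pd.DataFrame,
                    min_moa_count: int = MIN_MOA_COUNT,
                    direction: str = "greater", method: str = "plrt"
                    ) -> pd.DataFrame:
    """Firth-logistic MOA enrichment over a connectivity table.

    ``conn`` is the output of :func:`~sccmap.connectivity.correlate_library`
    (index signature_id, column ``p_neg``); ``metadata`` carries
    ``signature_id`` and ``moa``. Signatures with a null MOA stay in the
    background (m_k = 0 for every k) but are never a category themselves.
    Only MOAs with at least ``min_moa_count`` signatures are tested; the
    output is BH-corrected and sorted by (fdr, odds_ratio desc).
    """
    meta = metadata.set_index("signature_id")
    conn_ok = conn[conn["p_neg"].notna()]
    shared = conn_ok.index.intersection(meta.index)
    if len(shared) == 0:
        raise ValueError("no signatures shared between connectivity table "
                         "and metadata")
    x = -np.log10(np.clip(conn_ok.loc[shared, "p_neg"].to_numpy(), P_FLOOR, 1.0))
    moa_labels = meta.loc[shared, "moa"]
    counts = moa_labels.dropna().value_counts()
    qualifying = sorted(counts.index[counts >= min_moa_count])
    if not qualifying:
        raise ValueError(f"no MOA with at least {min_moa_count} signatures")
    rows = []
    for moa in qualifying:
        y = (moa_labels == moa).to_numpy().astype(float)
        if y.all():
            raise ValueError(f"MOA {moa!r} covers every signature; no "
                             "background class to contrast against")
        p, fit = moa_test(y, x, direction=direction, method=method)
        rows.append({
            "moa": moa, "n_signatures": int(counts[moa]),
            "beta0": fit.beta0, "beta1": fit.beta1,
            "odds_ratio": float(np.exp(fit.beta1)),
            "p_value": p, "converged": fit.converged,
        })
    table = pd.DataFrame(rows)
    tested = table["p_value"].notna()
    table.loc[tested, "fdr"] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    table = table.sort_values(["fdr", "odds_ratio"], ascending=[True, False],
                              kind="mergesort").reset_index(drop=True)
    return table
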