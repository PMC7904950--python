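"""Vectorised ordinary least squares over many response columns.

A single QR factorisation of the shared design matrix is reused for every
response, which is what makes protein-wide scans over hundreds of analytes
cheap. Inference is classical: homoskedastic errors, two-sided p-values from
the t distribution with n - p degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .datatypes import NumericalError


@dataclass
class OLSFit:
    """Coefficients and classical inference for a (possibly multi-response) OLS fit.

    Arrays are (p_design, m_responses); ``df`` is the residual degrees of freedom.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: np.ndarray
    df: int
    xtx_inv: np.ndarray

    def coef(self, j: int, col: int = 0) -> tuple[float, float, float]:
        """(beta, se, p) of design column ``j`` for response ``col``."""
        return float(self.beta[j, col]), float(self.se[j, col]), float(self.p[j, col])


def ols(X: np.ndarray, Y: np.ndarray, column_names: list[str] | None = None) -> OLSFit:
    """Fit Y ~ X by least squares for every column of Y.

    Raises :class:`NumericalError` on a rank-deficient design, naming the
    collinear columns when names are supplied.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise NumericalError(f"design has {n} rows but response has {Y.shape[0]}")
    if n <= p:
        raise NumericalError(f"need more observations ({n}) than parameters ({p})")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = np.finfo(float).eps * max(n, p) * (diag.max() if diag.size else 0.0)
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        labels = (
            [column_names[i] for i in bad] if column_names is not None else bad.tolist()
        )
        raise NumericalError(f"rank-deficient design; collinear columns: {labels}")
    beta = solve_triangular(R, Q.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    r_inv = solve_triangular(R, np.eye(p))
    xtx_inv = r_inv @ r_inv.T
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(beta=beta, se=se, t=t, p=pvals, sigma2=sigma2, df=df, xtx_inv=xtx_inv)


def add_intercept(*columns: np.ndarray) -> np.ndarray:
    """Stack an intercept with the given 1-D or 2-D column blocks."""
    blocks = [np.ones((len(columns[0]), 1))]
    for c in columns:
        c = np.asarray(c, dtype=float)
        blocks.append(c[:, None] if c.ndim == 1 else c)
    return np.hstack(blocks)


def per_snp_stats(
    dosages: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Marginal per-SNP regression of ``y`` on each dosage column.

    Each SNP is fit in its own model [1, g_j, covariates]; the
    Frisch-Waugh-Lovell projection makes this a single pass. Returns
    (beta, se, p) arrays over SNPs.
    """
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    C = np.ones((n, 1)) if covariates is None else add_intercept(covariates)
    # residualise y and every dosage column on the covariate block
    Qc, _ = np.linalg.qr(C)
    y_r = y - Qc @ (Qc.T @ y)
    G_r = G - Qc @ (Qc.T @ G)
    gss = np.einsum("ij,ij->j", G_r, G_r)
    if np.any(gss <= 0):
        raise NumericalError("monomorphic variant: zero dosage variance after adjustment")
    beta = (G_r.T @ y_r) / gss
    df = n - C.shape[1] - 1
    rss = (y_r @ y_r) - beta**2 * gss
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / gss)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p
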