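"""Biweight midcorrelation (bicor) screen of expression against traits.

bicor is a median/MAD-based robust alternative to Pearson correlation: each
vector is centred on its median, observations are downweighted by the
Tukey biweight (1 - u^2)^2 with u = (x - med) / (9 * mad) and zeroed beyond
|u| >= 1, and the correlation is computed between the weighted deviations.
The screen scores every gene x trait pair and retains those with
|bicor| > r_min and p < alpha (t approximation), annotated with the usual
*/**/*** significance tiers.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError


def _biweight(x: np.ndarray) -> np.ndarray | None:
    """Weighted median-centred deviations; None when mad is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors.

    Uses the unscaled MAD with the canonical 9*mad denominator. When either
    vector has zero MAD the function falls back to Pearson correlation with
    a warning, mirroring reference implementations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bicor expects two equal-length 1-D vectors")
    if len(x) < 4:
        raise ValidationError("bicor needs at least 4 observations")
    xt, yt = _biweight(x), _biweight(y)
    if xt is None or yt is None:
        warnings.warn("zero MAD: falling back to Pearson correlation", stacklevel=2)
        if x.std() == 0 or y.std() == 0:
            raise ValidationError("degenerate vector: zero spread")
        return float(np.corrcoef(x, y)[0, 1])
    nx, ny = np.sqrt(np.sum(xt**2)), np.sqrt(np.sum(yt**2))
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("degenerate vector: all biweights are zero")
    return float(np.sum(xt * yt) / (nx * ny))


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def screen(
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    r_min: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score all gene x trait pairs; retain |bicor| > r_min and p < alpha.

    ``expr`` is genes x samples and ``traits`` is traits x samples; they are
    joined on shared sample columns. p-values use the t approximation
    t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom, two-sided.
    """
    shared = [c for c in expr.columns if c in set(traits.columns)]
    n = len(shared)
    if n < 4:
        raise ValidationError(f"need at least 4 shared samples, found {n}")
    rows = []
    for gene, gvals in expr[shared].iterrows():
        gx = gvals.to_numpy(dtype=float)
        for trait, tvals in traits[shared].iterrows():
            r = bicor(gx, tvals.to_numpy(dtype=float))
            if abs(r) >= 1.0:
                p = 0.0 if abs(r) == 1.0 and n > 2 else np.nan
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * stats.t.sf(abs(t), n - 2))
            rows.append(
                {
                    "gene": gene,
                    "trait": trait,
                    "bicor": r,
                    "p": p,
                    "n": n,
                    "retained": bool(abs(r) > r_min and p < alpha),
                    "stars": _stars(p),
                }
            )
    return pd.DataFrame(rows)
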