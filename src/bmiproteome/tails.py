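"""Extreme polygenic-score (tail-effect) analysis.

Samples are stratified by score percentile; the association model fitted on
the full sample is refitted on the pooled lower and upper strata and the
tail-to-full effect ratio beta_tail / beta_full quantifies how much steeper
the relation is at the extremes of the score distribution. Decile summaries
(mean and normal 95% CI per score decile) provide the plot data, and
BMI-associated proteins are classified as score-associated, tail-associated
(tail p < 0.05 with at least a ``ratio_min``-fold amplification), or
BMI-only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regress import ols
from .datatypes import ValidationError
from .pwas import _design


@dataclass
class TailEffectResult:
    """Full-sample vs pooled-tail regression of one outcome on the score."""

    outcome: str
    percentile: float
    beta_full: float
    se_full: float
    p_full: float
    beta_tail: float
    se_tail: float
    p_tail: float
    ratio: float
    n_tail: int


def percentile_strata(score: np.ndarray, p: float) -> tuple[np.ndarray, np.ndarray]:
    """Index sets of the lower and upper p% of the score distribution.

    Ranks use a stable sort (ties broken by sample order); each stratum has
    ceil(n*p/100) members, disjoint for p < 50 and an exact partition at
    p = 50.
    """
    score = np.asarray(score, dtype=float)
    if np.isnan(score).any():
        raise ValidationError("scores contain missing values")
    if not (0.0 < p <= 50.0):
        raise ValidationError(f"percentile must be in (0, 50], got {p}")
    n = len(score)
    m = math.ceil(n * p / 100.0)
    order = np.argsort(score, kind="stable")
    lower = order[:m]
    upper = order[max(m, n - m):]
    return lower, upper


def tail_regression(
    y: np.ndarray,
    score: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    p: float,
    outcome: str = "y",
    standardize_exposure: bool = True,
) -> TailEffectResult:
    """Full-sample OLS of y on the score, refitted on the pooled p% tails.

    The tail fit re-uses the identical design (same covariates, same scale
    of the score), restricted to the lower-and-upper strata, and the ratio
    is the signed beta_tail / beta_full.
    """
    y = np.asarray(y, dtype=float)
    X, names, _ = _design(np.asarray(score, dtype=float), covariates, standardize_exposure)
    lower, upper = percentile_strata(score, p)
    idx = np.concatenate([lower, upper])
    if len(idx) < max(10, X.shape[1] + 2):
        raise ValidationError(f"tail strata too small ({len(idx)} samples) for the design")
    full = ols(X, y, column_names=names)
    tail = ols(X[idx], y[idx], column_names=names)
    beta_full, se_full, p_full = full.coef(1)
    beta_tail, se_tail, p_tail = tail.coef(1)
    ratio = beta_tail / beta_full if beta_full != 0 else np.nan
    return TailEffectResult(
        outcome=outcome,
        percentile=p,
        beta_full=beta_full,
        se_full=se_full,
        p_full=p_full,
        beta_tail=beta_tail,
        se_tail=se_tail,
        p_tail=p_tail,
        ratio=ratio,
        n_tail=len(idx),
    )


def tail_scan(
    proteins: pd.DataFrame,
    score: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    percentiles: tuple[float, ...] = (25, 20, 15, 10, 5),
) -> pd.DataFrame:
    """Tail regressions for every protein at every requested percentile."""
    rows = []
    for pct in percentiles:
        for pid in proteins.columns:
            res = tail_regression(
                proteins[pid].to_numpy(), score, covariates, pct, outcome=str(pid)
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows).rename(columns={"outcome": "protein_id"})


def decile_summary(y: np.ndarray, score: np.ndarray) -> pd.DataFrame:
    """Mean of y with a normal 95% CI within each score decile.

    Samples are binned by ascending-score rank: decile of rank r (0-based)
    is floor(10*r/n) + 1, so decile sizes differ by at most one.
    """
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    n = len(y)
    if n < 10:
        raise ValidationError("decile summary needs at least 10 samples")
    order = np.argsort(score, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    decile = (10 * ranks) // n + 1
    rows = []
    for d in range(1, 11):
        vals = y[decile == d]
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append((d, len(vals), mean, mean - 1.96 * sem, mean + 1.96 * sem))
    return pd.DataFrame(rows, columns=["decile", "n", "mean", "ci_low", "ci_high"])


def classify_proteins(
    bmi_scan: pd.DataFrame,
    gps_scan: pd.DataFrame,
    tail_results: pd.DataFrame,
    alpha_strict: float,
    ratio_min: float = 3.0,
) -> pd.DataFrame:
    """Three-way classification of BMI-associated proteins.

    ``gps_associated`` when the score association beats ``alpha_strict``;
    otherwise ``tail_associated`` when the tail fit is nominally significant
    (p < 0.05) with |ratio| > ratio_min; otherwise ``bmi_only``. All three
    inputs must cover every protein in ``bmi_scan``.
    """
    gps = gps_scan.set_index("protein_id")
    tails = tail_results.set_index("protein_id")
    rows = []
    for pid in bmi_scan["protein_id"]:
        if pid not in gps.index or pid not in tails.index:
            raise ValidationError(f"protein {pid!r} missing from gps or tail results")
        p_gps = float(gps.loc[pid, "p"])
        t = tails.loc[pid]
        if isinstance(t, pd.DataFrame):  # several percentiles: use the smallest
            t = t.sort_values("percentile").iloc[0]
        if p_gps < alpha_strict:
            label = "gps_associated"
        elif float(t["p_tail"]) < 0.05 and abs(float(t["ratio"])) > ratio_min:
            label = "tail_associated"
        else:
            label = "bmi_only"
        rows.append((pid, label))
    return pd.DataFrame(rows, columns=["protein_id", "protein_class"])
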