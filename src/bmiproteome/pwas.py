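"""Protein-wide association scans with replication and subsampling power.

Protein levels arrive as positive relative abundances, are log2 transformed
and z-scored, and each analyte is regressed on an exposure (BMI or a
polygenic score) with covariate adjustment by ordinary least squares. The
scan's family-wise error is controlled by Bonferroni correction; a
discovery replicates in a second study when it is both significant at the
replication threshold and directionally concordant. Replication power at a
smaller study size is estimated by refitting on repeated subsamples without
replacement and taking the 0.05*reps-th order statistic of the p-values
(the "p95" procedure: the p-value achievable with 95% probability).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regress import add_intercept, ols
from .datatypes import ValidationError
from .scorer import standardize

BASIC_COVARIATES = ["age", "sex"]
FULL_COVARIATES = ["age", "sex", "smoking", "alcohol", "physical_activity", "diabetes"]


@dataclass
class PowerResult:
    """p95 subsampling summary for one protein-exposure pair."""

    protein_id: str
    p95: float
    n_sub: int
    reps: int
    powered: bool
    alpha: float


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def preprocess_proteins(raw: pd.DataFrame) -> pd.DataFrame:
    """log2-transform then z-score (sample SD) every protein column.

    Raises on non-positive values, naming the protein and sample, and on
    constant columns.
    """
    values = raw.to_numpy(dtype=float)
    bad = np.argwhere(~(values > 0.0) | ~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"non-positive protein value for protein {raw.columns[c]!r}, "
            f"sample {raw.index[r]!r}: {values[r, c]}"
        )
    logged = np.log2(values)
    sd = logged.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        raise ValidationError(
            f"zero variance after log2 for proteins: {[raw.columns[i] for i in flat]}"
        )
    z = (logged - logged.mean(axis=0)) / sd
    return pd.DataFrame(z, index=raw.index, columns=raw.columns)


def _design(
    exposure: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    standardize_exposure: bool,
) -> tuple[np.ndarray, list[str], list[str]]:
    exposure = np.asarray(exposure, dtype=float)
    if standardize_exposure:
        exposure = standardize(exposure, name="exposure")
    if covariates is None:
        cov_names: list[str] = []
        X = add_intercept(exposure)
    else:
        if isinstance(covariates, pd.DataFrame):
            cov_names = [str(c) for c in covariates.columns]
            C = covariates.to_numpy(dtype=float)
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            cov_names = [f"cov{i}" for i in range(C.shape[1])]
        X = add_intercept(exposure, C)
    return X, ["intercept", "exposure"] + cov_names, cov_names


def association_scan(
    proteins: pd.DataFrame,
    exposure: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    exposure_name: str = "bmi",
    model: str = "basic",
    standardize_exposure: bool = True,
) -> pd.DataFrame:
    """OLS of every (standardized) protein on [1, exposure, covariates].

    With ``standardize_exposure`` (default) betas are in SD-per-SD units;
    set it False to keep the exposure on its raw scale (e.g. kg/m^2).
    Returns one row per protein: beta, se, p (t reference), n, model.
    """
    Y = proteins.to_numpy(dtype=float)
    if len(Y) != len(np.asarray(exposure)):
        raise ValidationError("proteins and exposure have different sample counts")
    X, names, cov_names = _design(np.asarray(exposure, dtype=float), covariates, standardize_exposure)
    fit = ols(X, Y, column_names=names)
    return pd.DataFrame(
        {
            "protein_id": list(proteins.columns),
            "exposure": exposure_name,
            "beta": fit.beta[1],
            "se": fit.se[1],
            "p": fit.p[1],
            "n": len(Y),
            "model": model,
            "covariates": ",".join(cov_names),
        }
    )


def assess_replication(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Per-protein replication status plus the cross-study effect correlation.

    The replication threshold is ``alpha / m`` with m the number of
    discovery proteins present in the replication table. Status is
    ``replicated`` (significant and sign-concordant), ``concordant_only``,
    ``discordant``, or ``missing``.
    """
    rep = replication.set_index("protein_id")
    shared = [p for p in discovery["protein_id"] if p in rep.index]
    if not shared:
        raise ValidationError("no shared proteins between discovery and replication")
    threshold = bonferroni_threshold(alpha, len(shared))
    rows = []
    for rec in discovery.itertuples(index=False):
        if rec.protein_id not in rep.index:
            rows.append((rec.protein_id, rec.beta, np.nan, np.nan, "missing"))
            continue
        r = rep.loc[rec.protein_id]
        concordant = np.sign(rec.beta) == np.sign(r["beta"])
        if concordant and r["p"] < threshold:
            status = "replicated"
        elif concordant:
            status = "concordant_only"
        else:
            status = "discordant"
        rows.append((rec.protein_id, rec.beta, r["beta"], r["p"], status))
    table = pd.DataFrame(
        rows, columns=["protein_id", "beta_discovery", "beta_replication", "p_replication", "status"]
    )
    table["threshold"] = threshold
    both = table.dropna(subset=["beta_replication"])
    corr = float(np.corrcoef(both["beta_discovery"], both["beta_replication"])[0, 1]) if len(both) > 1 else np.nan
    return table, corr


def subsample_power(
    protein: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    n_sub: int = 356,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05 / 184,
    protein_id: str = "protein",
    standardize_exposure: bool = True,
) -> PowerResult:
    """p95 replication power by repeated subsampling without replacement.

    Refits the association on ``reps`` subsamples of size ``n_sub`` and
    returns the ceil(0.05*reps)-th smallest p-value (for reps = 1000, the
    50th smallest); ``powered`` is True when that p95 beats ``alpha``.
    """
    y = np.asarray(protein, dtype=float)
    n = len(y)
    if n_sub > n:
        raise ValidationError(f"n_sub {n_sub} exceeds sample size {n}")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    X, names, _ = _design(np.asarray(exposure, dtype=float), covariates, standardize_exposure)
    rng = np.random.default_rng(seed)
    pvals = np.empty(reps)
    for i in range(reps):
        idx = rng.choice(n, size=n_sub, replace=False)
        fit = ols(X[idx], y[idx], column_names=names)
        pvals[i] = fit.p[1, 0]
    k = math.ceil(0.05 * reps)
    p95 = float(np.sort(pvals)[k - 1])
    return PowerResult(
        protein_id=protein_id, p95=p95, n_sub=n_sub, reps=reps, powered=p95 < alpha, alpha=alpha
    )
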