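"""Bidirectional Mendelian randomization.

Instrument selection follows genome-wide practice: keep SNPs with
p < 1e-8 and F > 10 for the exposure, drop SNPs associated with a
confounder at p < 1e-8, and greedily LD-clump (ascending p, pairwise
dosage r^2 <= 0.001 within a window against every accepted SNP).
Exposure and outcome summary statistics are harmonized onto the same
effect allele, dropping palindromic SNPs.

Estimators are implemented from first principles:

* Wald ratio by/bx with the first-order delta-method SE sy/|bx|;
* fixed-effect inverse-variance weighting (IVW), equivalent to weighted
  regression of outcome betas on exposure betas through the origin with
  weights 1/sy^2, with Cochran's Q heterogeneity statistic;
* MR-Egger: the same weighted regression with a free intercept (directional
  pleiotropy), SNPs re-oriented so bx >= 0;
* one-sample two-stage least squares (2SLS) with a polygenic score or an
  allelic score as the instrument, classical SEs computed from residuals
  against the actual exposure.

``run_bidirectional`` assembles the bidirectional report: per protein,
one-sample and two-sample estimates in both causal directions, with typed
"no instruments" markers instead of exceptions when selection comes back
empty.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._regress import add_intercept, ols, per_snp_stats
from .datatypes import GenotypeMatrix, ValidationError, is_palindromic
from .scorer import standardize

SUMMARY_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]

#: Default clumping window; the r^2 threshold is the headline parameter,
#: pairwise correlations are only evaluated within this distance.
DEFAULT_CLUMP_WINDOW_BP = 10_000_000

NO_INSTRUMENTS = "no_instruments"
INSUFFICIENT = "insufficient_instruments"
NOT_AVAILABLE = "not_available"
OK = "ok"


@dataclass
class MREstimate:
    """A causal-effect record from one MR method."""

    method: str
    beta: float = np.nan
    se: float = np.nan
    p: float = np.nan
    n_snps: int = 0
    status: str = OK
    q_stat: float = np.nan
    q_p: float = np.nan
    egger_intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_p: float = np.nan
    first_stage_f: float = np.nan

    @classmethod
    def unavailable(cls, method: str, status: str) -> "MREstimate":
        return cls(method=method, status=status)


@dataclass
class MRInstrumentSet:
    """Harmonized per-SNP summary statistics ready for estimation."""

    table: pd.DataFrame  # beta_exposure, se_exposure, beta_outcome, se_outcome, ...
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.table)


def _require_columns(df: pd.DataFrame, cols: list[str], label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{label} table missing columns: {missing}")


def select_instruments(
    exposure_stats: pd.DataFrame,
    p_max: float = 1e-8,
    f_min: float = 10.0,
    clump_r2: float = 0.001,
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    ld_reference: GenotypeMatrix | None = None,
    confounders: pd.DataFrame | None = None,
    confounder_p: float = 1e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter and LD-clump exposure summary statistics into instruments.

    Returns (instruments, removals); removals carries a reason per dropped
    SNP (weak, confounder, clumped). An empty result is returned, not
    raised — callers map it to a "no instruments" outcome.
    """
    _require_columns(exposure_stats, SUMMARY_COLUMNS, "exposure")
    df = exposure_stats.copy()
    if df["variant_id"].duplicated().any():
        raise ValidationError("duplicate variant_id in exposure stats")
    df["f_stat"] = (df["beta"] / df["se"]) ** 2
    removals = []

    weak = (df["p"] >= p_max) | (df["f_stat"] <= f_min)
    for vid in df.loc[weak, "variant_id"]:
        removals.append((vid, "weak"))
    df = df.loc[~weak]

    if confounders is not None and len(confounders):
        _require_columns(confounders, ["variant_id", "trait", "p"], "confounder")
        confounded = set(
            confounders.loc[confounders["p"] < confounder_p, "variant_id"]
        )
        hit = df["variant_id"].isin(confounded)
        for vid in df.loc[hit, "variant_id"]:
            removals.append((vid, "confounder"))
        df = df.loc[~hit]

    # greedy clumping: accept by ascending p unless correlated with an
    # already-accepted SNP on the same chromosome within the window
    df = df.sort_values(["p", "variant_id"], kind="stable")
    accepted: list[pd.Series] = []
    if ld_reference is not None:
        index = ld_reference.variant_index
        for _, row in df.iterrows():
            ok = True
            if row["variant_id"] in index:
                g = ld_reference.dosages[:, index[row["variant_id"]]]
                for prev in accepted:
                    if prev["chrom"] != row["chrom"]:
                        continue
                    if abs(int(prev["pos"]) - int(row["pos"])) > clump_window_bp:
                        continue
                    if prev["variant_id"] not in index:
                        continue
                    h = ld_reference.dosages[:, index[prev["variant_id"]]]
                    if g.std() == 0 or h.std() == 0:
                        continue
                    r2 = float(np.corrcoef(g, h)[0, 1] ** 2)
                    if r2 > clump_r2:
                        ok = False
                        break
            if ok:
                accepted.append(row)
            else:
                removals.append((row["variant_id"], "clumped"))
        df = pd.DataFrame(accepted, columns=df.columns) if accepted else df.iloc[0:0]

    removals_df = pd.DataFrame(removals, columns=["variant_id", "reason"])
    return df.reset_index(drop=True), removals_df


def harmonize_summary_stats(
    exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame
) -> MRInstrumentSet:
    """Align outcome betas onto the exposure effect allele.

    SNPs present in both tables are kept; when the outcome effect allele is
    the exposure's other allele the outcome beta is negated and alleles
    swapped; palindromic (A/T, C/G) and allele-incompatible SNPs are
    dropped with a recorded reason.
    """
    _require_columns(exposure_stats, SUMMARY_COLUMNS, "exposure")
    _require_columns(outcome_stats, ["variant_id", "effect_allele", "other_allele", "beta", "se"], "outcome")
    out = outcome_stats.set_index("variant_id")
    rows, dropped = [], []
    for rec in exposure_stats.itertuples(index=False):
        if rec.variant_id not in out.index:
            dropped.append((rec.variant_id, "missing_from_outcome"))
            continue
        if is_palindromic(rec.effect_allele, rec.other_allele):
            dropped.append((rec.variant_id, "palindromic"))
            continue
        o = out.loc[rec.variant_id]
        if o["effect_allele"] == rec.effect_allele and o["other_allele"] == rec.other_allele:
            by = float(o["beta"])
        elif o["effect_allele"] == rec.other_allele and o["other_allele"] == rec.effect_allele:
            by = -float(o["beta"])
        else:
            dropped.append((rec.variant_id, "allele_mismatch"))
            continue
        f_stat = (rec.beta / rec.se) ** 2
        rows.append(
            (
                rec.variant_id, rec.chrom, rec.pos, rec.effect_allele, rec.other_allele,
                float(rec.beta), float(rec.se), float(rec.p), f_stat, by, float(o["se"]),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "beta_exposure", "se_exposure", "p_exposure", "f_stat",
            "beta_outcome", "se_outcome",
        ],
    )
    return MRInstrumentSet(table=table, dropped=pd.DataFrame(dropped, columns=["variant_id", "reason"]))


def wald_ratio(bx: float, sx: float, by: float, sy: float, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate by/bx.

    The default SE is the first-order delta method sy/|bx| (exposure
    uncertainty ignored); ``second_order`` adds the bx-uncertainty term.
    """
    if bx == 0:
        raise ValidationError("null instrument: exposure beta is zero")
    beta = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta != 0 else 1.0)
    return MREstimate(method="wald", beta=float(beta), se=float(se), p=float(p), n_snps=1)


def ivw(instruments: MRInstrumentSet | pd.DataFrame, random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate with Cochran's Q.

    beta = sum(bx*by/sy^2) / sum(bx^2/sy^2); se = 1/sqrt(sum(bx^2/sy^2)).
    One SNP reduces to the Wald ratio (Q undefined). ``random_effects``
    inflates the SE by sqrt(Q/(k-1)) when Q/(k-1) > 1 (multiplicative
    random-effects model).
    """
    df = instruments.table if isinstance(instruments, MRInstrumentSet) else instruments
    k = len(df)
    if k == 0:
        return MREstimate.unavailable("ivw", NO_INSTRUMENTS)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    if np.any(sy <= 0):
        raise ValidationError("outcome SEs must be positive")
    if k == 1:
        est = wald_ratio(bx[0], float(df["se_exposure"].iloc[0]), by[0], sy[0])
        est.method = "ivw"
        return est
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / denom
    se = 1.0 / np.sqrt(denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if random_effects and q / (k - 1) > 1.0:
        se = se * np.sqrt(q / (k - 1))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    q_p = float(stats.chi2.sf(q, k - 1))
    return MREstimate(method="ivw", beta=float(beta), se=float(se), p=float(p), n_snps=k, q_stat=q, q_p=q_p)


def mr_egger(instruments: MRInstrumentSet | pd.DataFrame) -> MREstimate:
    """Weighted regression of outcome on exposure betas with a free intercept.

    SNPs are re-oriented so bx >= 0; weights are 1/sy^2; the intercept
    estimates directional pleiotropy and its two-sided p uses a t(k-2)
    reference. SEs use the estimated residual scale (no floor), which keeps
    the intercept test exactly calibrated under the no-pleiotropy null.
    """
    df = instruments.table if isinstance(instruments, MRInstrumentSet) else instruments
    k = len(df)
    if k < 3:
        return MREstimate.unavailable("egger", INSUFFICIENT if k else NO_INSTRUMENTS)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy
    X = np.column_stack([w, w * bx])  # weighted design: intercept, slope
    fit = ols(X, w * by, column_names=["intercept", "slope"])
    a, a_se, a_p = fit.coef(0)
    b, b_se, b_p = fit.coef(1)
    resid_q = float(fit.sigma2[0] * fit.df)  # residual heterogeneity Q'
    return MREstimate(
        method="egger",
        beta=b,
        se=b_se,
        p=b_p,
        n_snps=k,
        q_stat=resid_q,
        q_p=float(stats.chi2.sf(resid_q, k - 2)),
        egger_intercept=a,
        intercept_se=a_se,
        intercept_p=a_p,
    )


def two_stage_least_squares(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> MREstimate:
    """One-sample MR by two-stage least squares with a single instrument.

    Stage 1 regresses the exposure x on [1, z, covariates]; stage 2
    regresses the outcome y on [1, x_hat, covariates]. The SE is classical
    2SLS: residuals are computed against the actual x at the stage-2
    coefficients. The first-stage F of the instrument is recorded.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.std() == 0:
        raise ValidationError("irrelevant instrument: zero first-stage slope")
    if covariates is None:
        C = None
        X1 = add_intercept(z)
    else:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X1 = add_intercept(z, C)
    stage1 = ols(X1, x, column_names=["intercept", "z"])
    gamma, g_se, _ = stage1.coef(1)
    if gamma == 0:
        raise ValidationError("irrelevant instrument: zero first-stage slope")
    f_stat = (gamma / g_se) ** 2
    x_hat = X1 @ stage1.beta[:, 0]
    X2 = add_intercept(x_hat) if C is None else add_intercept(x_hat, C)
    stage2 = ols(X2, y, column_names=["intercept", "x_hat"])
    beta_vec = stage2.beta[:, 0]
    # classical 2SLS variance: residuals from the ACTUAL exposure
    X2_actual = add_intercept(x) if C is None else add_intercept(x, C)
    resid = y - X2_actual @ beta_vec
    n, p_design = X2.shape
    df = n - p_design
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * stage2.xtx_inv[1, 1]))
    beta = float(beta_vec[1])
    p = float(2.0 * stats.t.sf(abs(beta) / se, df))
    return MREstimate(method="tsls", beta=beta, se=se, p=p, n_snps=1, first_stage_f=float(f_stat), status=OK)


def summary_stats(
    geno: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Marginal per-SNP association statistics of ``y`` across all variants."""
    C = None
    if covariates is not None:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    beta, se, p = per_snp_stats(geno.dosages, np.asarray(y, dtype=float), C)
    meta = geno.meta_frame()
    return pd.DataFrame(
        {
            "variant_id": meta["variant_id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "effect_allele": meta["effect_allele"],
            "other_allele": meta["other_allele"],
            "beta": beta,
            "se": se,
            "p": p,
            "n": geno.n_samples,
        }
    )


def _estimate_cell_2smr(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    ld_reference: GenotypeMatrix | None,
    confounders: pd.DataFrame | None,
    p_max: float,
    f_min: float,
    clump_r2: float,
) -> MREstimate:
    selected, _ = select_instruments(
        exposure_stats,
        p_max=p_max,
        f_min=f_min,
        clump_r2=clump_r2,
        ld_reference=ld_reference,
        confounders=confounders,
    )
    if selected.empty:
        return MREstimate.unavailable("ivw", NO_INSTRUMENTS)
    harmonized = harmonize_summary_stats(selected, outcome_stats)
    if len(harmonized) == 0:
        return MREstimate.unavailable("ivw", NO_INSTRUMENTS)
    return ivw(harmonized)


def run_bidirectional(
    cohort,
    second=None,
    protein_ids: list[str] | None = None,
    covariate_columns: list[str] = ("age", "sex"),
    p_max: float = 1e-8,
    f_min: float = 10.0,
    clump_r2: float = 0.001,
    confounders: pd.DataFrame | None = None,
    alpha: float = 0.05 / 152,
    max_reverse_1smr_instruments: int = 2,
) -> pd.DataFrame:
    """Four-cell bidirectional MR report per protein.

    Forward (BMI -> protein): one-sample 2SLS with the cohort's polygenic
    score instrumenting BMI, and two-sample IVW with per-SNP BMI stats as
    exposure. Reverse (protein -> BMI): one-sample 2SLS with an allelic
    score of at most ``max_reverse_1smr_instruments`` strongest selected
    cis SNPs, and two-sample IVW with per-SNP protein stats as exposure.
    When ``second`` (an independent cohort under the same truth) is given,
    its summary statistics provide the two-sample outcome side; otherwise
    the same cohort is reused (one-sample approximation to 2SMR).

    ``cohort`` needs attributes geno, phenotypes, proteins, weights. The
    direction flags apply ``alpha`` to the better-powered cell per direction:
    1SMR forward, 2SMR reverse.
    """
    from .pwas import preprocess_proteins  # local import to avoid a cycle
    from .scorer import compute_gps

    geno = cohort.geno
    pheno = cohort.phenotypes
    prot_std = preprocess_proteins(cohort.proteins)
    gps = compute_gps(geno, cohort.weights).standardized_score
    bmi = pheno["bmi"].to_numpy(dtype=float)
    covs = pheno[list(covariate_columns)]
    z_bmi = standardize(bmi, name="bmi")

    other = second if second is not None else cohort
    other_pheno = other.phenotypes
    other_prot = preprocess_proteins(other.proteins)
    other_covs = other_pheno[list(covariate_columns)]
    other_bmi = other_pheno["bmi"].to_numpy(dtype=float)

    bmi_stats_a = summary_stats(geno, bmi, covs)
    bmi_stats_b = summary_stats(other.geno, other_bmi, other_covs)

    ids = protein_ids if protein_ids is not None else list(prot_std.columns)
    rows = []
    for pid in ids:
        if pid not in prot_std.columns:
            raise ValidationError(f"protein {pid!r} not in cohort proteins")
        y = prot_std[pid].to_numpy(dtype=float)

        # forward 1SMR: protein ~ BMI instrumented by the polygenic score
        fwd1 = two_stage_least_squares(y, z_bmi, gps, covs)

        # forward 2SMR: BMI summary stats (cohort A) vs protein stats (cohort B)
        prot_stats_b = summary_stats(other.geno, other_prot[pid].to_numpy(dtype=float), other_covs)
        fwd2 = _estimate_cell_2smr(
            bmi_stats_a, prot_stats_b, geno, confounders, p_max, f_min, clump_r2
        )

        # reverse: instruments from the protein's own summary stats (cohort A)
        prot_stats_a = summary_stats(geno, y, covs)
        selected, _ = select_instruments(
            prot_stats_a, p_max=p_max, f_min=f_min, clump_r2=clump_r2,
            ld_reference=geno, confounders=confounders,
        )
        if selected.empty:
            rev1 = MREstimate.unavailable("tsls", NO_INSTRUMENTS)
            rev2 = MREstimate.unavailable("ivw", NO_INSTRUMENTS)
        else:
            top = selected.nsmallest(max_reverse_1smr_instruments, "p")
            cols = [geno.variant_index[v] for v in top["variant_id"]]
            allelic = geno.dosages[:, cols] @ top["beta"].to_numpy(dtype=float)
            rev1 = two_stage_least_squares(z_bmi, y, allelic, covs)
            rev2 = _estimate_cell_2smr(
                prot_stats_a, bmi_stats_b, geno, confounders, p_max, f_min, clump_r2
            )

        fwd_sig = fwd1.status == OK and fwd1.p < alpha
        rev_sig = rev2.status == OK and rev2.p < alpha
        concordant = (
            np.sign(fwd1.beta) == np.sign(fwd2.beta)
            if fwd1.status == OK and fwd2.status == OK
            else np.nan
        )
        rows.append(
            {
                "protein_id": pid,
                "fwd_1smr_beta": fwd1.beta, "fwd_1smr_p": fwd1.p, "fwd_1smr_status": fwd1.status,
                "fwd_1smr_f": fwd1.first_stage_f,
                "fwd_2smr_beta": fwd2.beta, "fwd_2smr_p": fwd2.p, "fwd_2smr_status": fwd2.status,
                "fwd_2smr_nsnps": fwd2.n_snps,
                "rev_1smr_beta": rev1.beta, "rev_1smr_p": rev1.p, "rev_1smr_status": rev1.status,
                "rev_2smr_beta": rev2.beta, "rev_2smr_p": rev2.p, "rev_2smr_status": rev2.status,
                "rev_2smr_nsnps": rev2.n_snps,
                "forward_significant": fwd_sig,
                "reverse_significant": rev_sig,
                "forward_concordant_1smr_2smr": concordant,
            }
        )
    return pd.DataFrame(rows)
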