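"""Genome-wide polygenic score computation.

A score is the weighted sum of risk-allele dosages over the variants of a
weight table. Before scoring, weights are harmonized to the dosage-counted
allele of the genotype data: strand-ambiguous (A/T, C/G) variants are
dropped, weights reported on the other allele are flipped (dosage d becomes
2 - d), and unmatched rows are dropped and counted. Optionally all variants
within a window of a gene locus are excluded, which is how *cis* effects on
the encoded protein are removed from the score. Scores are standardized to
mean 0, sample SD 1 (n - 1 denominator).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GeneLocus,
    GenotypeMatrix,
    NumericalError,
    ValidationError,
    VariantMeta,
)

#: Default cis-exclusion window around the gene interval, in base pairs.
DEFAULT_CIS_WINDOW_BP = 100_000_000

WEIGHT_COLUMNS = ["variant_id", "effect_allele", "weight"]


@dataclass
class HarmonizationReport:
    """Bookkeeping of weight rows dropped during harmonization."""

    n_input: int = 0
    n_retained: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_unmatched: int = 0
    n_dropped_missing: int = 0
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class GPSVector:
    """Per-sample polygenic score, raw and standardized, with drop counts."""

    sample_ids: list[str]
    raw_score: np.ndarray
    standardized_score: np.ndarray
    n_variants_used: int
    n_dropped_ambiguous: int = 0
    n_dropped_unmatched: int = 0
    n_dropped_cis: int = 0
    n_imputed_dosages: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_score": self.raw_score,
                "gps": self.standardized_score,
            }
        )


def standardize(values: np.ndarray, name: str | None = None) -> np.ndarray:
    """Z-score a vector using the sample SD (n - 1).

    Raises :class:`NumericalError` on constant input, naming the offending
    column when ``name`` is given.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("standardize expects a 1-D vector")
    if len(x) < 2:
        raise ValidationError("standardize needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"non-finite values in {name or 'input'}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise NumericalError(f"zero variance in {name or 'input'}; cannot standardize")
    return (x - x.mean()) / sd


def _check_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValidationError(f"weight table missing columns: {missing}")
    if weights["variant_id"].duplicated().any():
        dupes = weights.loc[weights["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValidationError(f"duplicate variant_ids in weight table: {dupes}")
    if not np.all(np.isfinite(weights["weight"].to_numpy(dtype=float))):
        raise ValidationError("non-finite weights in weight table")
    return weights


def harmonize_weights(
    variants: list[VariantMeta], weights: pd.DataFrame
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align a weight table to the dosage-counted alleles of the genotype data.

    Returns the retained rows with an added ``orientation`` column (DIRECT or
    FLIP) plus a report of everything dropped: strand-ambiguous variants,
    rows whose effect allele matches neither genotype allele, and rows absent
    from the genotype metadata. Nothing here is fatal; mismatches are counted.
    """
    if not variants or weights.empty:
        raise ValidationError("harmonize_weights needs non-empty variants and weights")
    _check_weight_table(weights)
    meta = {v.variant_id: v for v in variants}
    report = HarmonizationReport(n_input=len(weights))
    rows, dropped = [], []
    for rec in weights.itertuples(index=False):
        var = meta.get(rec.variant_id)
        if var is None:
            report.n_dropped_missing += 1
            dropped.append((rec.variant_id, "missing_from_genotypes"))
            continue
        if var.is_ambiguous:
            report.n_dropped_ambiguous += 1
            dropped.append((rec.variant_id, "ambiguous"))
            continue
        if rec.effect_allele == var.effect_allele:
            orientation = "DIRECT"
        elif rec.effect_allele == var.other_allele:
            orientation = "FLIP"
        else:
            report.n_dropped_unmatched += 1
            dropped.append((rec.variant_id, "unmatched_allele"))
            continue
        rows.append((rec.variant_id, rec.effect_allele, float(rec.weight), orientation))
    aligned = pd.DataFrame(rows, columns=WEIGHT_COLUMNS + ["orientation"])
    report.n_retained = len(aligned)
    report.dropped = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    return aligned, report


def _cis_mask(variants: list[VariantMeta], locus: GeneLocus, window_bp: int) -> np.ndarray:
    """Boolean mask of variants inside [start - w, end + w] on the locus chromosome."""
    lo, hi = locus.start - window_bp, locus.end + window_bp
    return np.array(
        [v.chrom == locus.chrom and lo <= v.pos <= hi for v in variants], dtype=bool
    )


def compute_gps(
    geno: GenotypeMatrix,
    weights: pd.DataFrame,
    exclude: GeneLocus | None = None,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> GPSVector:
    """Compute the polygenic score of every sample.

    ``weights`` may be raw (harmonization is applied internally) or already
    aligned (an ``orientation`` column is present). With ``exclude`` given,
    variants within ``window_bp`` of the gene interval on the same chromosome
    are omitted from the sum and counted in ``n_dropped_cis``.
    """
    if "orientation" in weights.columns:
        aligned, report = weights, HarmonizationReport(n_input=len(weights), n_retained=len(weights))
    else:
        aligned, report = harmonize_weights(geno.variants, weights)

    index = geno.variant_index
    keep = aligned
    n_dropped_cis = 0
    if exclude is not None:
        mask = _cis_mask(geno.variants, exclude, window_bp)
        in_window = keep["variant_id"].map(lambda vid: bool(mask[index[vid]]))
        n_dropped_cis = int(in_window.sum())
        keep = keep.loc[~in_window]
    if keep.empty:
        raise NumericalError("no usable variants remain for score computation")

    cols = np.array([index[vid] for vid in keep["variant_id"]])
    D = geno.dosages[:, cols]
    n_imputed = 0
    if np.isnan(D).any():
        # PLINK-like mean-dosage imputation per variant for missing entries
        n_imputed = int(np.isnan(D).sum())
        means = np.nanmean(D, axis=0)
        D = np.where(np.isnan(D), means, D)
    w = keep["weight"].to_numpy(dtype=float)
    flip = (keep["orientation"] == "FLIP").to_numpy()
    # FLIP rows count the other allele: dosage becomes 2 - d
    raw = (np.where(flip, 2.0, 0.0) - np.where(flip, 1.0, -1.0) * D) @ w
    std = standardize(raw, name="raw polygenic score") if geno.n_samples >= 2 else raw.copy()
    return GPSVector(
        sample_ids=list(geno.sample_ids),
        raw_score=raw,
        standardized_score=std,
        n_variants_used=len(keep),
        n_dropped_ambiguous=report.n_dropped_ambiguous,
        n_dropped_unmatched=report.n_dropped_unmatched,
        n_dropped_cis=n_dropped_cis,
        n_imputed_dosages=n_imputed,
    )
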