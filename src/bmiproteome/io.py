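"""Readers and writers for the on-disk TSV formats.

Everything is tab-separated UTF-8 with a header row and '.' decimal
separator. Readers validate headers against the documented schemas and
reject out-of-contract values (dosages outside [0, 2], non-biallelic
alleles) with the offending row/column named. An optional VCF 4.2 reader
(DS format field) is provided for dosages; the TSV path is canonical.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneLocus, GenotypeMatrix, ValidationError, VariantMeta

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "maf"]
PHENOTYPE_COLUMNS = ["sample_id", "bmi", "age", "sex"]


def _read_tsv(path: str | Path, required: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "sample_id", "chrom", "gene"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{label} file {path}: missing columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_variant_table(path: str | Path) -> list[VariantMeta]:
    df = _read_tsv(path, VARIANT_COLUMNS, "variant metadata")
    variants = []
    for i, rec in enumerate(df.itertuples(index=False)):
        try:
            variants.append(
                VariantMeta(
                    variant_id=str(rec.variant_id),
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    effect_allele=str(rec.effect_allele),
                    other_allele=str(rec.other_allele),
                    maf=float(rec.maf),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"variant file {path}, line {i + 2}: {err}") from err
    return variants


def read_dosage_bundle(dosage_path: str | Path, variants_path: str | Path) -> GenotypeMatrix:
    """Load a dosage TSV (sample_id + one column per variant) with metadata.

    The dosage header must match the metadata variant_ids one-to-one;
    dosages outside [0, 2] are rejected with row and column named.
    """
    variants = read_variant_table(variants_path)
    df = pd.read_csv(dosage_path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValidationError(f"dosage file {dosage_path}: first column must be 'sample_id'")
    header = list(df.columns[1:])
    meta_ids = [v.variant_id for v in variants]
    if set(header) != set(meta_ids):
        only_meta = sorted(set(meta_ids) - set(header))
        only_dose = sorted(set(header) - set(meta_ids))
        raise ValidationError(
            f"dosage/metadata mismatch: missing from dosages {only_meta}, "
            f"missing from metadata {only_dose}"
        )
    by_id = {v.variant_id: v for v in variants}
    ordered = [by_id[h] for h in header]
    dosages = df[header].to_numpy(dtype=float)
    bad = np.argwhere(~((dosages >= 0) & (dosages <= 2)) & ~np.isnan(dosages))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"dosage file {dosage_path}: value {dosages[r, c]} out of [0, 2] at "
            f"sample {df.iloc[r, 0]!r}, variant {header[c]!r} (line {r + 2})"
        )
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df["sample_id"]], variants=ordered, dosages=dosages
    )


def write_dosage_bundle(geno: GenotypeMatrix, dosage_path: str | Path, variants_path: str | Path) -> None:
    dose = geno.dosage_frame().reset_index(names="sample_id")
    write_tsv(dose, dosage_path)
    write_tsv(geno.meta_frame(), variants_path)


def read_weight_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["variant_id", "effect_allele", "weight"], "weight")
    df["weight"] = df["weight"].astype(float)
    return df


def read_gene_loci(path: str | Path) -> dict[str, GeneLocus]:
    """BED-like TSV (gene, chrom, start, end), 1-based inclusive."""
    df = _read_tsv(path, ["gene", "chrom", "start", "end"], "gene loci")
    return {
        str(r.gene): GeneLocus(str(r.gene), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    }


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, PHENOTYPE_COLUMNS, "phenotype")
    if (df["bmi"].astype(float) <= 0).any():
        bad = df.loc[df["bmi"].astype(float) <= 0, "sample_id"].iloc[0]
        raise ValidationError(f"phenotype file {path}: non-positive BMI for sample {bad!r}")
    return df


def read_protein_matrix(path: str | Path) -> pd.DataFrame:
    """Samples x proteins positive abundance matrix (first column sample_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValidationError(f"protein file {path}: first column must be 'sample_id'")
    return df.set_index("sample_id")


def write_protein_matrix(proteins: pd.DataFrame, path: str | Path) -> None:
    write_tsv(proteins.reset_index(names="sample_id"), path)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"],
        "summary statistics",
    )
    for col in ("beta", "se", "p"):
        df[col] = df[col].astype(float)
    df["pos"] = df["pos"].astype(int)
    return df


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read dosages from the DS FORMAT field of a VCF 4.2 file.

    Requires cyvcf2. Only biallelic SNVs are accepted; the ALT allele is the
    dosage-counted (effect) allele and the maf is estimated from the data.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading VCF dosages requires the cyvcf2 package") from err
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValidationError(
                f"VCF {path}: non-biallelic or non-SNV record at {rec.CHROM}:{rec.POS}"
            )
        ds = rec.format("DS")
        if ds is None:
            raise ValidationError(f"VCF {path}: missing DS field at {rec.CHROM}:{rec.POS}")
        d = np.asarray(ds, dtype=float).reshape(-1)
        af = float(np.nanmean(d) / 2.0)
        maf = min(af, 1.0 - af)
        if maf <= 0.0:
            raise ValidationError(f"VCF {path}: monomorphic variant at {rec.CHROM}:{rec.POS}")
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantMeta(
                variant_id=vid,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                effect_allele=str(rec.ALT[0]),
                other_allele=str(rec.REF),
                maf=maf,
            )
        )
        columns.append(d)
    if not variants:
        raise ValidationError(f"VCF {path}: no variant records")
    return GenotypeMatrix(
        sample_ids=sample_ids, variants=variants, dosages=np.column_stack(columns)
    )


def write_cohort(cohort, out_dir: str | Path, confounders: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write every table of a simulated cohort; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": out / "dosages.tsv",
        "variants": out / "variants.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "proteins": out / "proteins.tsv",
        "weights": out / "weights.tsv",
        "truth": out / "truth.tsv",
    }
    write_dosage_bundle(cohort.geno, paths["dosages"], paths["variants"])
    write_tsv(cohort.phenotypes, paths["phenotypes"])
    write_protein_matrix(cohort.proteins, paths["proteins"])
    write_tsv(cohort.weights, paths["weights"])
    write_tsv(cohort.truth, paths["truth"])
    if confounders is not None:
        paths["confounders"] = out / "confounders.tsv"
        write_tsv(confounders, paths["confounders"])
    return paths
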