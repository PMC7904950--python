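"""Shared domain containers: variants, dosage matrices, gene loci.

Dosages are expected allele counts in [0, 2] from imputed genotypes; each
variant carries the allele pair and minor-allele frequency used downstream
for harmonization and Hardy-Weinberg simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = frozenset("ACGT")
#: Allele pairs that cannot be strand-resolved from the alleles alone.
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class NumericalError(RuntimeError):
    """Raised when a computation is degenerate (zero variance, rank deficiency...)."""


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """True for A/T or C/G pairs, whose strand orientation is ambiguous."""
    return frozenset((allele_a.upper(), allele_b.upper())) in AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class VariantMeta:
    """Descriptor of a biallelic variant.

    ``effect_allele`` is the dosage-counted allele; ``maf`` the frequency of
    that allele, in (0, 0.5] by convention.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in _BASES:
                raise ValidationError(
                    f"{self.variant_id}: {name} must be a single base in ACGT, got {allele!r}"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: effect and other allele are identical")
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"{self.variant_id}: maf must be in (0, 0.5], got {self.maf}")

    @property
    def is_ambiguous(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass(frozen=True)
class GeneLocus:
    """1-based inclusive genomic interval of a protein-coding gene."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene}: start {self.start} > end {self.end}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus per-variant metadata."""

    sample_ids: list[str]
    variants: list[VariantMeta]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate variant_ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise ValidationError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def variant_index(self) -> dict[str, int]:
        return {v.variant_id: i for i, v in enumerate(self.variants)}

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant."""
        return self.dosages[:, self.variant_index[variant_id]]

    def meta_frame(self) -> pd.DataFrame:
        """Per-variant metadata as a DataFrame (one row per variant)."""
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "maf": [v.maf for v in self.variants],
            }
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.variant_ids)
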