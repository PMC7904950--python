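import numpy as np
import pytest

from bmiproteome import SimConfig, simulate_cohort
from bmiproteome.datatypes import VariantMeta


@pytest.fixture(scope="session")
def small_cohort():
    """A modest four-regime cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_samples=1500, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_variants(n, maf=0.3, chrom="1", spacing=1_000_000, prefix="rs"):
    pairs = [("A", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
    return [
        VariantMeta(
            variant_id=f"{prefix}{i}",
            chrom=chrom,
            pos=1_000_000 + spacing * i,
            effect_allele=pairs[i % 4][0],
            other_allele=pairs[i % 4][1],
            maf=maf,
        )
        for i in range(n)
    ]
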