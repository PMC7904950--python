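"""Robust biweight-midcorrelation screen of expression against traits.

Builds a small expression matrix with one trait-linked gene, one
outlier-contaminated gene and noise genes, and retains gene-trait pairs
with |bicor| > 0.1 and p < 0.05 — showing why the median-based bicor is
preferred over Pearson when outliers are present.
"""
import numpy as np
import pandas as pd

import bmiproteome as bp

rng = np.random.default_rng(6)
n = 300
samples = [f"m{i}" for i in range(n)]
trait = rng.normal(size=n)

linked = 0.5 * trait + rng.normal(size=n) * 0.9
contaminated = 0.5 * trait + rng.normal(size=n) * 0.9
idx = rng.choice(n, size=6, replace=False)
contaminated[idx] = rng.normal(size=6) * 12  # 2% gross outliers

expr = pd.DataFrame(
    [linked, contaminated, rng.normal(size=n), rng.normal(size=n)],
    index=["Lep_like", "Lep_like_outliers", "noise_1", "noise_2"],
    columns=samples,
)
traits = pd.DataFrame([trait], index=["fat_mass"], columns=samples)

table = bp.screen(expr, traits, r_min=0.1, alpha=0.05)
print(table.to_string(index=False))
print()
r_pe = np.corrcoef(contaminated, trait)[0, 1]
r_bi = bp.bicor(contaminated, trait)
print(f"contaminated gene: Pearson {r_pe:.3f} vs bicor {r_bi:.3f} "
      f"(bicor downweights the outliers and keeps the true signal ~0.5)")
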