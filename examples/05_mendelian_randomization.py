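"""Bidirectional Mendelian randomization against known ground truth.

Simulates two independent 5000-sample cohorts sharing the same genetic
architecture, runs one-sample 2SLS (score-instrumented) and two-sample IVW
(cis-instrumented) in both causal directions for each of the four regime
proteins, and compares the flags with the generative truth.
"""
import pandas as pd

import bmiproteome as bp

pd.set_option("display.width", 200)

cfg = bp.SimConfig(n_samples=5000, seed=4)
cohort = bp.simulate_cohort(cfg)
second = bp.replication_cohort(cfg, n_samples=5000)

report = bp.run_bidirectional(cohort, second=second, alpha=0.05 / 152)
cols = ["protein_id", "fwd_1smr_beta", "fwd_1smr_p", "rev_2smr_beta", "rev_2smr_p",
        "forward_significant", "reverse_significant"]
print("Bidirectional MR report (forward = BMI->protein 2SLS, reverse = protein->BMI IVW):")
print(report[cols].to_string(index=False))
print()
print("Expected pattern from the generative truth:")
print(cohort.truth[["protein_id", "regime"]].to_string(index=False))
print()
print("bmi_to_protein should flag forward only; protein_to_bmi reverse only;")
print("bidirectional both; confounded_null neither (the spurious observational")
print("correlation is removed by instrumenting).")
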