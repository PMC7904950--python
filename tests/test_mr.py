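"""MR estimators against closed forms and oracles; selection and harmonization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmiproteome import (
    harmonize_summary_stats,
    ivw,
    mr_egger,
    select_instruments,
    simulate_genotypes,
    simulate_mr_summary_stats,
    two_stage_least_squares,
    wald_ratio,
)
from bmiproteome.datatypes import ValidationError
from bmiproteome.mr import NO_INSTRUMENTS

from conftest import make_variants


def _stats_df(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"],
    )


def _instruments(bx, sx, by, sy):
    return pd.DataFrame(
        {
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
        }
    )


class TestSelectInstruments:
    def test_single_strong_snp_retained(self):
        df = _stats_df([("rs1", "1", 100, "A", "G", 0.1, 0.1 / 5, 1e-9)])
        selected, removed = select_instruments(df)
        assert selected["variant_id"].tolist() == ["rs1"]
        assert removed.empty

    def test_weak_snp_removed(self):
        df = _stats_df(
            [
                ("rs1", "1", 100, "A", "G", 0.1, 0.02, 1e-9),
                ("rs2", "1", 200, "A", "G", 0.01, 0.02, 0.5),
            ]
        )
        selected, removed = select_instruments(df)
        assert selected["variant_id"].tolist() == ["rs1"]
        assert dict(zip(removed["variant_id"], removed["reason"])) == {"rs2": "weak"}

    def test_ld_clumping_keeps_most_significant(self):
        specs = make_variants(2, maf=0.3, spacing=10_000)
        geno = simulate_genotypes(4000, specs, seed=2, ld_pairs=[("rs0", "rs1", 0.5)])
        df = _stats_df(
            [
                ("rs0", "1", specs[0].pos, "A", "G", 0.10, 0.012, 1e-9),
                ("rs1", "1", specs[1].pos, "T", "C", 0.12, 0.012, 1e-12),
            ]
        )
        selected, removed = select_instruments(df, ld_reference=geno)
        assert selected["variant_id"].tolist() == ["rs1"]  # smaller p wins
        assert dict(zip(removed["variant_id"], removed["reason"])) == {"rs0": "clumped"}

    def test_confounded_snp_removed(self):
        df = _stats_df([("rs1", "1", 100, "A", "G", 0.1, 0.012, 1e-9)])
        conf = pd.DataFrame({"variant_id": ["rs1"], "trait": ["education"], "p": [5e-9]})
        selected, removed = select_instruments(df, confounders=conf)
        assert selected.empty
        assert removed["reason"].tolist() == ["confounder"]

    def test_empty_result_is_not_an_exception(self):
        df = _stats_df([("rs1", "1", 100, "A", "G", 0.01, 0.02, 0.5)])
        selected, _ = select_instruments(df)
        assert selected.empty
        assert ivw(_instruments([], [], [], [])).status == NO_INSTRUMENTS


class TestHarmonize:
    def test_swapped_alleles_negate_outcome(self):
        exp = _stats_df([("rs1", "1", 100, "A", "G", 0.1, 0.01, 1e-9)])
        out = _stats_df([("rs1", "1", 100, "G", "A", 0.05, 0.02, 0.01)])
        h = harmonize_summary_stats(exp, out)
        assert h.table["beta_outcome"].iloc[0] == pytest.approx(-0.05)

    def test_palindromic_dropped(self):
        exp = _stats_df([("rs1", "1", 100, "A", "T", 0.1, 0.01, 1e-9)])
        out = _stats_df([("rs1", "1", 100, "A", "T", 0.05, 0.02, 0.01)])
        h = harmonize_summary_stats(exp, out)
        assert len(h) == 0
        assert h.dropped["reason"].tolist() == ["palindromic"]

    def test_identical_coding_passthrough_and_fstat(self):
        exp = _stats_df([("rs1", "1", 100, "A", "G", 0.1, 0.02, 1e-9)])
        out = _stats_df([("rs1", "1", 100, "A", "G", 0.05, 0.02, 0.01)])
        h = harmonize_summary_stats(exp, out)
        assert h.table["beta_outcome"].iloc[0] == pytest.approx(0.05)
        assert h.table["f_stat"].iloc[0] == pytest.approx((0.1 / 0.02) ** 2, abs=1e-9)

    def test_incompatible_alleles_dropped_with_reason(self):
        exp = _stats_df([("rs1", "1", 100, "A", "G", 0.1, 0.01, 1e-9)])
        out = _stats_df([("rs1", "1", 100, "T", "C", 0.05, 0.02, 0.01)])
        h = harmonize_summary_stats(exp, out)
        assert h.dropped["reason"].tolist() == ["allele_mismatch"]


class TestWaldRatio:
    def test_point_estimate_and_se(self):
        est = wald_ratio(0.5, 0.01, 0.25, 0.1)
        assert est.beta == pytest.approx(0.5)
        est2 = wald_ratio(2.0, 0.01, 0.4, 0.1)
        assert est2.se == pytest.approx(0.05)

    def test_zero_outcome_beta(self):
        est = wald_ratio(0.5, 0.01, 0.0, 0.1)
        assert est.beta == 0.0 and est.p == pytest.approx(1.0)

    def test_null_instrument_rejected(self):
        with pytest.raises(ValidationError, match="null instrument"):
            wald_ratio(0.0, 0.01, 0.1, 0.1)


class TestIVW:
    def test_single_snp_equals_wald(self):
        inst = _instruments([0.3], [0.01], [0.12], [0.05])
        w = wald_ratio(0.3, 0.01, 0.12, 0.05)
        est = ivw(inst)
        assert est.beta == w.beta and est.se == w.se and est.p == w.p

    def test_shared_ratio_gives_zero_q(self, rng):
        bx = rng.uniform(0.05, 0.2, 6)
        inst = _instruments(bx, 0.01, 1.7 * bx, rng.uniform(0.02, 0.08, 6))
        est = ivw(inst)
        assert est.beta == pytest.approx(1.7, abs=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_matches_wls_through_origin_oracle(self, rng):
        # independent normal-equations oracle with explicit sums
        for _ in range(50):
            k = rng.integers(3, 12)
            bx = rng.normal(0.1, 0.05, k)
            by = rng.normal(0.05, 0.05, k)
            sy = rng.uniform(0.01, 0.1, k)
            est = ivw(_instruments(bx, 0.01, by, sy))
            w = 1.0 / sy**2
            beta_oracle = float(np.sum(w * bx * by) / np.sum(w * bx**2))
            se_oracle = float(1.0 / np.sqrt(np.sum(w * bx**2)))
            assert est.beta == pytest.approx(beta_oracle, abs=1e-10)
            assert est.se == pytest.approx(se_oracle, abs=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_ordering_and_joint_signflip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        df = _instruments(
            rng.normal(0.1, 0.05, k), 0.01, rng.normal(0.0, 0.05, k), rng.uniform(0.01, 0.1, k)
        )
        base = ivw(df)
        shuffled = df.sample(frac=1, random_state=int(rng.integers(1e6))).reset_index(drop=True)
        assert ivw(shuffled).beta == pytest.approx(base.beta, abs=1e-12)
        assert ivw(shuffled).q_stat == pytest.approx(base.q_stat, abs=1e-9)
        flipped = df.copy()
        pick = rng.random(k) < 0.5
        flipped.loc[pick, ["beta_exposure", "beta_outcome"]] *= -1
        assert ivw(flipped).beta == pytest.approx(base.beta, abs=1e-12)


class TestEgger:
    def test_exact_affine_fit_recovered(self, rng):
        bx = np.abs(rng.normal(0.2, 0.05, 8))
        inst = _instruments(bx, 0.01, 0.03 + 1.5 * bx, rng.uniform(0.02, 0.08, 8))
        est = mr_egger(inst)
        assert est.beta == pytest.approx(1.5, abs=1e-9)
        assert est.egger_intercept == pytest.approx(0.03, abs=1e-9)
        assert est.q_stat == pytest.approx(0.0, abs=1e-15)

    def test_zero_intercept_exact_fit_matches_ivw(self, rng):
        bx = np.abs(rng.normal(0.2, 0.05, 8))
        inst = _instruments(bx, 0.01, 1.5 * bx, rng.uniform(0.02, 0.08, 8))
        assert mr_egger(inst).beta == pytest.approx(ivw(inst).beta, abs=1e-9)

    def test_matches_statsmodels_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(50):
            k = 10
            bx = np.abs(rng.normal(0.15, 0.05, k))
            by = rng.normal(0.02, 0.05, k)
            sy = rng.uniform(0.02, 0.1, k)
            est = mr_egger(_instruments(bx, 0.01, by, sy))
            ref = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
            assert est.beta == pytest.approx(ref.params[1], abs=1e-10)
            assert est.se == pytest.approx(ref.bse[1], abs=1e-10)
            assert est.egger_intercept == pytest.approx(ref.params[0], abs=1e-10)
            assert est.intercept_se == pytest.approx(ref.bse[0], abs=1e-10)
            assert est.intercept_p == pytest.approx(ref.pvalues[0], abs=1e-10)

    def test_too_few_snps(self):
        est = mr_egger(_instruments([0.1, 0.2], [0.01, 0.01], [0.0, 0.1], [0.05, 0.05]))
        assert est.status == "insufficient_instruments"


class TestTSLS:
    def test_perfect_instrument_equals_ols(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        est = two_stage_least_squares(y, x, z=x)
        from bmiproteome._regress import add_intercept, ols

        ref = ols(add_intercept(x), y)
        assert est.beta == pytest.approx(ref.beta[1, 0], abs=1e-10)

    def test_single_instrument_closed_form(self, rng):
        n = 500
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        est = two_stage_least_squares(y, x, z)
        closed = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
        assert est.beta == pytest.approx(closed, abs=1e-10)

    def test_reduced_form_wald_identity(self, rng):
        # 2SLS equals the ratio of the two reduced-form slopes
        n = 400
        z = rng.normal(size=n)
        x = 0.4 * z + rng.normal(size=n)
        y = 0.2 * x + rng.normal(size=n)
        est = two_stage_least_squares(y, x, z)
        from bmiproteome._regress import add_intercept, ols

        bzy = ols(add_intercept(z), y).beta[1, 0]
        bzx = ols(add_intercept(z), x).beta[1, 0]
        assert est.beta == pytest.approx(bzy / bzx, abs=1e-10)

    def test_irrelevant_instrument_rejected(self, rng):
        n = 50
        x = rng.normal(size=n)
        with pytest.raises(ValidationError, match="irrelevant"):
            two_stage_least_squares(rng.normal(size=n), x, z=np.zeros(n))


class TestCalibration:
    def test_ivw_coverage_ninety_five_percent(self):
        hits = 0
        n_sims, beta = 400, 0.3
        for s in range(n_sims):
            exp, out = simulate_mr_summary_stats(20, beta, seed=9000 + s)
            h = harmonize_summary_stats(exp, out)
            est = ivw(h)
            if abs(est.beta - beta) < 1.96 * est.se:
                hits += 1
        assert 0.92 <= hits / n_sims <= 0.98

    def test_egger_intercept_type_one_error(self):
        rejections = 0
        n_sims = 400
        for s in range(n_sims):
            exp, out = simulate_mr_summary_stats(20, 0.3, seed=15_000 + s)
            est = mr_egger(harmonize_summary_stats(exp, out))
            rejections += int(est.intercept_p < 0.05)
        assert 0.03 <= rejections / n_sims <= 0.08
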