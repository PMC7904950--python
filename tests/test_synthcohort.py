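"""Generator contracts: determinism, Hardy-Weinberg frequencies, causal truth."""
import numpy as np
import pandas as pd
import pytest

from bmiproteome import (
    RegimeSpec,
    SimConfig,
    hinge_link,
    make_confounder_catalog,
    simulate_cohort,
    simulate_genotypes,
    simulate_traits,
)
from bmiproteome.datatypes import ValidationError, VariantMeta
from bmiproteome.synthcohort import hinge_link_variance, resolve_beta_gps

from conftest import make_variants


class TestSimulateGenotypes:
    def test_deterministic_given_seed(self):
        specs = make_variants(8)
        a = simulate_genotypes(500, specs, seed=7)
        b = simulate_genotypes(500, specs, seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        c = simulate_genotypes(500, specs, seed=8)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_allele_frequency_matches_maf(self):
        specs = [VariantMeta("rs1", "1", 100, "A", "G", 0.3)]
        geno = simulate_genotypes(20_000, specs, seed=1)
        emp = geno.dosages.mean() / 2.0
        assert abs(emp - 0.3) < 0.01
        assert set(np.unique(geno.dosages)) <= {0.0, 1.0, 2.0}

    def test_palindromic_variant_generated_without_complaint(self):
        # generation is allele-agnostic; ambiguity matters only downstream
        specs = [VariantMeta("rs_at", "1", 100, "A", "T", 0.5)]
        geno = simulate_genotypes(50, specs, seed=3)
        assert geno.variants[0].is_ambiguous

    def test_ld_pair_reaches_target_r2(self):
        specs = make_variants(2, maf=0.3)
        geno = simulate_genotypes(30_000, specs, seed=5, ld_pairs=[("rs0", "rs1", 0.5)])
        r2 = np.corrcoef(geno.dosages[:, 0], geno.dosages[:, 1])[0, 1] ** 2
        assert abs(r2 - 0.5) < 0.04

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            VariantMeta("rs1", "1", 100, "A", "G", 0.7)
        dup = make_variants(1) * 2
        with pytest.raises(ValidationError, match="duplicate"):
            simulate_genotypes(10, dup, seed=0)


class TestSimulateTraits:
    def test_global_null_gives_uniform_pvalues(self):
        from bmiproteome import association_scan, preprocess_proteins

        regimes = [
            RegimeSpec(f"P{i}", "bmi_to_protein", alpha=0.0, delta=0.0) for i in range(40)
        ]
        cfg = SimConfig(n_samples=800, regimes=regimes, seed=3)
        cohort = simulate_cohort(cfg)
        prot = preprocess_proteins(cohort.proteins)
        scan = association_scan(prot, cohort.phenotypes["bmi"], cohort.phenotypes[["age", "sex"]])
        # under the null p-values are U(0,1); crude band on the mean
        assert 0.35 < scan["p"].mean() < 0.65
        assert scan["p"].min() > 1e-5  # no wild outliers among 40 nulls

    def test_score_explains_configured_bmi_variance(self):
        from bmiproteome import compute_gps

        cfg = SimConfig(
            n_samples=10_000,
            regimes=[RegimeSpec("P0", "bmi_to_protein", alpha=0.1, delta=0.3)],
            gps_r2=0.14,
            seed=11,
        )
        cohort = simulate_cohort(cfg)
        gps = compute_gps(cohort.geno, cohort.weights).standardized_score
        r2 = np.corrcoef(gps, cohort.phenotypes["bmi"])[0, 1] ** 2
        assert abs(r2 - 0.14) < 0.02

    def test_forward_regime_recovers_alpha(self):
        # OLS of standardized protein on z(BMI) averages to alpha/sd(P)
        from bmiproteome import preprocess_proteins, standardize
        from bmiproteome._regress import add_intercept, ols

        alpha, est = 0.10, []
        for r in range(60):
            cfg = SimConfig(
                n_samples=5000,
                regimes=[RegimeSpec("P0", "bmi_to_protein", alpha=alpha, delta=0.0)],
                seed=500 + r,
            )
            cohort = simulate_cohort(cfg)
            y = preprocess_proteins(cohort.proteins)["P0"].to_numpy()
            zb = standardize(cohort.phenotypes["bmi"].to_numpy())
            est.append(ols(add_intercept(zb), y).beta[1, 0])
        sd_p = np.sqrt(alpha**2 + 1.0)  # generative protein SD (delta = 0)
        mcse = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - alpha / sd_p) < 3 * mcse

    def test_confounded_null_biases_ols_away_from_zero(self, small_cohort):
        from bmiproteome import preprocess_proteins, standardize
        from bmiproteome._regress import add_intercept, ols

        truth = small_cohort.truth.set_index("protein_id")
        assert truth.loc["PROT_CONF", "regime"] == "confounded_null"
        assert truth.loc["PROT_CONF", "alpha"] == 0.0  # no causal edge
        y = preprocess_proteins(small_cohort.proteins)["PROT_CONF"].to_numpy()
        zb = standardize(small_cohort.phenotypes["bmi"].to_numpy())
        fit = ols(add_intercept(zb), y)
        assert abs(fit.beta[1, 0] / fit.se[1, 0]) > 5  # spurious association

    def test_k_below_one_rejected(self):
        with pytest.raises(ValidationError, match="amplification_k"):
            SimConfig(amplification_k=0.5)
        with pytest.raises(ValidationError):
            hinge_link(np.zeros(5), k=0.5, q=0.9)

    def test_insufficient_cis_variants_rejected(self):
        cfg = SimConfig(n_samples=50, seed=0)
        geno = simulate_genotypes(50, make_variants(5), seed=0)
        with pytest.raises(ValidationError, match="needs"):
            simulate_traits(geno, cfg)

    def test_proteins_positive_scale(self, small_cohort):
        assert (small_cohort.proteins.to_numpy() > 0).all()

    def test_truth_lists_existing_cis_instruments(self, small_cohort):
        known = set(small_cohort.geno.variant_ids)
        for ids in small_cohort.truth["cis_variants"]:
            assert set(ids.split(";")) <= known


class TestHingeLink:
    def test_identity_when_k_is_one(self, rng):
        s = rng.standard_normal(1000)
        assert np.allclose(hinge_link(s, 1.0, 0.9), s)

    def test_slope_k_beyond_hinge(self, rng):
        s = rng.standard_normal(10_000)
        t = np.quantile(np.abs(s), 0.9)
        l = hinge_link(s, 4.0, 0.9)
        far = np.abs(s) > t
        np.testing.assert_allclose((l[far] - np.sign(s[far]) * t) / (np.abs(s[far]) - t),
                                   4.0 * np.sign(s[far]), rtol=1e-10)

    def test_variance_formula_matches_simulation(self, rng):
        s = rng.standard_normal(400_000)
        for k, q in [(1.0, 0.9), (4.0, 0.9), (2.0, 0.8)]:
            emp = hinge_link(s, k, q).var()
            assert abs(emp - hinge_link_variance(k, q)) / hinge_link_variance(k, q) < 0.03

    def test_resolved_beta_reproduces_r2_identity(self):
        cfg = SimConfig(gps_r2=0.2)
        beta = resolve_beta_gps(cfg)
        var_rest = (
            cfg.beta_age**2 * 36**2 / 12 + cfg.beta_sex**2 * 0.48 * 0.52 + cfg.noise_sd**2
        )
        r2 = beta**2 / (beta**2 + var_rest)
        assert abs(r2 - 0.2) < 1e-12


class TestConfounderCatalog:
    def test_no_planting_gives_no_genomewide_hits(self, small_cohort):
        cat = make_confounder_catalog(small_cohort.geno, ["education"], seed=1)
        assert (cat["p"] >= 1e-8).all()

    def test_planted_variants_are_exactly_the_sub_threshold_set(self, small_cohort):
        vids = small_cohort.geno.variant_ids[:3]
        cat = make_confounder_catalog(
            small_cohort.geno, ["education", "smoking"], seed=1,
            planted={"education": vids},
        )
        hits = cat.loc[cat["p"] < 1e-8]
        assert sorted(hits["variant_id"]) == sorted(vids)
        assert set(hits["trait"]) == {"education"}

    def test_round_trip(self, small_cohort, tmp_path):
        from bmiproteome.io import write_tsv

        cat = make_confounder_catalog(small_cohort.geno, ["education"], seed=1)
        path = tmp_path / "conf.tsv"
        write_tsv(cat, path)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(cat.reset_index(drop=True), back, check_exact=False)

    def test_unknown_planted_variant_rejected(self, small_cohort):
        with pytest.raises(ValidationError, match="not in genotype"):
            make_confounder_catalog(
                small_cohort.geno, ["education"], seed=1, planted={"education": ["nope"]}
            )


def test_cohort_fully_deterministic():
    a = simulate_cohort(SimConfig(n_samples=200, seed=9))
    b = simulate_cohort(SimConfig(n_samples=200, seed=9))
    assert np.array_equal(a.geno.dosages, b.geno.dosages)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.proteins, b.proteins)
    pd.testing.assert_frame_equal(a.weights, b.weights)


def test_replication_cohort_shares_structure_not_samples():
    cfg = SimConfig(n_samples=300, seed=4)
    a = simulate_cohort(cfg)
    b = __import__("bmiproteome").replication_cohort(cfg, n_samples=250)
    pd.testing.assert_frame_equal(a.weights, b.weights)  # same true score weights
    assert a.geno.variant_ids == b.geno.variant_ids
    assert b.geno.n_samples == 250
    assert not np.array_equal(a.geno.dosages[:250], b.geno.dosages)
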