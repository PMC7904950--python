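"""Synthetic cohorts with known causal structure.

The generator emulates the statistical assumptions of a population cohort in
which body mass index (BMI) is partly driven by a genome-wide polygenic
score and plasma protein levels relate to BMI under one of four causal
regimes:

``bmi_to_protein``
    P = alpha * z(BMI) + delta * G_cis + e  — BMI causally shifts the protein.
``protein_to_bmi``
    P = delta * G_cis + e, then BMI += theta * P — the protein drives BMI.
``bidirectional``
    the protein feeds BMI and the final readout adds the BMI response.
``confounded_null``
    a shared latent confounder moves both BMI and the protein with no causal
    edge between them.

Genotypes are Hardy-Weinberg Binomial(2, maf) dosages, independent across
variants except for explicitly declared LD pairs (needed to exercise
clumping). BMI responds to the standardized score S through a
piecewise-linear link L(S) that is the identity inside the central
``amplification_q`` mass of |S| and has slope ``amplification_k`` beyond the
hinge, so the extreme-score tail effect can be switched on (k > 1) or off
(k = 1). Protein matrices are emitted on a positive exp2 scale so the
downstream log2 + z-score preprocessing has real work to do.

Everything is bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ValidationError, VariantMeta

REGIMES = ("bmi_to_protein", "protein_to_bmi", "bidirectional", "confounded_null")

_AGE_RANGE = (43.0, 79.0)  # years, mid-life European population cohort
_MALE_FRACTION = 0.48
_PROTEIN_LOG2_OFFSET = 10.0  # shifts log2 protein levels onto a positive RFU-like scale


@dataclass(frozen=True)
class RegimeSpec:
    """Causal regime and effect sizes of one simulated protein.

    alpha: BMI -> protein effect, protein units per SD of BMI.
    theta: protein -> BMI effect, kg/m^2 per protein unit.
    delta: cis-pQTL effect, protein units per effect allele.
    """

    protein_id: str
    regime: str
    alpha: float = 0.0
    theta: float = 0.0
    delta: float = 0.0
    n_cis: int | None = None  # falls back to SimConfig.n_cis_variants_per_protein

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"{self.protein_id}: unknown regime {self.regime!r}")
        for name in ("alpha", "theta", "delta"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValidationError(f"{self.protein_id}: effect size {name} is missing")


def canonical_regime_panel() -> list[RegimeSpec]:
    """One protein per causal regime at the package's reference effect sizes.

    The sizes (alpha=0.35, theta=0.45, delta=0.8, three cis instruments at
    maf 0.3) were fixed by analytic power calculation — accounting for the
    protein-standardisation attenuation alpha/sd(P) of the 2SLS estimand —
    so that, at n = 5000 and a per-test alpha of 0.05/152, the correct
    causal direction is detected with >95% power in each directed regime.
    """
    return [
        RegimeSpec("PROT_FWD", "bmi_to_protein", alpha=0.35, delta=0.8),
        RegimeSpec("PROT_REV", "protein_to_bmi", theta=0.45, delta=0.8),
        RegimeSpec("PROT_BOTH", "bidirectional", alpha=0.35, theta=0.45, delta=0.8),
        RegimeSpec("PROT_CONF", "confounded_null", delta=0.8),
    ]


def default_regime_panel(n_proteins: int, seed: int = 0) -> list[RegimeSpec]:
    """A mixed panel for pipeline demonstrations.

    Forward effects are drawn in a realistic association-scan range
    (|alpha| in 0.04-0.30 with both signs) and a share of proteins are pure
    nulls (alpha = theta = delta = 0), so a scan produces a plausible mix of
    hits and non-hits.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    specs: list[RegimeSpec] = []
    kinds = ["bmi_to_protein", "protein_to_bmi", "bidirectional", "confounded_null", "null"]
    probs = [0.40, 0.15, 0.10, 0.15, 0.20]
    for i in range(n_proteins):
        kind = rng.choice(kinds, p=probs)
        sign = rng.choice([-1.0, 1.0])
        pid = f"SOMA_{i + 1:04d}"
        if kind == "null":
            specs.append(RegimeSpec(pid, "bmi_to_protein", alpha=0.0, delta=0.0))
        elif kind == "bmi_to_protein":
            specs.append(
                RegimeSpec(pid, kind, alpha=sign * rng.uniform(0.04, 0.30), delta=rng.uniform(0.2, 0.8))
            )
        elif kind == "protein_to_bmi":
            specs.append(
                RegimeSpec(pid, kind, theta=sign * rng.uniform(0.2, 0.5), delta=rng.uniform(0.4, 0.8))
            )
        elif kind == "bidirectional":
            specs.append(
                RegimeSpec(
                    pid, kind,
                    alpha=sign * rng.uniform(0.04, 0.30),
                    theta=sign * rng.uniform(0.2, 0.5),
                    delta=rng.uniform(0.4, 0.8),
                )
            )
        else:
            specs.append(RegimeSpec(pid, "confounded_null", delta=rng.uniform(0.2, 0.8)))
    return specs


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    ``beta_gps`` (kg/m^2 per SD of the true score) may be left None, in which
    case it is resolved from ``gps_r2``, the fraction of baseline BMI
    variance the score should explain (default 0.14, matching the ~13.9%
    reported for genome-wide BMI scores in Europeans).
    """

    n_samples: int = 2000
    n_score_variants: int = 20
    n_cis_variants_per_protein: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_maf: float = 0.3
    beta_gps: float | None = None
    gps_r2: float = 0.14
    amplification_k: float = 1.0
    amplification_q: float = 0.9
    regimes: list[RegimeSpec] = field(default_factory=canonical_regime_panel)
    noise_sd: float = 3.2  # residual BMI SD, kg/m^2
    bmi_mean: float = 27.3
    beta_age: float = 0.05  # kg/m^2 per year, age centred at 61
    beta_sex: float = 0.4  # kg/m^2, male vs female
    confounder_bmi: float = 2.0  # kg/m^2 per SD of the latent confounder
    confounder_protein: float = 0.5
    protein_noise_sd: float = 1.0
    seed: int = 0
    #: seed of the *structural* randomness (variant panel mafs, true score
    #: weights); defaults to ``seed``. Replication cohorts re-draw samples
    #: while keeping the structure fixed.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be positive")
        if self.amplification_k < 1.0:
            raise ValidationError(f"amplification_k must be >= 1, got {self.amplification_k}")
        if not (0.0 < self.amplification_q < 1.0):
            raise ValidationError("amplification_q must be in (0, 1)")
        if self.noise_sd <= 0 or self.protein_noise_sd <= 0:
            raise ValidationError("noise SDs must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not self.regimes:
            raise ValidationError("at least one protein regime is required")

    def n_cis(self, spec: RegimeSpec) -> int:
        return spec.n_cis if spec.n_cis is not None else self.n_cis_variants_per_protein

    @property
    def effective_structure_seed(self) -> int:
        return self.seed if self.structure_seed is None else self.structure_seed


@dataclass
class Cohort:
    """Everything one simulated study produces, with ground truth attached."""

    geno: GenotypeMatrix
    phenotypes: pd.DataFrame
    proteins: pd.DataFrame  # samples x proteins, positive exp2 scale
    weights: pd.DataFrame  # true score weights (variant_id, effect_allele, weight)
    truth: pd.DataFrame  # one row per protein: regime, alpha, theta, delta, cis ids


def hinge_link(s: np.ndarray, k: float, q: float) -> np.ndarray:
    """Piecewise-linear link: identity inside the central q-mass of |s|,
    slope k beyond the hinge t = empirical q-quantile of |s|."""
    if k < 1.0:
        raise ValidationError("amplification factor k must be >= 1")
    s = np.asarray(s, dtype=float)
    t = float(np.quantile(np.abs(s), q))
    a = np.abs(s)
    return np.where(a <= t, s, np.sign(s) * (t + k * (a - t)))


def hinge_link_variance(k: float, q: float) -> float:
    """Var(L(S)) for standard-normal S under the hinge link (analytic)."""
    t = stats.norm.ppf(0.5 + q / 2.0)  # q-quantile of |S|
    Q = stats.norm.sf(t)
    phi = stats.norm.pdf(t)
    A = 2.0 * (t * phi + Q)  # E[s^2 1(|s|>t)]
    B = 2.0 * phi  # E[|s| 1(|s|>t)]
    return (1.0 - A) + k**2 * A - 2.0 * k * (k - 1.0) * t * B + (k - 1.0) ** 2 * t**2 * 2.0 * Q


def resolve_beta_gps(config: SimConfig) -> float:
    """Slope of BMI on the true score implied by the configured R^2.

    Solves beta^2 var(L) / (beta^2 var(L) + var_rest) = gps_r2 where
    var_rest collects the age, sex and residual-noise variance of the
    baseline BMI model (regime feedback and confounders are on top of this
    baseline and are not part of the target).
    """
    if config.beta_gps is not None:
        return float(config.beta_gps)
    var_age = (config.beta_age**2) * (_AGE_RANGE[1] - _AGE_RANGE[0]) ** 2 / 12.0
    var_sex = (config.beta_sex**2) * _MALE_FRACTION * (1.0 - _MALE_FRACTION)
    var_rest = var_age + var_sex + config.noise_sd**2
    var_l = hinge_link_variance(config.amplification_k, config.amplification_q)
    r2 = config.gps_r2
    if not (0.0 < r2 < 1.0):
        raise ValidationError("gps_r2 must be in (0, 1)")
    return float(np.sqrt(r2 / (1.0 - r2) * var_rest / var_l))


def score_variant_panel(config: SimConfig, rng: np.random.Generator) -> list[VariantMeta]:
    """Variant descriptors for the score block followed by per-protein cis blocks.

    Score variants are spread over chromosomes 1-22; each protein's cis
    variants sit together near its (synthetic) gene locus so that cis-window
    logic has something to act on. Allele pairs are non-palindromic.
    """
    lo, hi = config.maf_range
    variants: list[VariantMeta] = []
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
    for i in range(config.n_score_variants):
        ea, oa = pairs[i % len(pairs)]
        variants.append(
            VariantMeta(
                variant_id=f"rs{i + 1:05d}",
                chrom=str(i % 22 + 1),
                pos=1_000_000 + 50_000 * i,
                effect_allele=ea,
                other_allele=oa,
                maf=float(rng.uniform(lo, hi)),
            )
        )
    for j, spec in enumerate(config.regimes):
        for c in range(config.n_cis(spec)):
            ea, oa = pairs[(j + c) % len(pairs)]
            variants.append(
                VariantMeta(
                    variant_id=f"cis_{spec.protein_id}_{c + 1}",
                    chrom=str(j % 22 + 1),
                    pos=10_000_000 + 1_000_000 * j + 5_000 * c,
                    effect_allele=ea,
                    other_allele=oa,
                    maf=config.cis_maf,
                )
            )
    return variants


def simulate_genotypes(
    n_samples: int,
    variant_specs: list[VariantMeta],
    seed: int | np.random.SeedSequence,
    ld_pairs: list[tuple[str, str, float]] | None = None,
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages Binomial(2, maf), independent across variants.

    ``ld_pairs`` entries ``(leader_id, follower_id, r2)`` re-draw the
    follower by copying each of the leader's two alleles with probability
    sqrt(r2), which yields a dosage correlation of sqrt(r2) (hence squared
    correlation r2) when the two variants share a maf.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if not variant_specs:
        raise ValidationError("variant_specs must be non-empty")
    ids = [v.variant_id for v in variant_specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate variant_id in specs: {dupes}")
    rng = np.random.default_rng(seed)
    mafs = np.array([v.maf for v in variant_specs])
    # allele-level draws so LD pairs can share alleles
    alleles = (rng.random((n_samples, len(ids), 2)) < mafs[None, :, None]).astype(float)
    if ld_pairs:
        index = {vid: i for i, vid in enumerate(ids)}
        for leader, follower, r2 in ld_pairs:
            if leader not in index or follower not in index:
                raise ValidationError(f"LD pair references unknown variant: {leader}/{follower}")
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"LD r2 must be in [0, 1], got {r2}")
            li, fi = index[leader], index[follower]
            if variant_specs[li].maf != variant_specs[fi].maf:
                raise ValidationError(
                    f"LD pair {leader}/{follower} must share a maf for the copy construction"
                )
            copy = rng.random((n_samples, 2)) < np.sqrt(r2)
            fresh = (rng.random((n_samples, 2)) < mafs[fi]).astype(float)
            alleles[:, fi, :] = np.where(copy, alleles[:, li, :], fresh)
    dosages = alleles.sum(axis=2)
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=list(variant_specs), dosages=dosages)


def simulate_traits(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate phenotypes, proteins, the true weight table and the truth table.

    The first ``n_score_variants`` columns of ``geno`` form the polygenic
    score; subsequent columns are consumed, in order, as cis-pQTL blocks for
    each protein regime. See the module docstring for the generative model.
    """
    n = geno.n_samples
    n_score = config.n_score_variants
    needed = n_score + sum(config.n_cis(s) for s in config.regimes)
    if geno.n_variants < needed:
        raise ValidationError(
            f"genotype matrix has {geno.n_variants} variants but the config needs {needed}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    structure_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.effective_structure_seed, spawn_key=(3,))
    )

    # --- polygenic score and baseline BMI ----------------------------------
    w = structure_rng.normal(0.0, 1.0, n_score)
    s_raw = geno.dosages[:, :n_score] @ w
    sd = s_raw.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate score: zero variance (increase n_samples/mafs)")
    s = (s_raw - s_raw.mean()) / sd
    link = hinge_link(s, config.amplification_k, config.amplification_q)
    beta_gps = resolve_beta_gps(config)

    age = rng.uniform(*_AGE_RANGE, n)
    sex = rng.binomial(1, _MALE_FRACTION, n).astype(float)
    bmi = (
        config.bmi_mean
        + beta_gps * link
        + config.beta_age * (age - 61.0)
        + config.beta_sex * sex
        + rng.normal(0.0, config.noise_sd, n)
    )

    # --- first pass: regimes that feed BMI ---------------------------------
    cursor = n_score
    cis_scores: dict[str, np.ndarray] = {}
    cis_ids: dict[str, list[str]] = {}
    p0: dict[str, np.ndarray] = {}
    latent_u: dict[str, np.ndarray] = {}
    for spec in config.regimes:
        m = config.n_cis(spec)
        block = geno.dosages[:, cursor : cursor + m]
        mafs = np.array([v.maf for v in geno.variants[cursor : cursor + m]])
        cis_ids[spec.protein_id] = [v.variant_id for v in geno.variants[cursor : cursor + m]]
        cursor += m
        cis_scores[spec.protein_id] = spec.delta * (block - 2.0 * mafs).sum(axis=1)
        if spec.regime in ("protein_to_bmi", "bidirectional"):
            base = cis_scores[spec.protein_id] + rng.normal(0.0, config.protein_noise_sd, n)
            p0[spec.protein_id] = base
            bmi = bmi + spec.theta * base
        elif spec.regime == "confounded_null":
            u = rng.normal(0.0, 1.0, n)
            latent_u[spec.protein_id] = u
            bmi = bmi + config.confounder_bmi * u

    # --- second pass: protein readouts against the final BMI ----------------
    z_bmi = (bmi - bmi.mean()) / bmi.std(ddof=1)
    proteins: dict[str, np.ndarray] = {}
    for spec in config.regimes:
        if spec.regime == "bmi_to_protein":
            proteins[spec.protein_id] = (
                spec.alpha * z_bmi
                + cis_scores[spec.protein_id]
                + rng.normal(0.0, config.protein_noise_sd, n)
            )
        elif spec.regime == "protein_to_bmi":
            proteins[spec.protein_id] = p0[spec.protein_id]
        elif spec.regime == "bidirectional":
            proteins[spec.protein_id] = p0[spec.protein_id] + spec.alpha * z_bmi
        else:  # confounded_null
            proteins[spec.protein_id] = (
                cis_scores[spec.protein_id]
                + config.confounder_protein * latent_u[spec.protein_id]
                + rng.normal(0.0, config.protein_noise_sd, n)
            )

    smoking = rng.binomial(1, 0.22, n)
    alcohol = rng.choice([0, 1, 2], size=n, p=[0.3, 0.5, 0.2])
    activity = rng.binomial(1, 0.55, n)
    diabetes = rng.binomial(1, np.clip(0.02 + 0.012 * (bmi - 22.0), 0.01, 0.7))

    pheno = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "bmi": bmi,
            "age": age,
            "sex": sex.astype(int),
            "smoking": smoking,
            "alcohol": alcohol,
            "physical_activity": activity,
            "diabetes": diabetes,
        }
    )
    protein_df = pd.DataFrame(
        {pid: np.exp2(v + _PROTEIN_LOG2_OFFSET) for pid, v in proteins.items()},
        index=geno.sample_ids,
    )
    weight_df = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in geno.variants[:n_score]],
            "effect_allele": [v.effect_allele for v in geno.variants[:n_score]],
            "weight": w,
        }
    )
    truth = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in config.regimes],
            "regime": [s.regime for s in config.regimes],
            "alpha": [s.alpha for s in config.regimes],
            "theta": [s.theta for s in config.regimes],
            "delta": [s.delta for s in config.regimes],
            "cis_variants": [";".join(cis_ids[s.protein_id]) for s in config.regimes],
        }
    )
    return pheno, protein_df, weight_df, truth


def simulate_cohort(config: SimConfig) -> Cohort:
    """Variant panel + genotypes + traits in one deterministic call."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
    panel_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.effective_structure_seed, spawn_key=(2,))
    )
    variants = score_variant_panel(config, panel_rng)
    geno = simulate_genotypes(config.n_samples, variants, ss)
    pheno, proteins, weights, truth = simulate_traits(geno, config)
    return Cohort(geno=geno, phenotypes=pheno, proteins=proteins, weights=weights, truth=truth)


def replication_cohort(config: SimConfig, n_samples: int, seed_offset: int = 1) -> Cohort:
    """An independent cohort drawn under the same truth-generating config.

    Only the sample-level randomness changes (new seed); regimes, effect
    sizes, the variant panel and the true score weights are shared, so the
    second study measures the same genetic architecture in new samples (as
    a replication cohort or the second sample of a two-sample MR must).
    """
    cfg = replace(
        config,
        n_samples=n_samples,
        seed=config.seed + 100_003 * seed_offset,
        structure_seed=config.effective_structure_seed,
    )
    return simulate_cohort(cfg)


def make_confounder_catalog(
    geno: GenotypeMatrix,
    confounder_traits: list[str],
    seed: int,
    planted: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Variant x trait association table with optional planted confounders.

    Planted (variant, trait) pairs get p < 1e-8; everything else is drawn
    from U(0.001, 1), safely above any genome-wide threshold.
    """
    if not confounder_traits:
        raise ValidationError("confounder_traits must be non-empty")
    planted = planted or {}
    known = set(geno.variant_ids)
    for trait, vids in planted.items():
        unknown = set(vids) - known
        if unknown:
            raise ValidationError(f"planted confounders not in genotype matrix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for trait in confounder_traits:
        hits = set(planted.get(trait, []))
        for vid in geno.variant_ids:
            if vid in hits:
                p = 10.0 ** rng.uniform(-30.0, -8.1)
            else:
                p = rng.uniform(1e-3, 1.0)
            rows.append((vid, trait, p))
    return pd.DataFrame(rows, columns=["variant_id", "trait", "p"])


def simulate_mr_summary_stats(
    n_snps: int,
    beta: float,
    seed: int,
    bx_mean: float = 0.1,
    bx_sd: float = 0.03,
    se_exposure: float = 0.01,
    se_outcome: float = 0.05,
    pleiotropy_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired exposure/outcome summary statistics for estimator calibration.

    Outcome effects are ``beta * bx + N(0, se_outcome^2)`` (plus an optional
    balanced-pleiotropy term), with the reported exposure betas treated as
    exact, so inverse-variance-weighted confidence intervals have nominal
    coverage by construction.
    """
    rng = np.random.default_rng(seed)
    bx = rng.normal(bx_mean, bx_sd, n_snps)
    pleio = rng.normal(0.0, pleiotropy_sd, n_snps) if pleiotropy_sd > 0 else 0.0
    by = beta * bx + pleio + rng.normal(0.0, se_outcome, n_snps)
    ids = [f"rs{i + 1:05d}" for i in range(n_snps)]
    base = {
        "variant_id": ids,
        "chrom": [str(i % 22 + 1) for i in range(n_snps)],
        "pos": [1_000_000 + 10_000_000 * i for i in range(n_snps)],
        "effect_allele": ["A"] * n_snps,
        "other_allele": ["G"] * n_snps,
    }
    exp_df = pd.DataFrame(
        base
        | {
            "beta": bx,
            "se": se_exposure,
            "p": 2.0 * stats.norm.sf(np.abs(bx) / se_exposure),
            "n": 300_000,
        }
    )
    out_df = pd.DataFrame(
        base
        | {
            "beta": by,
            "se": se_outcome,
            "p": 2.0 * stats.norm.sf(np.abs(by) / se_outcome),
            "n": 3_000,
        }
    )
    return exp_df, out_df
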