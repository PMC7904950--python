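# Methods

## The analysis chain

The package implements the statistical machinery used to relate blood
plasma protein levels to body mass index (BMI) through genetic
predisposition. Three layers interact:

* an **observational layer**: per-protein ordinary least squares of
  log2-transformed, z-scored abundances on BMI (or on a polygenic score)
  with covariate adjustment, Bonferroni family-wise control, replication in
  a second study, and subsampling power;
* a **stratification layer**: percentile strata of the score, tail-restricted
  regressions and decile profiles, quantifying whether the genetic signal is
  amplified in the extremes of the score distribution;
* a **causal layer**: bidirectional Mendelian randomization treating the
  polygenic score (forward) or cis-pQTLs (reverse) as instruments.

All regression inference is classical: homoskedastic errors, two-sided
p-values from the t distribution with n − p degrees of freedom. Z-scoring
always uses the sample SD (n − 1), which makes the (1,2,3) → (−1,0,1)
contract exact.

## The synthetic-cohort generator

Real cohorts of this design are access-restricted, so the generator is a
first-class module rather than a test fixture. It emulates:

* **Genotypes.** Dosages are Binomial(2, maf) under Hardy–Weinberg,
  independent across variants. Linkage disequilibrium is induced only in
  explicitly declared pairs (a follower copies each of the leader's alleles
  with probability √r², giving dosage-squared-correlation r²); the analysis
  itself never models genome-wide LD, only pairwise r² at clumping time.
* **The score and BMI.** A true weight vector over `n_score_variants = 20`
  variants defines the raw score; the standardized score S enters BMI
  through a piecewise-linear hinge link L(S): identity inside the central
  `amplification_q = 0.9` mass of |S|, slope `amplification_k` beyond the
  hinge. k = 1 is a strictly linear link; k > 1 switches on a tail effect.
  The slope of BMI on L(S) is resolved so the score explains `gps_r2 = 0.14`
  of baseline BMI variance (the share genome-wide BMI scores reach in
  European-ancestry cohorts). Age (uniform 43–79 years, 0.05 kg/m² per
  year), sex (48% male, 0.4 kg/m²) and Gaussian noise (SD 3.2 kg/m²) bring
  the BMI distribution to a realistic mean ≈ 27.5, SD ≈ 4 kg/m².
* **Proteins under four causal regimes.** Each protein carries a cis-pQTL
  block (default 3 variants at maf 0.3, effect δ per allele) and one of:
  BMI→protein (`P = α·z(BMI) + δ·G_cis + e`), protein→BMI
  (`P = δ·G_cis + e`, then `BMI += θ·P`), bidirectional (both, generated
  sequentially so the model stays acyclic and the truth well-defined), or
  confounded-null (a latent U moves BMI by 2.0 kg/m²/SD and the protein by
  0.5 units/SD with no causal edge). Proteins are emitted on a positive
  exp2 scale so the log2 + z preprocessing path is genuinely exercised.
* **Two-cohort designs.** `replication_cohort` redraws samples while
  keeping the *structural* randomness (variant panel, true weights, effect
  sizes) fixed, which is what a replication study or the second sample of a
  two-sample MR requires.

**Reference effect sizes.** The canonical four-regime panel uses α = 0.35,
θ = 0.45, δ = 0.8. These were fixed by analytic power calculation for the
package's reference direction-recovery experiment (n = 5000, per-test
α = 0.05/152): the one-sample 2SLS z-statistic is approximately
`(α/sd(P)) · √(n·R²_fs)` with first-stage R² ≈ 0.10 and sd(P) ≈ 1.37, and
the reverse IVW z is `√k · θδ · √(n·var(G))/sd(BMI)`; the chosen values put
both above 5, i.e. >95% power at the 3.6-SD significance threshold, while
the confounded-null regime stays null by construction. The mixed panel used
for pipeline demonstrations draws forward effects in a weaker, realistic
scan range (|α| 0.04–0.30 with both signs, 20% pure nulls) so scans produce
a plausible mixture of hits, near-misses and replication failures.

What the generator does **not** emulate: population structure and
admixture, genome-wide LD, imputation uncertainty, assay batch effects and
aptamer cross-reactivity, non-Gaussian protein error distributions.
Passing tests therefore demonstrate the correctness and calibration of the
*estimators* under the stated generative assumptions, not robustness to
those real-data complications.

## Numerical and design choices

* **Vectorised OLS.** Protein-wide scans share one QR factorisation of the
  design across hundreds of response columns; per-SNP summary statistics
  use the Frisch–Waugh–Lovell projection. Rank-deficient designs raise an
  error naming the collinear columns.
* **Exposure scale.** Scans z-score the exposure by default so betas are
  SD-per-SD; a flag keeps BMI in kg/m². The choice is recorded in the
  output's model metadata.
* **p95.** The k-th order statistic with k = ⌈0.05·reps⌉ (the 50th smallest
  of 1000), on the sorted multiset of p-values with ties kept as-is.
* **Strata and deciles.** Ranks use a stable sort (ties broken by sample
  order); strata have ⌈n·p/100⌉ members and partition the sample exactly at
  p = 50; decile of 0-based rank r is ⌊10r/n⌋ + 1. Decile CIs are normal
  (±1.96·SE).
* **Tail regression** pools both tails into a single fit with one slope and
  the same covariates as the full model — the only reading under which a
  per-score-unit β and its ratio to the full-sample β are both defined, and
  which guarantees ratio(p = 50) = 1 identically.
* **MR estimators.** IVW is fixed-effect (SE = 1/√Σ(b_x²/s_y²)); a
  multiplicative random-effects variant (SE inflated by √(Q/(k−1)) when
  above 1) sits behind a flag. The Wald-ratio SE is first-order delta
  method s_y/|b_x| with the second-order term behind a flag. MR-Egger
  re-orients SNPs so b_x ≥ 0 and fits weighted least squares with a free
  intercept, weights 1/s_y², with the *estimated* residual scale and a
  t(k−2) reference — no variance floor — so the intercept test is exactly
  calibrated under the no-pleiotropy null. 2SLS uses classical SEs with
  residuals computed against the actual exposure and a t reference
  (homoskedastic; robust SEs are out of scope). Clumping uses a 10 Mb
  window around the headline r² ≤ 0.001 rule; dosage correlations come from
  the supplied reference matrix. Reverse one-sample MR uses an allelic
  score of at most the two strongest selected cis instruments. Confounder
  exclusion applies to both directions.
* **Cis windows** are anchored on gene boundaries (start − w, end + w),
  same chromosome only, w = 100 Mb by default and configurable.
* **bicor** uses the unscaled MAD with the canonical 9·mad denominator and
  falls back to Pearson (with a warning) when a MAD is zero; screen
  p-values use the t approximation with n − 2 df, two-sided.
* **Missing dosages** are disallowed in the synthetic path; file readers
  apply per-variant mean imputation (PLINK-like) and count it in the drop
  report.

## The tail-effect ratio: an estimator bound

For any outcome whose conditional mean is a *monotone* function of a
normally distributed score, the pooled 5%-tail restricted-OLS slope ratio
is bounded:

  ratio = E[L(s)·s·1_T] / (E[s²·1_T] · E[L(s)·s]) ≤ 1/E[s²·1_T] ≈ 2.28,

because the extreme 5% tails of a standard normal carry ≈ 44% of its
variance — amplifying the tails inflates the full-sample slope too. The
hinge link with k = 4, q = 0.9 sits at ratio ≈ 1.30 (analytic and
simulated). Empirical tail-to-full ratios of 3–7 reported for percentile
analyses of polygenic scores therefore cannot be same-scale restricted-OLS
ratios; they are consistent with a score re-standardised within the tail
subsample (which multiplies the tail slope by sd(s | tails) ≈ 2.1 and
lifts the bound to ≈ 4.8). This package keeps the same-scale definition
because it is the one under which the linear link gives ratio = 1 and
ratio(p = 50) = 1 exactly; the amplified link is validated against its
analytic value (≈ 1.30) rather than against the larger re-scaled figures.

## Known limitations

* One-sample 2SLS p-values assume homoskedastic errors; weak-instrument
  inference beyond the first-stage F diagnostic is not implemented.
* The two-sample MR path assumes both cohorts share the variant panel and
  underlying per-SNP effects; cross-ancestry effect heterogeneity is not
  modelled.
* No MR-PRESSO, weighted-median, mode-based or Steiger filtering; no
  colocalization.
* The expression screen has no permutation p-values and no module
  (network) detection.
* Problem sizes in the test suite and acceptance script (150–200 replicate
  cohorts of n = 5000–10,000; 500 calibration simulations) were chosen as
  the smallest designs at which the Monte-Carlo error of each reported rate
  is comfortably below the width of its target band.
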