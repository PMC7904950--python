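"""End-to-end orchestration: simulate/load -> score -> scan -> tails -> MR -> screen.

Every stage writes its output as TSV into the run directory together with a
machine-readable ``manifest.json`` (package and library versions, seed,
thresholds, input checksums) sufficient to re-run any stage in isolation.
Runs are deterministic for a fixed configuration and seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, mr, pwas, tails, xscreen
from .datatypes import ValidationError
from .pwas import BASIC_COVARIATES, FULL_COVARIATES
from .scorer import compute_gps
from .synthcohort import (
    Cohort,
    SimConfig,
    default_regime_panel,
    replication_cohort,
    simulate_cohort,
)

log = logging.getLogger("bmiproteome")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run_output"
    seed: int = 0
    # synthetic-cohort stage (ignored when explicit input paths are given)
    n_samples: int = 2000
    n_proteins: int = 60
    replication_n: int = 356
    # optional pre-existing inputs
    dosages: str | None = None
    variants: str | None = None
    phenotypes: str | None = None
    proteins: str | None = None
    weights: str | None = None
    # models and thresholds
    model: str = "basic"
    alpha: float = 0.05
    percentiles: tuple[float, ...] = (25, 20, 15, 10, 5)
    p_max: float = 1e-8
    f_min: float = 10.0
    clump_r2: float = 0.001
    window_bp: int = 100_000_000
    r_min: float = 0.1
    power_n_sub: int = 356
    power_reps: int = 1000
    power_max_proteins: int = 5
    mr_max_proteins: int | None = None
    stages: tuple[str, ...] = ("simulate", "gps", "pwas", "replication", "tails", "mr", "xscreen")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("percentiles", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.model not in ("basic", "full"):
            raise ValidationError(f"model must be 'basic' or 'full', got {self.model!r}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        explicit = [self.dosages, self.variants, self.phenotypes, self.proteins, self.weights]
        if any(explicit) and not all(explicit):
            raise ValidationError(
                "either provide all of dosages/variants/phenotypes/proteins/weights or none"
            )
        for p in explicit:
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _covariates(pheno: pd.DataFrame, model: str) -> pd.DataFrame:
    cols = BASIC_COVARIATES if model == "basic" else FULL_COVARIATES
    missing = [c for c in cols if c not in pheno.columns]
    if missing:
        raise ValidationError(f"phenotype table missing covariates for model {model!r}: {missing}")
    if pheno[cols].isna().any().any():
        raise ValidationError(f"missing values in covariates {cols}")
    return pheno[cols]


def _load_or_simulate(config: RunConfig) -> tuple[Cohort, Cohort | None]:
    if config.dosages is not None:
        geno = io.read_dosage_bundle(config.dosages, config.variants)
        cohort = Cohort(
            geno=geno,
            phenotypes=io.read_phenotypes(config.phenotypes),
            proteins=io.read_protein_matrix(config.proteins),
            weights=io.read_weight_table(config.weights),
            truth=pd.DataFrame(),
        )
        return cohort, None
    sim = SimConfig(
        n_samples=config.n_samples,
        regimes=default_regime_panel(config.n_proteins, seed=config.seed),
        seed=config.seed,
    )
    cohort = simulate_cohort(sim)
    second = replication_cohort(sim, n_samples=config.replication_n)
    return cohort, second


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the map of written outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log.info("pipeline start (seed=%d, out=%s)", config.seed, out)

    cohort, second = _load_or_simulate(config)
    if "simulate" in config.stages and not cohort.truth.empty:
        paths = io.write_cohort(cohort, out / "cohort")
        outputs.update({f"cohort_{k}": v for k, v in paths.items()})
        if second is not None:
            paths2 = io.write_cohort(second, out / "replication_cohort")
            outputs.update({f"replication_{k}": v for k, v in paths2.items()})

    pheno = cohort.phenotypes
    covs = _covariates(pheno, config.model)
    prot_std = pwas.preprocess_proteins(cohort.proteins)
    m_proteins = prot_std.shape[1]
    threshold = pwas.bonferroni_threshold(config.alpha, m_proteins)

    gps_vec = compute_gps(cohort.geno, cohort.weights)
    if "gps" in config.stages:
        outputs["gps"] = out / "gps.tsv"
        io.write_tsv(gps_vec.to_frame(), outputs["gps"])
        log.info(
            "gps: %d variants used, %d ambiguous, %d unmatched dropped",
            gps_vec.n_variants_used, gps_vec.n_dropped_ambiguous, gps_vec.n_dropped_unmatched,
        )

    bmi_scan = pwas.association_scan(
        prot_std, pheno["bmi"], covs, exposure_name="bmi", model=config.model
    )
    gps_scan = pwas.association_scan(
        prot_std, gps_vec.standardized_score, covs, exposure_name="gps",
        model=config.model, standardize_exposure=False,
    )
    if "pwas" in config.stages:
        outputs["pwas_bmi"] = out / "pwas_bmi.tsv"
        io.write_tsv(bmi_scan.assign(bonferroni=threshold, significant=bmi_scan["p"] < threshold),
                     outputs["pwas_bmi"])
        outputs["pwas_gps"] = out / "pwas_gps.tsv"
        io.write_tsv(gps_scan.assign(bonferroni=threshold, significant=gps_scan["p"] < threshold),
                     outputs["pwas_gps"])
        log.info("pwas: %d/%d proteins pass p < %.3g", int((bmi_scan["p"] < threshold).sum()),
                 m_proteins, threshold)

    if "replication" in config.stages and second is not None:
        rep_std = pwas.preprocess_proteins(second.proteins)
        rep_covs = _covariates(second.phenotypes, config.model)
        discovered = bmi_scan.loc[bmi_scan["p"] < threshold]
        rep_scan = pwas.association_scan(
            rep_std, second.phenotypes["bmi"], rep_covs, exposure_name="bmi", model=config.model
        )
        if len(discovered):
            rep_table, corr = pwas.assess_replication(discovered, rep_scan, alpha=config.alpha)
            outputs["replication"] = out / "replication.tsv"
            io.write_tsv(rep_table.assign(effect_correlation=corr), outputs["replication"])
            rep_threshold = pwas.bonferroni_threshold(config.alpha, len(discovered))
            power_rows = []
            for pid in discovered["protein_id"].head(config.power_max_proteins):
                res = pwas.subsample_power(
                    prot_std[pid].to_numpy(), pheno["bmi"].to_numpy(), covs,
                    n_sub=min(config.power_n_sub, cohort.geno.n_samples),
                    reps=config.power_reps, seed=config.seed, alpha=rep_threshold,
                    protein_id=pid,
                )
                power_rows.append(res.__dict__)
            outputs["power"] = out / "power.tsv"
            io.write_tsv(pd.DataFrame(power_rows), outputs["power"])

    if "tails" in config.stages:
        score = gps_vec.standardized_score
        bmi_tail = tails.tail_regression(
            pheno["bmi"].to_numpy(), score, covs, 5, outcome="BMI", standardize_exposure=False
        )
        hit_ids = bmi_scan.loc[bmi_scan["p"] < threshold, "protein_id"].tolist()
        tail_table = tails.tail_scan(
            prot_std[hit_ids] if hit_ids else prot_std.iloc[:, :0],
            score, covs, percentiles=config.percentiles,
        )
        outputs["tails"] = out / "tails.tsv"
        io.write_tsv(
            pd.concat([pd.DataFrame([{**bmi_tail.__dict__, "protein_id": "BMI"}]), tail_table],
                      ignore_index=True),
            outputs["tails"],
        )
        outputs["deciles"] = out / "deciles_bmi.tsv"
        io.write_tsv(tails.decile_summary(pheno["bmi"].to_numpy(), score), outputs["deciles"])
        if hit_ids:
            t5 = tail_table.loc[tail_table["percentile"] == 5].copy()
            classes = tails.classify_proteins(
                bmi_scan.loc[bmi_scan["protein_id"].isin(hit_ids)],
                gps_scan, t5, alpha_strict=threshold,
            )
            outputs["protein_classes"] = out / "protein_classes.tsv"
            io.write_tsv(classes, outputs["protein_classes"])

    if "mr" in config.stages:
        ids = bmi_scan.loc[bmi_scan["p"] < threshold, "protein_id"].tolist() or list(prot_std.columns)
        if config.mr_max_proteins:
            ids = ids[: config.mr_max_proteins]
        report = mr.run_bidirectional(
            cohort, second=second, protein_ids=ids,
            p_max=config.p_max, f_min=config.f_min, clump_r2=config.clump_r2,
            alpha=pwas.bonferroni_threshold(config.alpha, max(len(ids), 1)),
        )
        outputs["mr"] = out / "mr_bidirectional.tsv"
        io.write_tsv(report, outputs["mr"])

    if "xscreen" in config.stages:
        expr = prot_std.T  # proteins x samples
        traits = pheno.set_index("sample_id")[["bmi", "age"]].T
        traits.columns = expr.columns
        screen_table = xscreen.screen(expr, traits, r_min=config.r_min, alpha=config.alpha)
        outputs["xscreen"] = out / "xscreen.tsv"
        io.write_tsv(screen_table, outputs["xscreen"])

    manifest = {
        "package": "bmiproteome",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "bonferroni_threshold": threshold,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = out / "manifest.json"
    log.info("pipeline done: %d outputs", len(outputs))
    return outputs
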