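"""Synthetic individual-level cohorts with the structure the analysis assumes.

The generator emulates two cohorts: a large exposure cohort (genotypes,
covariates, log2-CRP) for the exposure GWAS, and a cancer-patient outcome
cohort followed for survival.  Its defaults are the study conditions of the
analysis this package reproduces: seven independent biallelic instruments at
the fixture effect-allele frequencies, instruments explaining 4.0% of
log2-CRP variance, an outcome cohort of 6,460 patients followed 8 years with
a ~41.4% all-cause death fraction of which ~60.6% are cause-of-interest
deaths, and survival generated under an additive-hazards model with
administrative censoring.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning; stage substreams are drawn in a fixed order (genotypes,
covariates, exposure, survival), so the same config and seed reproduce a
cohort bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .datamodel import ConfigurationError, ValidationError, load_table1_fixture
from .hazards import CAUSE_OF_INTEREST

__all__ = ["CovariateSpec", "SimConfig", "CohortData", "simulate_genotypes",
           "simulate_exposure", "simulate_survival", "simulate_cohort",
           "write_cohort", "read_cohort", "concat_cohorts"]

# Study-condition defaults: the death fraction and follow-up of the emulated
# patient cohort, and the fixture instruments' frequencies and effects.
_FOLLOWUP_YEARS = 8.0
_DEATH_FRACTION = 0.414
_CAUSE_SPLIT = 1622.0 / 2676.0          # CRC share of all deaths
_BASELINE_HAZARD = -np.log(1.0 - _DEATH_FRACTION) / _FOLLOWUP_YEARS  # ~0.0668/PY


def _fixture_defaults():
    table = load_table1_fixture()
    return (
        [r.variant.id for r in table],
        [r.variant.eaf for r in table],
        [r.exposure.beta for r in table],
        [r.variant.chrom for r in table],
        [r.variant.pos for r in table],
    )


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate distributions and their effects on exposure and hazard.

    Defaults: age ~ Normal(57, 8) years, sex ~ Bernoulli(0.5), 10
    standard-normal principal-component columns; all effects zero unless
    configured.  Effects are per covariate unit: on the log2-exposure scale
    for ``exposure_effects`` and per person-year for ``hazard_effects``.
    """

    age_mean: float = 57.0
    age_sd: float = 8.0
    sex_p: float = 0.5
    n_pcs: int = 10
    exposure_effects: dict = field(default_factory=dict)
    hazard_effects: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return ["age", "sex"] + [f"pc{i + 1}" for i in range(self.n_pcs)]


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_subjects: int = 6460
    eafs: list[float] | None = None          # default: fixture EAFs
    snp_effects: list[float] | None = None   # default: fixture betas
    variant_ids: list[str] | None = None
    chroms: list[str] | None = None
    positions: list[int] | None = None
    target_r2: float = 0.04
    causal_hd: float = 0.0                   # per PY per unit log2-exposure
    baseline_hazard: float = _BASELINE_HAZARD
    cause_split: float = _CAUSE_SPLIT
    followup_years: float = _FOLLOWUP_YEARS
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    ld_rho: float = 0.0
    ld_blocks: list[int] | None = None       # block sizes; None = one block
    hazard_floor: float = 1e-6
    dosage_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eafs is None:
            ids, eafs, betas, chroms, poss = _fixture_defaults()
            self.eafs = eafs
            if self.snp_effects is None:
                self.snp_effects = betas
            if self.variant_ids is None:
                self.variant_ids = ids
                self.chroms = chroms
                self.positions = poss
        k = len(self.eafs)
        if self.snp_effects is None:
            self.snp_effects = [0.0] * k
        if self.variant_ids is None:
            self.variant_ids = [f"snp{j + 1}" for j in range(k)]
        if self.chroms is None:
            self.chroms = ["1"] * k
        if self.positions is None:
            self.positions = [1_000_000 + 2_000_000 * j for j in range(k)]
        if not (0.0 <= self.target_r2 < 1.0):
            raise ConfigurationError(f"target_r2 must be in [0,1), got {self.target_r2}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not (0.0 <= self.cause_split <= 1.0):
            raise ConfigurationError("cause_split must be in [0,1]")
        if len(self.snp_effects) != k:
            raise ConfigurationError("snp_effects and eafs lengths differ")


@dataclass
class CohortData:
    """Individual-level cohort: dosages, covariates, exposure, survival."""

    dosages: pd.DataFrame            # subjects x variants, values in [0,2] or NaN
    covariates: pd.DataFrame
    exposure: pd.Series              # log2 scale
    survival: pd.DataFrame           # time, event, cause
    variants: pd.DataFrame           # id, chrom, pos, ea, ra, eaf
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.dosages)
        for part, name in ((self.covariates, "covariates"),
                           (self.exposure, "exposure"),
                           (self.survival, "survival")):
            if len(part) != n:
                raise ValidationError(f"{name} row count {len(part)} != dosages {n}")
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size:
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
                    raise ValidationError("dosages must lie in [0, 2] (or NaN)")

    @property
    def n_subjects(self) -> int:
        return len(self.dosages)


def simulate_genotypes(n: int, eafs, ld_rho: float = 0.0,
                       ld_blocks=None, seed=0) -> np.ndarray:
    """Hardy-Weinberg dosages, optionally correlated via a Gaussian copula.

    With ``ld_rho`` nonzero, latent Gaussians follow an AR(1) correlation
    within each block (``ld_blocks`` gives block sizes; by default all
    variants form one block) and dosages are the Binomial(2, eaf) quantiles
    of their probit scores.  The realized dosage correlation is slightly
    below the latent ``ld_rho`` (discretization), which is why calibration
    tests bound rather than pin it.
    """
    eafs = np.asarray(eafs, dtype=float)
    if np.any((eafs <= 0) | (eafs >= 1)):
        raise ConfigurationError("each EAF must be in (0, 1)")
    if not abs(ld_rho) < 1:
        raise ConfigurationError("|ld_rho| must be < 1")
    rng = np.random.default_rng(seed)
    k = eafs.size
    if ld_rho == 0.0:
        return rng.binomial(2, eafs, size=(n, k)).astype(float)
    blocks = list(ld_blocks) if ld_blocks is not None else [k]
    if sum(blocks) != k:
        raise ConfigurationError("ld_blocks must sum to the number of variants")
    cols, start = [], 0
    for size in blocks:
        z = rng.standard_normal((n, size))
        for j in range(1, size):   # AR(1) within block
            z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1 - ld_rho**2) * z[:, j]
        u = norm.cdf(z)
        for j in range(size):
            cols.append(binom.ppf(u[:, j], 2, eafs[start + j]))
        start += size
    return np.column_stack(cols).astype(float)


def simulate_exposure(genotypes, snp_effects, target_r2: float,
                      covariates=None, covariate_effects=None, seed=0) -> np.ndarray:
    """Exposure = genetic score + covariate effects + Gaussian noise.

    The noise variance is calibrated so the genetic component explains
    ``target_r2`` of the total exposure variance; the genetic-score variance
    is taken from the realized sample (consistent under LD, where the
    independent-SNP closed form does not apply).  Scaling all SNP effects by
    a common factor rescales the noise and leaves the realized R² unchanged.
    """
    g = np.asarray(genotypes, dtype=float)
    beta = np.asarray(snp_effects, dtype=float)
    rng = np.random.default_rng(seed)
    n = g.shape[0]
    gscore = np.where(np.isnan(g), np.nanmean(g, axis=0), g) @ beta
    var_g = float(np.var(gscore))

    cov_part = np.zeros(n)
    if covariates is not None and covariate_effects:
        for name, eff in covariate_effects.items():
            cov_part += eff * np.asarray(covariates[name], dtype=float)

    eps = rng.standard_normal(n)
    if target_r2 == 0.0:
        if np.any(beta != 0.0):
            raise ConfigurationError(
                "target_r2 = 0 requires all snp_effects to be zero")
        return cov_part + eps
    if var_g == 0.0:
        raise ConfigurationError("all snp_effects are zero but target_r2 > 0")
    var_other = var_g * (1.0 - target_r2) / target_r2
    var_eps = var_other - float(np.var(cov_part))
    if var_eps <= 0:
        raise ConfigurationError(
            "covariate effects alone exceed the non-genetic variance implied "
            f"by target_r2={target_r2}; reduce covariate effects")
    return gscore + cov_part + np.sqrt(var_eps) * eps


def simulate_survival(predictor, baseline_hazard: float, cause_split: float,
                      followup_years: float, seed=0, hazard_floor: float = 1e-6
                      ) -> pd.DataFrame:
    """Constant-hazard event times with administrative censoring.

    Per-subject hazard is max(baseline + predictor, floor); the additive
    model can drive individual hazards negative, so they are clamped and
    the clamped fraction is recorded in ``DataFrame.attrs['clamped_fraction']``
    (warned about above 1%).  Events are cause-of-interest with probability
    ``cause_split``, independently.
    """
    if baseline_hazard <= 0:
        raise ValidationError("baseline_hazard must be > 0")
    if followup_years <= 0:
        raise ValidationError("followup_years must be > 0 (degenerate follow-up)")
    pred = np.asarray(predictor, dtype=float)
    rng = np.random.default_rng(seed)
    lam_raw = baseline_hazard + pred
    lam = np.maximum(lam_raw, hazard_floor)
    clamped = float(np.mean(lam_raw < hazard_floor))
    if clamped > 0.01:
        warnings.warn(f"{clamped:.1%} of subject hazards clamped at the floor")
    t_event = rng.exponential(1.0 / lam)
    event = t_event <= followup_years
    time = np.minimum(t_event, followup_years)
    is_cause = rng.random(pred.size) < cause_split
    cause = np.where(event & is_cause, CAUSE_OF_INTEREST,
                     np.where(event, "other", None))
    df = pd.DataFrame({"time": time, "event": event.astype(int), "cause": cause})
    df.attrs["clamped_fraction"] = clamped
    return df


def simulate_cohort(config: SimConfig) -> CohortData:
    """Compose genotypes, covariates, exposure and survival into one cohort."""
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_cov, s_expo, s_surv, s_miss = ss.spawn(5)
    n, spec = config.n_subjects, config.covariate_spec

    geno = simulate_genotypes(n, config.eafs, ld_rho=config.ld_rho,
                              ld_blocks=config.ld_blocks, seed=s_geno)

    rng_c = np.random.default_rng(s_cov)
    cov = pd.DataFrame({
        "age": rng_c.normal(spec.age_mean, spec.age_sd, n),
        "sex": rng_c.binomial(1, spec.sex_p, n).astype(float),
    })
    for i in range(spec.n_pcs):
        cov[f"pc{i + 1}"] = rng_c.standard_normal(n)

    exposure = simulate_exposure(geno, config.snp_effects, config.target_r2,
                                 covariates=cov,
                                 covariate_effects=spec.exposure_effects,
                                 seed=s_expo)

    # Hazard predictor centered so baseline_hazard stays the population-
    # averaged rate regardless of effect sizes.
    pred = config.causal_hd * exposure
    for name, eff in spec.hazard_effects.items():
        pred = pred + eff * cov[name].to_numpy()
    pred = pred - pred.mean()
    survival = simulate_survival(pred, config.baseline_hazard, config.cause_split,
                                 config.followup_years, seed=s_surv,
                                 hazard_floor=config.hazard_floor)

    if config.dosage_missing_rate > 0:
        rng_m = np.random.default_rng(s_miss)
        mask = rng_m.random(geno.shape) < config.dosage_missing_rate
        geno = np.where(mask, np.nan, geno)

    variants = pd.DataFrame({
        "id": config.variant_ids, "chrom": config.chroms, "pos": config.positions,
        "ea": "A", "ra": "G", "eaf": config.eafs,
    })
    return CohortData(
        dosages=pd.DataFrame(geno, columns=config.variant_ids),
        covariates=cov,
        exposure=pd.Series(exposure, name="log2_exposure"),
        survival=survival,
        variants=variants,
        config=config,
    )


def concat_cohorts(*cohorts: CohortData) -> CohortData:
    """Stack cohorts sharing the same variant panel (pooled analysis)."""
    first = cohorts[0]
    for c in cohorts[1:]:
        if list(c.dosages.columns) != list(first.dosages.columns):
            raise ValidationError("cohorts have different variant panels")
    return CohortData(
        dosages=pd.concat([c.dosages for c in cohorts], ignore_index=True),
        covariates=pd.concat([c.covariates for c in cohorts], ignore_index=True),
        exposure=pd.concat([c.exposure for c in cohorts], ignore_index=True),
        survival=pd.concat([c.survival for c in cohorts], ignore_index=True),
        variants=first.variants,
        config=None,
    )


def write_cohort(cohort: CohortData, directory: str | Path) -> None:
    """Write a cohort as TSVs plus a JSON sidecar of the generating config."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.dosages.to_csv(d / "dosages.tsv", sep="\t", index=False)
    subjects = cohort.covariates.copy()
    subjects["log2_exposure"] = cohort.exposure.to_numpy()
    subjects.to_csv(d / "subjects.tsv", sep="\t", index=False)
    cohort.survival.to_csv(d / "survival.tsv", sep="\t", index=False)
    cohort.variants.to_csv(d / "variants.tsv", sep="\t", index=False)
    if cohort.config is not None:
        cfg = asdict(cohort.config)
        (d / "config.json").write_text(json.dumps(cfg, indent=2, default=str))


def read_cohort(directory: str | Path) -> CohortData:
    d = Path(directory)
    subjects = pd.read_csv(d / "subjects.tsv", sep="\t")
    return CohortData(
        dosages=pd.read_csv(d / "dosages.tsv", sep="\t"),
        covariates=subjects.drop(columns=["log2_exposure"]),
        exposure=subjects["log2_exposure"],
        survival=pd.read_csv(d / "survival.tsv", sep="\t"),
        variants=pd.read_csv(d / "variants.tsv", sep="\t"),
    )
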