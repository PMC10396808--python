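"""Exposure GWAS: per-variant linear association, instrument selection.

Covers the variant-to-instrument funnel: a least-squares scan of dosage
against log2-exposure with covariate adjustment, MAF and genome-wide
significance filters, greedy LD clumping on raw dosage correlations,
discovery/replication selection, pooled re-estimation, and the
instrument-strength statistics (per-SNP F, joint variance explained).

Scan results are plain DataFrames with columns id, chrom, pos, ea, ra, eaf,
beta, se, p, n; the covariate set used is recorded in ``.attrs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigurationError,
    InstrumentTable,
    InstrumentRecord,
    ExposureAssoc,
    Variant,
    ValidationError,
    p_from_z,
)
from .simulate import CohortData, concat_cohorts

__all__ = ["snp_exposure_scan", "maf_filter", "significance_filter", "ld_clump",
           "ReplicationRule", "discovery_replication", "pooled_reestimate",
           "dosages_from_vcf", "f_statistic", "f_statistic_r2",
           "variance_explained"]


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, C] by least squares."""
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def snp_exposure_scan(cohort: CohortData, covariates: list[str] | None = None
                      ) -> pd.DataFrame:
    """Per-variant least squares of exposure on dosage plus covariates.

    p-values use the normal approximation to the t distribution (the
    intended sample sizes make the difference negligible).  Missing dosages
    are handled per variant by complete-case analysis; a constant dosage
    column yields NaN statistics with a warning rather than a hard failure.
    """
    covariates = covariates or []
    y_all = cohort.exposure.to_numpy(dtype=float)
    n_all = y_all.size
    C_all = np.column_stack(
        [np.ones(n_all)] + [cohort.covariates[c].to_numpy(dtype=float)
                            for c in covariates])
    k_cov = C_all.shape[1]

    G = cohort.dosages.to_numpy(dtype=float)
    complete = not np.isnan(G).any()
    if complete:
        y_res = _residualize(y_all, C_all)

    rows = []
    for j, vid in enumerate(cohort.dosages.columns):
        g = G[:, j]
        mask = ~np.isnan(g)
        if complete:
            g_use, y_use, n = g, y_res, n_all
            g_res = _residualize(g_use, C_all)
        else:
            C = C_all[mask]
            y_use = _residualize(y_all[mask], C)
            g_res = _residualize(g[mask], C)
            n = int(mask.sum())
        ss_g = float(g_res @ g_res)
        if ss_g <= 1e-12:
            warnings.warn(f"{vid}: constant dosage; association undefined")
            beta = se = p = np.nan
        else:
            beta = float(g_res @ y_use) / ss_g
            resid = y_use - beta * g_res
            dof = n - k_cov - 1
            sigma2 = float(resid @ resid) / dof
            se = float(np.sqrt(sigma2 / ss_g))
            p = p_from_z(beta / se)
        meta = cohort.variants.set_index("id").loc[vid]
        rows.append({"id": vid, "chrom": str(meta["chrom"]), "pos": int(meta["pos"]),
                     "ea": meta["ea"], "ra": meta["ra"],
                     "eaf": float(np.nanmean(g)) / 2.0,
                     "beta": beta, "se": se, "p": p, "n": n})
    scan = pd.DataFrame(rows)
    scan.attrs["covariates"] = list(covariates)
    return scan


def maf_filter(scan: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Retain variants with minor-allele frequency >= threshold (variants
    below the cut are excluded; equality retains)."""
    if not (0.0 < threshold < 0.5):
        raise ConfigurationError("MAF threshold must be in (0, 0.5)")
    maf = np.minimum(scan["eaf"], 1.0 - scan["eaf"])
    return scan[maf >= threshold].reset_index(drop=True)


def significance_filter(scan: pd.DataFrame, alpha: float = 5e-8) -> pd.DataFrame:
    """Retain variants with p strictly below alpha."""
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha must be in (0, 1)")
    return scan[scan["p"] < alpha].reset_index(drop=True)


def ld_clump(scan: pd.DataFrame, genotypes: pd.DataFrame,
             r2_threshold: float = 0.001, window_kb: float = 10_000
             ) -> pd.DataFrame:
    """Greedy LD clumping on raw dosage correlations.

    Variants are visited by ascending p (ties broken by genomic coordinate);
    a variant is accepted iff its squared dosage correlation with every
    already-accepted variant on the same chromosome within ``window_kb`` is
    below ``r2_threshold``.
    """
    missing = [v for v in scan["id"] if v not in genotypes.columns]
    if missing:
        raise ValidationError(f"clumping requires genotypes for {missing}")
    order = scan.sort_values(["p", "chrom", "pos"], kind="stable")
    accepted: list[int] = []
    for idx, row in order.iterrows():
        ok = True
        g1 = genotypes[row["id"]].to_numpy(dtype=float)
        for aidx in accepted:
            arow = scan.loc[aidx]
            if arow["chrom"] != row["chrom"]:
                continue
            if abs(arow["pos"] - row["pos"]) > window_kb * 1000:
                continue
            g2 = genotypes[arow["id"]].to_numpy(dtype=float)
            mask = ~(np.isnan(g1) | np.isnan(g2))
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(g1[mask], g2[mask])[0, 1]
            if np.isnan(r):
                r = 0.0
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(idx)
    return scan.loc[accepted].reset_index(drop=True)


@dataclass(frozen=True)
class ReplicationRule:
    """Replication criterion: same effect direction and replication p below
    a threshold (default Bonferroni over the candidate count)."""

    alpha: float | None = None     # None -> 0.05 / n_candidates
    require_direction: bool = True

    def threshold(self, n_candidates: int) -> float:
        return self.alpha if self.alpha is not None else 0.05 / max(n_candidates, 1)


def discovery_replication(discovery: pd.DataFrame, replication: pd.DataFrame,
                          rule: ReplicationRule | None = None) -> pd.DataFrame:
    """Keep discovery candidates that replicate.

    ``discovery`` is the already-filtered candidate scan; candidates absent
    from the replication scan are excluded with a warning.  Returns the
    discovery rows of the retained variants with replication beta/p attached.
    """
    rule = rule or ReplicationRule()
    repl = replication.set_index("id")
    thr = rule.threshold(len(discovery))
    kept = []
    for _, row in discovery.iterrows():
        vid = row["id"]
        if vid not in repl.index:
            warnings.warn(f"{vid}: absent from replication scan; excluded")
            continue
        r = repl.loc[vid]
        if rule.require_direction and np.sign(r["beta"]) != np.sign(row["beta"]):
            continue
        if not (r["p"] < thr):
            continue
        out = dict(row)
        out["beta_repl"], out["p_repl"] = float(r["beta"]), float(r["p"])
        kept.append(out)
    return pd.DataFrame(kept, columns=list(discovery.columns) + ["beta_repl", "p_repl"])


def pooled_reestimate(cohorts: list[CohortData], variant_ids: list[str],
                      covariates: list[str] | None = None,
                      metadata: dict | None = None) -> InstrumentTable:
    """Re-estimate instrument-exposure effects on the concatenated cohorts.

    The pooled betas/SEs populate the instrument table used downstream (the
    selection cohorts' own estimates are discarded to avoid winner's curse
    asymmetries between stages being baked into the weights).
    """
    pooled = concat_cohorts(*cohorts) if len(cohorts) > 1 else cohorts[0]
    pooled = CohortData(
        dosages=pooled.dosages[variant_ids],
        covariates=pooled.covariates,
        exposure=pooled.exposure,
        survival=pooled.survival,
        variants=pooled.variants[pooled.variants["id"].isin(variant_ids)],
    )
    scan = snp_exposure_scan(pooled, covariates)
    records = []
    for _, row in scan.iterrows():
        records.append(InstrumentRecord(
            variant=Variant(id=row["id"], chrom=str(row["chrom"]), pos=int(row["pos"]),
                            effect_allele=str(row["ea"]), reference_allele=str(row["ra"]),
                            eaf=float(row["eaf"])),
            exposure=ExposureAssoc(beta=float(row["beta"]), se=float(row["se"]),
                                   p=float(row["p"]), n=int(row["n"])),
        ))
    return InstrumentTable(records=records, metadata=metadata or {"stage": "pooled"})


def dosages_from_vcf(path: str) -> pd.DataFrame:
    """Read biallelic genotypes from a VCF as ALT-allele dosage counts.

    GT fields map to 0/1/2 (missing genotypes to NaN); multiallelic records
    are rejected, matching the biallelic instrument model.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{rec.ID or rec.CHROM + ':' + str(rec.POS)}: multiallelic "
                "record; split or filter before ingestion")
        gt = rec.gt_types.astype(float)   # 0/1/2, 3 = unknown with gts012
        gt[gt == 3] = np.nan
        cols[rec.ID or f"{rec.CHROM}:{rec.POS}"] = gt
    return pd.DataFrame(cols, index=vcf.samples)


def f_statistic(beta: float, se: float) -> float:
    """Single-predictor Wald F = (beta/se)^2."""
    if se <= 0:
        raise ValidationError("se must be > 0")
    return (beta / se) ** 2


def f_statistic_r2(r2: float, n: int) -> float:
    """R^2-based convention: F = (n - 2) * r2 / (1 - r2)."""
    return (n - 2) * r2 / (1.0 - r2)


def variance_explained(cohort: CohortData, variant_ids: list[str] | None = None,
                       covariates: list[str] | None = None) -> float:
    """Joint R² of (covariate-residualized) exposure on instrument dosages."""
    ids = list(variant_ids) if variant_ids is not None else list(cohort.dosages.columns)
    G = cohort.dosages[ids].to_numpy(dtype=float)
    G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    n = G.shape[0]
    if n <= G.shape[1] + 1:
        raise ValidationError("fewer subjects than predictors")
    y = cohort.exposure.to_numpy(dtype=float)
    if covariates:
        C = np.column_stack([np.ones(n)] + [cohort.covariates[c].to_numpy(dtype=float)
                                            for c in covariates])
        y = _residualize(y, C)
    X = np.column_stack([np.ones(n), G])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid ** 2).sum()) / tss
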