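"""Semiparametric additive-hazards regression with constant covariate effects.

The model is lambda_i(t) = lambda_0(t) + beta' Z_i: covariates shift the
hazard additively, so per-allele effects stay collapsible and linear — the
property that makes hazard differences a valid outcome scale for two-sample
Mendelian randomization, unlike hazard ratios from a Cox model.

The constant-effect (Lin-Ying) estimator solves the closed-form estimating
equation

    A beta = b,
    A = sum_i int Y_i(t) (Z_i - Zbar(t)) (Z_i - Zbar(t))' dt,
    b = sum_i int (Z_i - Zbar(t)) dN_i(t),

with Zbar(t) the at-risk average of Z and Y_i(t) = 1{T_i >= t}.  The
variance is the sandwich A^-1 B A^-1 with
B = sum_i int (Z_i - Zbar(t)) (Z_i - Zbar(t))' dN_i(t).  Tied event times
are treated as simultaneous (the risk-set average at the tied time includes
every tied subject).  Entry time is 0 for everyone (diagnosis is the time
origin) and integration stops at the largest observed time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError, p_from_z

__all__ = ["HazardFit", "RankDeficiencyError", "lin_ying_fit",
           "cause_specific", "snp_outcome_scan", "CAUSE_OF_INTEREST"]

#: cause code used for the cause-of-interest throughout the package
CAUSE_OF_INTEREST = "CRC"


class RankDeficiencyError(np.linalg.LinAlgError):
    """The at-risk design is singular; names the offending columns."""


@dataclass
class HazardFit:
    """Constant-effect additive-hazards fit.

    ``coef`` is in hazard-difference per person-year per covariate unit;
    multiply by 1,000 (``hd_per_1000py``) for the reporting scale.
    """

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray            # robust (sandwich) variance
    n_subjects: int
    n_events: int
    scale_note: str = "multiply coef by 1,000 for HD per 1,000 person-years"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return np.array([p_from_z(z) for z in self.z])

    @property
    def hd_per_1000py(self) -> np.ndarray:
        return 1000.0 * self.coef

    @property
    def se_per_1000py(self) -> np.ndarray:
        return 1000.0 * self.se

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names,
            "hd_per_1000py": self.hd_per_1000py,
            "se_per_1000py": self.se_per_1000py,
            "z": self.z,
            "p": self.p,
        })


def _as_design(design, names):
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    Z = np.asarray(design, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if names is None:
        names = [f"x{j}" for j in range(Z.shape[1])]
    return Z, list(names)


def lin_ying_fit(time, event, design, names: list[str] | None = None) -> HazardFit:
    """Fit the constant-effect additive-hazards model.

    Parameters
    ----------
    time, event
        Follow-up times (> 0, years) and event indicators (0/1).
    design
        Covariate matrix (n x p), without an intercept column — the
        baseline hazard absorbs the intercept nonparametrically.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    Z, names = _as_design(design, names)
    n, p = Z.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise ValidationError("time, event and design must have equal length")
    if np.any(t <= 0):
        raise ValidationError("all follow-up times must be > 0")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValidationError("no events: additive-hazards fit undefined")

    order = np.argsort(t, kind="stable")
    t, e, Z = t[order], e[order], Z[order]

    # Suffix (risk-set) sums: row k aggregates subjects with time >= t_k.
    # With tied times, the risk set at t must include every tied subject,
    # so per-row quantities are read at the first occurrence of each time.
    S0 = np.arange(n, 0, -1, dtype=float)
    S1 = np.cumsum(Z[::-1], axis=0)[::-1]
    first = np.searchsorted(t, t, side="left")
    Zbar = S1[first] / S0[first][:, None]

    # A = int risk-set scatter dt.  Using sum_k dt_k * M2_k = Z' diag(t) Z
    # (each subject contributes Z_i Z_i' for exactly t_i time units) and
    # sum_k dt_k S1_k S1_k'/S0_k = W' diag(dt) W with W = S1/sqrt(S0).
    dt = np.diff(t, prepend=0.0)
    W = S1 / np.sqrt(S0)[:, None]
    A = Z.T @ (t[:, None] * Z) - W.T @ (dt[:, None] * W)
    A = (A + A.T) / 2.0

    ev = e > 0
    Zc_ev = Z[ev] - Zbar[ev]
    b = Zc_ev.sum(axis=0)
    B = Zc_ev.T @ Zc_ev

    # Rank check with informative column naming.
    diag = np.diag(A).copy()
    degenerate = [names[j] for j in range(p) if diag[j] <= 0 or not np.isfinite(diag[j])]
    scale = np.sqrt(np.where(diag > 0, diag, 1.0))
    Acorr = A / np.outer(scale, scale)
    if degenerate or np.linalg.matrix_rank(Acorr, tol=1e-10) < p:
        if not degenerate:
            # name columns whose removal restores full rank
            for j in range(p):
                keep = [k for k in range(p) if k != j]
                sub = Acorr[np.ix_(keep, keep)]
                if np.linalg.matrix_rank(sub, tol=1e-10) == p - 1:
                    degenerate.append(names[j])
        raise RankDeficiencyError(
            f"singular at-risk design; offending columns: {degenerate or names}"
        )

    coef = np.linalg.solve(A, b)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    return HazardFit(names=names, coef=coef, cov=cov,
                     n_subjects=n, n_events=n_events)


def cause_specific(survival: pd.DataFrame, cause_of_interest: str = CAUSE_OF_INTEREST
                   ) -> pd.DataFrame:
    """Recode deaths from other causes as censoring at the death time.

    ``survival`` needs columns ``time``, ``event`` and ``cause`` (the cause
    code, set whenever event == 1).  The all-cause view is the input itself.
    """
    out = survival.copy()
    ev = out["event"].astype(bool)
    if "cause" not in out.columns:
        raise ValidationError("survival table lacks a 'cause' column")
    missing = ev & out["cause"].isna()
    if missing.any():
        raise ValidationError(
            f"{int(missing.sum())} events have no cause code; cannot form "
            "cause-specific view"
        )
    other = ev & (out["cause"] != cause_of_interest)
    out.loc[other, "event"] = 0
    out.loc[~out["event"].astype(bool), "cause"] = pd.NA
    return out


def snp_outcome_scan(cohort, covariates: list[str] | None = None,
                     cause_view: str = "overall") -> pd.DataFrame:
    """Per-variant additive-hazards association with survival.

    One constant-effect fit per variant (dosage plus the named covariate
    columns); reports the dosage coefficient as HD per 1,000 person-years
    with its robust SE and two-sided p.  Monomorphic or otherwise
    degenerate variants are skipped with a warning rather than aborting
    the scan.
    """
    surv = cohort.survival
    if cause_view != "overall":
        surv = cause_specific(surv, cause_view)
    covariates = covariates or []
    C = cohort.covariates[covariates].to_numpy(dtype=float) if covariates else None

    rows = []
    for vid in cohort.dosages.columns:
        g = cohort.dosages[vid].to_numpy(dtype=float)
        mask = ~np.isnan(g)
        design = g[mask, None] if C is None else np.column_stack([g[mask], C[mask]])
        names = ["dosage"] + covariates
        try:
            fit = lin_ying_fit(surv["time"].to_numpy()[mask],
                               surv["event"].to_numpy()[mask],
                               design, names=names)
        except (ValidationError, RankDeficiencyError) as err:
            warnings.warn(f"{vid}: skipped in outcome scan ({err})")
            continue
        rows.append({
            "id": vid,
            "hd": fit.hd_per_1000py[0],
            "se": fit.se_per_1000py[0],
            "p": fit.p[0],
            "n": int(mask.sum()),
            "n_events": fit.n_events,
        })
    return pd.DataFrame(rows)
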