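"""Weighted genetic risk scores and their additive-hazards associations.

The score is the weighted mean per non-missing marker (not the weighted
sum), matching how PLINK scores profiles: subjects with missing genotypes
are averaged over the markers they do carry.  Association with survival is
reported per 1 SD of the score and by quintile with the middle quintile as
the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError
from .hazards import HazardFit, cause_specific, lin_ying_fit

__all__ = ["GRSVector", "compute_grs", "quintile_labels", "grs_survival"]


@dataclass
class GRSVector:
    score: np.ndarray          # weighted mean per non-missing marker; NaN if none
    standardized: np.ndarray   # (score - mean) / SD over non-missing subjects
    quintile: np.ndarray       # 1..5 (0 marks subjects with no observed marker)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.score).sum())


def compute_grs(dosages: pd.DataFrame, weights: dict[str, float]) -> GRSVector:
    """score_i = sum_j w_j g_ij / #observed markers for subject i."""
    ids = list(dosages.columns)
    missing_w = [i for i in ids if i not in weights]
    if missing_w:
        raise ValidationError(f"no weight for markers: {missing_w}")
    w = np.array([weights[i] for i in ids], dtype=float)
    if np.all(w == 0):
        raise ValidationError("all weights are zero; score is degenerate")
    G = dosages.to_numpy(dtype=float)
    obs = ~np.isnan(G)
    n_obs = obs.sum(axis=1)
    contrib = np.where(obs, G * w, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_obs > 0, contrib / n_obs, np.nan)
    ok = n_obs > 0
    mu, sd = score[ok].mean(), score[ok].std(ddof=0)
    if sd == 0:
        raise ValidationError("score has zero variance")
    std = np.where(ok, (score - mu) / sd, np.nan)
    return GRSVector(score=score, standardized=std, quintile=quintile_labels(score))


def quintile_labels(score: np.ndarray) -> np.ndarray:
    """Rank-based quintiles 1..5 with sizes within one of n/5.

    Ties are broken by stable subject order; subjects with a missing score
    get label 0.
    """
    ok = ~np.isnan(score)
    n = int(ok.sum())
    labels = np.zeros(score.size, dtype=int)
    if n == 0:
        return labels
    order = np.argsort(score[ok], kind="stable")
    q_sorted = 1 + (5 * np.arange(n)) // n
    lab_ok = np.empty(n, dtype=int)
    lab_ok[order] = q_sorted
    labels[ok] = lab_ok
    return labels


def grs_survival(grs: GRSVector, survival: pd.DataFrame,
                 covariates: pd.DataFrame | None = None,
                 covariate_names: list[str] | None = None,
                 cause_view: str = "overall") -> tuple[HazardFit, HazardFit]:
    """Additive-hazards association of the score with survival.

    Returns (per-SD fit, per-quintile fit).  The quintile design holds
    indicator columns for quintiles 1, 2, 4 and 5; quintile 3 is the
    reference and its contrast is zero by construction.
    """
    surv = survival if cause_view == "overall" else cause_specific(survival, cause_view)
    ok = ~np.isnan(grs.score)
    covariate_names = covariate_names or []
    C = (covariates[covariate_names].to_numpy(dtype=float)[ok]
         if covariate_names else None)
    t = surv["time"].to_numpy()[ok]
    e = surv["event"].to_numpy()[ok]

    design_sd = grs.standardized[ok, None]
    if C is not None:
        design_sd = np.column_stack([design_sd, C])
    fit_sd = lin_ying_fit(t, e, design_sd, names=["grs_per_sd"] + covariate_names)

    q = grs.quintile[ok]
    cols = [(q == k).astype(float) for k in (1, 2, 4, 5)]
    names_q = ["q1", "q2", "q4", "q5"]
    design_q = np.column_stack(cols if C is None else cols + [C])
    fit_q = lin_ying_fit(t, e, design_q, names=names_q + covariate_names)
    return fit_sd, fit_q
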