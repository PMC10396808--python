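"""Two-sample Mendelian randomization estimators on summary statistics.

Given per-variant exposure betas (log2-CRP per allele) and outcome hazard
differences (per 1,000 person-years per allele), each instrument yields a
Wald ratio by/bx — the hazard difference per doubling of CRP, since a unit
change in log2-exposure is a doubling.  The estimators combine the ratios:

* IVW: inverse-variance-weighted mean with weights bx^2/se_by^2, optionally
  with multiplicative random-effects SE inflation by sqrt(Q/(J-1)).
* simple / weighted median: the ratio at 50% of the (equal or IVW) weight
  distribution, SE by parametric bootstrap.
* MR-Egger: weighted regression of by on bx with a free intercept; the
  intercept estimates average directional pleiotropy per variant.

Wald-ratio SEs are first order (se_by/|bx|), ignoring exposure-side
uncertainty; a second-order option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import t as student_t

from .datamodel import (
    InstrumentTable,
    MREstimate,
    ValidationError,
    p_from_z,
    z_from_p,
)

__all__ = ["OrientedInstrument", "orient", "ivw", "simple_median",
           "weighted_median", "weighted_median_point", "egger", "leave_out",
           "mr_summary"]

_Z95 = z_from_p(0.05)


@dataclass(frozen=True)
class OrientedInstrument:
    """One instrument with the exposure effect oriented positive (outcome
    effect sign-flipped in tandem, which leaves the Wald ratio unchanged)."""

    id: str
    bx: float
    se_bx: float
    by: float
    se_by: float

    def __post_init__(self) -> None:
        if self.bx <= 0:
            raise ValidationError(f"{self.id}: oriented bx must be > 0")

    @property
    def ratio(self) -> float:
        return self.by / self.bx

    def ratio_se(self, order: int = 1) -> float:
        first = self.se_by / abs(self.bx)
        if order == 1:
            return first
        return float(np.sqrt(first**2 + self.by**2 * self.se_bx**2 / self.bx**4))

    @property
    def weight(self) -> float:
        """IVW weight = 1 / ratio_se^2 = bx^2 / se_by^2 (first order)."""
        return self.bx**2 / self.se_by**2


def orient(table: InstrumentTable, outcome: str = "overall") -> list[OrientedInstrument]:
    """Build oriented instruments, recovering missing SEs from p-values."""
    out = []
    for rec in table:
        bx = rec.exposure.beta
        if bx == 0:
            raise ValidationError(f"{rec.variant.id}: exposure beta is 0; invalid instrument")
        se_bx = rec.exposure.se_or_recovered()
        assoc = rec.outcome(outcome)
        by, se_by = assoc.hd, assoc.se_or_recovered()
        sign = 1.0 if bx > 0 else -1.0
        out.append(OrientedInstrument(id=rec.variant.id, bx=sign * bx, se_bx=se_bx,
                                      by=sign * by, se_by=se_by))
    return out


def _estimate(method, est, se, n):
    p = p_from_z(est / se) if se > 0 else 0.0
    return MREstimate(method=method, estimate=float(est), se=float(se),
                      ci_low=float(est - _Z95 * se), ci_high=float(est + _Z95 * se),
                      p=max(p, 1e-300), n_instruments=n)


def ivw(oriented: list[OrientedInstrument],
        model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate of the HD per doubling of exposure.

    ``model='fixed'`` uses SE = (sum w)^{-1/2}; ``'multiplicative_random'``
    (default) inflates it by max(1, sqrt(Q/(J-1))), Q being Cochran's
    heterogeneity statistic.  The point estimate is identical either way.
    """
    if not oriented:
        raise ValidationError("IVW needs at least one instrument")
    w = np.array([o.weight for o in oriented])
    r = np.array([o.ratio for o in oriented])
    est = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if model == "multiplicative_random" and len(oriented) > 1:
        q = float(np.sum(w * (r - est) ** 2))
        se *= max(1.0, np.sqrt(q / (len(oriented) - 1)))
    elif model not in ("fixed", "multiplicative_random"):
        raise ValidationError(f"unknown IVW variance model {model!r}")
    return _estimate("IVW", est, se, len(oriented))


def weighted_median_point(ratios, weights) -> float:
    """Ratio at 50% of the standardized mid-cumulative weight distribution.

    Sort ratios ascending; s_j = (cumw_j - w_j/2) / sum(w); return theta_j
    where s_j = 0.5 exactly, else interpolate linearly between the
    bracketing (s, theta) pairs.
    """
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.size == 0:
        raise ValidationError("weighted median of an empty set")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    s = (np.cumsum(w) - w / 2.0) / w.sum()
    exact = np.isclose(s, 0.5, rtol=0.0, atol=1e-12)
    if exact.any():
        return float(r[np.argmax(exact)])
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _median_bootstrap(oriented, weight_fn, method, n_boot, seed):
    if len(oriented) < 3:
        import warnings
        warnings.warn(f"{method}: fewer than 3 instruments; estimate is fragile")
    r = np.array([o.ratio for o in oriented])
    w = weight_fn(oriented)
    point = weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    bx = np.array([o.bx for o in oriented])
    se_bx = np.array([o.se_bx for o in oriented])
    by = np.array([o.by for o in oriented])
    se_by = np.array([o.se_by for o in oriented])
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, se_bx)
        by_b = rng.normal(by, se_by)
        # keep orientation tied to the drawn exposure effect
        sign = np.where(bx_b >= 0, 1.0, -1.0)
        bx_b, by_b = np.abs(bx_b), by_b * sign
        bx_b = np.where(bx_b == 0, 1e-300, bx_b)
        ratios_b = by_b / bx_b
        w_b = bx_b**2 / se_by**2 if weight_fn is _ivw_weights else np.ones_like(bx_b)
        draws[b] = weighted_median_point(ratios_b, w_b)
    se = float(draws.std(ddof=1))
    if se == 0:
        se = 1e-300
    return _estimate(method, point, se, len(oriented))


def _equal_weights(oriented):
    return np.ones(len(oriented))


def _ivw_weights(oriented):
    return np.array([o.weight for o in oriented])


def simple_median(oriented, n_boot: int = 10000, seed: int = 0) -> MREstimate:
    """Equal-weight median of the Wald ratios; SE by parametric bootstrap."""
    return _median_bootstrap(oriented, _equal_weights, "simple_median", n_boot, seed)


def weighted_median(oriented, n_boot: int = 10000, seed: int = 0) -> MREstimate:
    """IVW-weighted median of the Wald ratios; SE by parametric bootstrap."""
    return _median_bootstrap(oriented, _ivw_weights, "weighted_median", n_boot, seed)


def egger(oriented, model: str = "multiplicative_random", dist: str = "normal"
          ) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted least squares of by on bx with intercept.

    Returns (slope, intercept) estimates.  Weights are 1/se_by^2.  The slope
    is the pleiotropy-adjusted causal estimate per doubling; the intercept is
    the average directional pleiotropic effect per variant, and its p-value
    is the pleiotropy test.  Needs >= 3 instruments (with 2 the fit is exact
    and inference is vacuous).

    ``dist`` picks the reference distribution for CIs and p-values:
    ``'normal'`` (the convention of the common summary-MR tools) or ``'t'``
    with J-2 degrees of freedom, which keeps the intercept test calibrated
    for small instrument counts when the multiplicative scale is estimated.
    """
    j = len(oriented)
    if j < 3:
        raise ValidationError(f"MR-Egger needs >= 3 instruments, got {j}")
    bx = np.array([o.bx for o in oriented])
    by = np.array([o.by for o in oriented])
    w = np.array([1.0 / o.se_by**2 for o in oriented])
    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=w).fit()
    se_fixed = np.sqrt(np.diag(res.normalized_cov_params))
    if dist == "normal":
        crit, sf = _Z95, None
        inflate = max(1.0, np.sqrt(res.scale))  # floored, as MR tooling does
    elif dist == "t":
        crit = float(student_t.ppf(0.975, j - 2))
        sf = lambda z: float(2.0 * student_t.sf(abs(z), j - 2))  # noqa: E731
        inflate = np.sqrt(res.scale)            # plain WLS scale: exact t under the null
    else:
        raise ValidationError(f"unknown reference distribution {dist!r}")
    if model == "multiplicative_random":
        se = se_fixed * inflate
    elif model == "fixed":
        se = se_fixed
    else:
        raise ValidationError(f"unknown Egger variance model {model!r}")

    def build(method, est, s):
        p = p_from_z(est / s) if sf is None else sf(est / s)
        return MREstimate(method=method, estimate=float(est), se=float(s),
                          ci_low=float(est - crit * s), ci_high=float(est + crit * s),
                          p=max(p, 1e-300), n_instruments=j)

    return (build("egger_slope", res.params[1], se[1]),
            build("egger_intercept", res.params[0], se[0]))


def leave_out(table: InstrumentTable, exclude_ids) -> InstrumentTable:
    """Drop named instruments; downstream estimators re-run unchanged."""
    return table.drop(list(exclude_ids))


def mr_summary(table: InstrumentTable, outcomes=("overall", "cause_specific"),
               exclusions=((),), n_boot: int = 10000, seed: int = 0,
               model: str = "multiplicative_random"):
    """All five estimators for each outcome and exclusion set.

    Returns a list of dicts mirroring the usual MR results-table layout
    (method x outcome x analysis), convenient for TSV export.
    """
    rows = []
    for excl in exclusions:
        sub = leave_out(table, list(excl)) if excl else table
        label = "main" if not excl else "excluding " + ",".join(excl)
        for outcome in outcomes:
            o = orient(sub, outcome)
            ests = [ivw(o, model=model),
                    simple_median(o, n_boot=n_boot, seed=seed),
                    weighted_median(o, n_boot=n_boot, seed=seed)]
            if len(o) >= 3:
                ests.extend(egger(o, model=model))
            else:
                import warnings
                warnings.warn(f"{label}/{outcome}: <3 instruments, Egger skipped")
            for est in ests:
                rows.append({"analysis": label, "outcome": outcome,
                             "method": est.method, "estimate": est.estimate,
                             "se": est.se, "ci_low": est.ci_low,
                             "ci_high": est.ci_high, "p": est.p,
                             "n_instruments": est.n_instruments})
    return rows
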