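"""Domain types and delimited-text I/O for instrument summary statistics.

The central container is :class:`InstrumentTable`, an ordered collection of
per-variant records pairing a variant's exposure association (change in
log2-CRP per effect-allele copy) with its outcome associations (hazard
difference per 1,000 person-years for overall and cause-specific mortality).
Published tables typically print a point estimate and a two-sided p-value but
no standard error; :func:`se_from_p` recovers the SE by normal inversion, the
canonical path used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "Variant",
    "ExposureAssoc",
    "OutcomeAssoc",
    "InstrumentRecord",
    "InstrumentTable",
    "MREstimate",
    "z_from_p",
    "se_from_p",
    "p_from_z",
    "read_instruments",
    "write_instruments",
    "load_table1_fixture",
]


class ValidationError(ValueError):
    """A value or table violates a domain invariant."""


class ConfigurationError(ValueError):
    """An input file or configuration is structurally unusable."""


# ---------------------------------------------------------------------------
# p-value / z conversions
# ---------------------------------------------------------------------------

def z_from_p(p: float) -> float:
    """Two-sided p-value to the magnitude of the standard-normal score.

    Returns z >= 0 with 2*(1 - Phi(z)) = p.  ``scipy``'s inverse survival
    function works in log space internally, so the inversion is stable down
    to p ~ 1e-300 (needed for GWAS p-values such as 7.23e-200).
    """
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p-value must be in (0, 1], got {p!r}")
    return float(norm.isf(p / 2.0))


def p_from_z(z: float) -> float:
    """Magnitude of a standard-normal score to its two-sided p-value."""
    return float(2.0 * norm.sf(abs(z)))


def se_from_p(estimate: float, p: float) -> float:
    """Recover a standard error from a point estimate and two-sided p-value.

    SE = |estimate| / z(p).  Used to reconstruct per-SNP outcome SEs from
    printed hazard differences and p-values.
    """
    z = z_from_p(p)
    if z == 0.0:
        if estimate != 0.0:
            raise ValidationError(
                f"SE undefined: p = 1 with nonzero estimate {estimate!r}"
            )
        return math.inf
    return abs(estimate) / z


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A biallelic variant.  Positions are 1-based GRCh37; indel alleles
    (e.g. ``insA``) are opaque strings, never normalized."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    reference_allele: str
    eaf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.id}: EAF must be in (0,1), got {self.eaf}")
        if self.effect_allele == self.reference_allele:
            raise ValidationError(f"{self.id}: effect and reference allele identical")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class ExposureAssoc:
    """Variant-exposure association: beta on the log2-exposure scale."""

    beta: float
    p: float
    se: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"exposure p must be in (0,1], got {self.p}")
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"exposure se must be > 0, got {self.se}")

    def se_or_recovered(self) -> float:
        return self.se if self.se is not None else se_from_p(self.beta, self.p)


@dataclass(frozen=True)
class OutcomeAssoc:
    """Variant-outcome association: hazard difference per 1,000 person-years
    per effect-allele copy."""

    hd: float
    p: float
    se: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"outcome p must be in (0,1], got {self.p}")
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"outcome se must be > 0, got {self.se}")

    def se_or_recovered(self) -> float:
        return self.se if self.se is not None else se_from_p(self.hd, self.p)


@dataclass(frozen=True)
class InstrumentRecord:
    variant: Variant
    exposure: ExposureAssoc
    outcome_overall: OutcomeAssoc | None = None
    outcome_cause_specific: OutcomeAssoc | None = None

    def outcome(self, which: str) -> OutcomeAssoc:
        if which == "overall":
            out = self.outcome_overall
        elif which == "cause_specific":
            out = self.outcome_cause_specific
        else:
            raise ConfigurationError(
                f"unknown outcome {which!r}; expected 'overall' or 'cause_specific'"
            )
        if out is None:
            raise ValidationError(f"{self.variant.id}: no {which} outcome association")
        return out


@dataclass
class InstrumentTable:
    """Ordered collection of instruments with unique variant ids."""

    records: list[InstrumentRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.variant.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate variant ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InstrumentRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.variant.id for r in self.records]

    def get(self, variant_id: str) -> InstrumentRecord:
        for r in self.records:
            if r.variant.id == variant_id:
                return r
        raise KeyError(f"{variant_id!r} not in table; known ids: {self.ids}")

    def drop(self, exclude_ids: Sequence[str]) -> "InstrumentTable":
        unknown = [i for i in exclude_ids if i not in self.ids]
        if unknown:
            raise KeyError(f"{unknown} not in table; known ids: {self.ids}")
        kept = [r for r in self.records if r.variant.id not in exclude_ids]
        return InstrumentTable(records=kept, metadata=dict(self.metadata))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            v, x = r.variant, r.exposure
            row = {
                "id": v.id, "chrom": v.chrom, "pos": v.pos,
                "ea": v.effect_allele, "ra": v.reference_allele, "eaf": v.eaf,
                "beta_x": x.beta, "se_x": x.se, "p_x": x.p, "n_x": x.n,
            }
            for key, out in (("y", r.outcome_overall), ("cs", r.outcome_cause_specific)):
                row[f"hd_{key}"] = out.hd if out else None
                row[f"se_{key}"] = out.se if out else None
                row[f"p_{key}"] = out.p if out else None
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MREstimate:
    """One MR estimator's output on the hazard-difference-per-doubling scale
    (per 1,000 person-years); the Egger intercept is per variant."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError(
                f"{self.method}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket estimate {self.estimate}"
            )
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.method}: p must be in (0,1], got {self.p}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REQUIRED = ["id", "chrom", "pos", "ea", "ra", "eaf", "beta_x", "p_x"]
_NUMERIC = ["pos", "eaf", "beta_x", "se_x", "p_x", "n_x",
            "hd_y", "se_y", "p_y", "hd_cs", "se_cs", "p_cs"]


def _opt(row: pd.Series, col: str):
    if col not in row.index:
        return None
    v = row[col]
    return None if pd.isna(v) else v


def read_instruments(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
    metadata: dict | None = None,
) -> InstrumentTable:
    """Read an instrument table from delimited text.

    ``dialect`` maps canonical column names (id, chrom, pos, ea, ra, eaf,
    beta_x, p_x, and optionally se_x, n_x, hd_y, se_y, p_y, hd_cs, se_cs,
    p_cs) to the column names in the file.  Tab-separated by default;
    pass ``sep=','`` for CSV.
    """
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "chrom": str, "ea": str, "ra": str})
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")
    for col in _NUMERIC:
        if col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any() and col in _REQUIRED:
                raise ValidationError(
                    f"{path}: non-numeric values in required column {col!r}: "
                    f"rows {list(df.index[bad])}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")

    records = []
    for _, row in df.iterrows():
        variant = Variant(
            id=str(row["id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            effect_allele=str(row["ea"]), reference_allele=str(row["ra"]),
            eaf=float(row["eaf"]),
        )
        n_x = _opt(row, "n_x")
        exposure = ExposureAssoc(
            beta=float(row["beta_x"]), p=float(row["p_x"]),
            se=_opt(row, "se_x"), n=int(n_x) if n_x is not None else None,
        )
        outcomes = {}
        for attr, key in (("outcome_overall", "y"), ("outcome_cause_specific", "cs")):
            hd, p = _opt(row, f"hd_{key}"), _opt(row, f"p_{key}")
            if hd is not None and p is not None:
                outcomes[attr] = OutcomeAssoc(hd=float(hd), p=float(p),
                                              se=_opt(row, f"se_{key}"))
        records.append(InstrumentRecord(variant=variant, exposure=exposure, **outcomes))
    return InstrumentTable(records=records, metadata=metadata or {})


def write_instruments(table: InstrumentTable, path: str | Path, sep: str = "\t") -> None:
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def write_estimates(estimates: Sequence[tuple[str, MREstimate]], path: str | Path,
                    sep: str = "\t") -> None:
    """Write (outcome label, estimate) pairs as a TSV."""
    rows = [
        {"method": e.method, "outcome": outcome, "estimate": e.estimate, "se": e.se,
         "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p,
         "n_instruments": e.n_instruments}
        for outcome, e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_table1_fixture() -> InstrumentTable:
    """The packaged 7-SNP instrument table for log2-transformed CRP.

    Seven replicated genome-wide-significant, mutually independent SNPs
    (near CRP, IL6R, LINC02819, GCKR, IL6, HNF1A and APOE) with their
    exposure betas and per-allele hazard differences for overall and
    CRC-specific mortality.  Outcome SEs are not printed at the source and
    are recovered downstream from the p-values.
    """
    with resources.as_file(
        resources.files("crpmr.data") / "table1_instruments.tsv"
    ) as path:
        return read_instruments(
            path,
            metadata={
                "exposure": "log2 CRP (mg/L)",
                "outcome": "CRC survival (HD per 1,000 PY)",
                "units_note": "per 2-fold increase in CRP",
            },
        )
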