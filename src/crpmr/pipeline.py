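"""End-to-end orchestration: simulate -> exposure GWAS -> instrument
selection -> outcome scan -> MR -> GRS -> power, from one structured config.

Each stage writes a self-describing TSV into the run directory and appends
one log line with its input/output record counts, so any downstream stage
can be re-run from the written intermediates.  A config pointing at an
instrument summary-statistics file instead of simulation settings runs the
MR stage alone (the desk-scale reproduction path).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grs as grs_mod
from . import gwas, hazards, mr
from .datamodel import (
    InstrumentRecord,
    InstrumentTable,
    OutcomeAssoc,
    read_instruments,
    load_table1_fixture,
)
from .power import PowerScenario, analytic_binary_power, simulate_survival_power
from .simulate import SimConfig, simulate_cohort, write_cohort

log = logging.getLogger("crpmr.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "attach_outcomes", "plot_instruments"]


@dataclass
class PipelineConfig:
    """Configuration for a full run; thresholds default to the study's."""

    instruments_path: str | None = None    # MR-only mode when set
    n_discovery: int = 47258
    n_replication: int = 12347
    n_outcome: int = 6460
    sim_overrides: dict = field(default_factory=dict)   # forwarded to SimConfig
    maf_threshold: float = 0.05
    gwas_alpha: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    exposure_covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    outcome_covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    exclusions: list[list[str]] = field(default_factory=lambda: [["rs429358"]])
    subgroup_column: str | None = None
    n_boot: int = 10000
    variance_model: str = "multiplicative_random"
    run_power: bool = True
    write_cohorts: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def attach_outcomes(table: InstrumentTable, scan_overall: pd.DataFrame,
                    scan_cause: pd.DataFrame | None = None) -> InstrumentTable:
    """Pair an exposure-side instrument table with outcome-scan results."""
    ov = scan_overall.set_index("id")
    cs = scan_cause.set_index("id") if scan_cause is not None else None
    records = []
    for rec in table:
        vid = rec.variant.id
        kwargs = {}
        if vid in ov.index:
            r = ov.loc[vid]
            kwargs["outcome_overall"] = OutcomeAssoc(hd=float(r["hd"]),
                                                     se=float(r["se"]), p=float(r["p"]))
        if cs is not None and vid in cs.index:
            r = cs.loc[vid]
            kwargs["outcome_cause_specific"] = OutcomeAssoc(
                hd=float(r["hd"]), se=float(r["se"]), p=float(r["p"]))
        records.append(InstrumentRecord(variant=rec.variant, exposure=rec.exposure,
                                        **kwargs))
    return InstrumentTable(records=records, metadata=dict(table.metadata))


def _stage(name, t0, n_in, n_out, seed=None):
    log.info("stage=%s in=%s out=%s seed=%s wall=%.2fs", name, n_in, n_out, seed,
             time.time() - t0)


def _mr_stage(table, cfg, outdir):
    t0 = time.time()
    known = set(table.ids)
    exclusions = [()]
    for excl in cfg.exclusions:
        resolvable = [i for i in excl if i in known]
        if len(resolvable) < len(excl):
            log.warning("exclusion ids %s not in instrument table; skipped",
                        [i for i in excl if i not in known])
        if resolvable:
            exclusions.append(tuple(resolvable))
    outcomes = [w for w in ("overall", "cause_specific")
                if all(getattr(r, f"outcome_{w}") is not None for r in table)]
    rows = mr.mr_summary(table, outcomes=outcomes, exclusions=exclusions,
                         n_boot=cfg.n_boot, seed=cfg.seed, model=cfg.variance_model)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "mr_estimates.tsv", sep="\t", index=False)
    _stage("mr", t0, len(table), len(df), cfg.seed)
    return df


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages; returns a dict of the key outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str))
    outputs: dict = {}

    if config.instruments_path is not None:
        try:
            table = (load_table1_fixture()
                     if config.instruments_path == "fixture"
                     else read_instruments(config.instruments_path))
        except Exception as err:
            raise RuntimeError(f"stage=load_instruments failed on "
                               f"{config.instruments_path}: {err}") from err
        outputs["instruments"] = table
        outputs["mr"] = _mr_stage(table, config, outdir)
        return outputs

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    def stage_guard(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"stage={name} failed: {err}") from err

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    base = dict(config.sim_overrides)
    disc = stage_guard("simulate", simulate_cohort,
                       SimConfig(n_subjects=config.n_discovery, seed=seeds[0], **base))
    repl = stage_guard("simulate", simulate_cohort,
                       SimConfig(n_subjects=config.n_replication, seed=seeds[1], **base))
    outc = stage_guard("simulate", simulate_cohort,
                       SimConfig(n_subjects=config.n_outcome, seed=seeds[2], **base))
    if config.write_cohorts:
        for name, c in (("discovery", disc), ("replication", repl), ("outcome", outc)):
            write_cohort(c, outdir / f"cohort_{name}")
    _stage("simulate", t0, "-",
           f"{disc.n_subjects}+{repl.n_subjects}+{outc.n_subjects}", config.seed)

    # --- exposure GWAS and instrument selection -----------------------------
    t0 = time.time()
    scan_d = stage_guard("gwas", gwas.snp_exposure_scan, disc, config.exposure_covariates)
    after_maf = gwas.maf_filter(scan_d, config.maf_threshold)
    after_sig = gwas.significance_filter(after_maf, config.gwas_alpha)
    clumped = gwas.ld_clump(after_sig, disc.dosages, config.clump_r2,
                            config.clump_window_kb)
    scan_r = stage_guard("gwas", gwas.snp_exposure_scan, repl, config.exposure_covariates)
    replicated = gwas.discovery_replication(clumped, scan_r)
    table = stage_guard("gwas", gwas.pooled_reestimate, [disc, repl],
                        list(replicated["id"]), config.exposure_covariates)
    scan_d.to_csv(outdir / "scan_discovery.tsv", sep="\t", index=False)
    replicated.to_csv(outdir / "instruments_selected.tsv", sep="\t", index=False)
    log.info("funnel: scanned=%d maf=%d significant=%d clumped=%d replicated=%d",
             len(scan_d), len(after_maf), len(after_sig), len(clumped), len(replicated))
    _stage("gwas", t0, len(scan_d), len(table), config.seed)
    outputs["r2"] = gwas.variance_explained(disc, list(replicated["id"]),
                                            config.exposure_covariates)

    # --- outcome scan -------------------------------------------------------
    t0 = time.time()
    ids = table.ids
    sub_outc = outc
    scan_ov = stage_guard("outcome", hazards.snp_outcome_scan, sub_outc,
                          config.outcome_covariates, "overall")
    scan_cs = stage_guard("outcome", hazards.snp_outcome_scan, sub_outc,
                          config.outcome_covariates, hazards.CAUSE_OF_INTEREST)
    scan_ov = scan_ov[scan_ov["id"].isin(ids)]
    scan_cs = scan_cs[scan_cs["id"].isin(ids)]
    table = attach_outcomes(table, scan_ov, scan_cs)
    pd.merge(scan_ov, scan_cs, on="id", suffixes=("_overall", "_cause")).to_csv(
        outdir / "outcome_scan.tsv", sep="\t", index=False)
    _stage("outcome", t0, len(ids), len(scan_ov), config.seed)
    outputs["instruments"] = table

    # --- MR -----------------------------------------------------------------
    outputs["mr"] = _mr_stage(table, config, outdir)

    # --- subgroup -----------------------------------------------------------
    if config.subgroup_column:
        t0 = time.time()
        col = outc.covariates[config.subgroup_column]
        frames = []
        for level in sorted(col.unique()):
            mask = (col == level).to_numpy()
            from .simulate import CohortData
            stratum = CohortData(
                dosages=outc.dosages[mask].reset_index(drop=True),
                covariates=outc.covariates[mask].reset_index(drop=True),
                exposure=outc.exposure[mask].reset_index(drop=True),
                survival=outc.survival[mask].reset_index(drop=True),
                variants=outc.variants)
            cov = [c for c in config.outcome_covariates if c != config.subgroup_column]
            s_ov = hazards.snp_outcome_scan(stratum, cov, "overall")
            s_cs = hazards.snp_outcome_scan(stratum, cov, hazards.CAUSE_OF_INTEREST)
            t_sub = attach_outcomes(table, s_ov[s_ov["id"].isin(ids)],
                                    s_cs[s_cs["id"].isin(ids)])
            rows = mr.mr_summary(t_sub, exclusions=[()], n_boot=config.n_boot,
                                 seed=config.seed, model=config.variance_model)
            df = pd.DataFrame(rows)
            df.insert(0, "subgroup", f"{config.subgroup_column}={level}")
            frames.append(df)
        sub_df = pd.concat(frames, ignore_index=True)
        sub_df.to_csv(outdir / "mr_subgroups.tsv", sep="\t", index=False)
        outputs["mr_subgroups"] = sub_df
        _stage("subgroup", t0, len(col), len(sub_df), config.seed)

    # --- GRS ----------------------------------------------------------------
    t0 = time.time()
    weights = {r.variant.id: r.exposure.beta for r in table}
    score = grs_mod.compute_grs(outc.dosages[ids], weights)
    fit_sd, fit_q = grs_mod.grs_survival(score, outc.survival, outc.covariates,
                                         config.outcome_covariates)
    grs_rows = fit_sd.summary().head(1).assign(analysis="per_sd")
    q_rows = fit_q.summary().head(4).assign(analysis="quintile_vs_q3")
    pd.concat([grs_rows, q_rows], ignore_index=True).to_csv(
        outdir / "grs_estimates.tsv", sep="\t", index=False)
    outputs["grs"] = (fit_sd, fit_q)
    _stage("grs", t0, outc.n_subjects, 5, config.seed)

    # --- power --------------------------------------------------------------
    if config.run_power:
        t0 = time.time()
        scenario = PowerScenario(n=config.n_outcome, seed=seeds[3])
        analytic = analytic_binary_power(dataclasses.replace(scenario, effect=1.5))
        simulated = simulate_survival_power(scenario)
        pd.DataFrame([
            {"mode": "analytic_binary", "power": analytic.power, "mc_se": 0.0},
            {"mode": "simulate_additive_hazards", "power": simulated.power,
             "mc_se": simulated.mc_se},
        ]).to_csv(outdir / "power.tsv", sep="\t", index=False)
        outputs["power"] = simulated
        _stage("power", t0, scenario.n_reps, 2, seeds[3])

    return outputs


def plot_instruments(table: InstrumentTable, outcome: str, path: str | Path,
                     model: str = "multiplicative_random") -> None:
    """Scatter of per-SNP outcome HD against exposure beta (oriented), with
    the fitted IVW (through the origin) and Egger lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    oriented = mr.orient(table, outcome)
    bx = np.array([o.bx for o in oriented])
    by = np.array([o.by for o in oriented])
    se = np.array([o.se_by for o in oriented])
    est_ivw = mr.ivw(oriented, model=model)
    slope, intercept = mr.egger(oriented, model=model)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(bx, by, yerr=1.96 * se, fmt="o", ms=4, lw=1, capsize=2)
    xs = np.linspace(0, bx.max() * 1.1, 50)
    ax.plot(xs, est_ivw.estimate * xs, label=f"IVW ({est_ivw.estimate:.2f})")
    ax.plot(xs, intercept.estimate + slope.estimate * xs, "--",
            label=f"Egger (int {intercept.estimate:.2f})")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("SNP effect on log2-CRP (per allele)")
    ax.set_ylabel("SNP effect on mortality (HD / 1,000 PY)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
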