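"""Exposure GWAS scan, instrument filtering, clumping and strength statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from conftest import brute_force_clump
from crpmr.datamodel import ValidationError
from crpmr.gwas import (
    ReplicationRule,
    discovery_replication,
    f_statistic,
    f_statistic_r2,
    ld_clump,
    maf_filter,
    pooled_reestimate,
    significance_filter,
    snp_exposure_scan,
    variance_explained,
)
from crpmr.simulate import CohortData, SimConfig, simulate_cohort


def _scan_frame(ps, eafs=None, chroms=None, poss=None, betas=None):
    k = len(ps)
    return pd.DataFrame({
        "id": [f"v{i}" for i in range(k)],
        "chrom": chroms or ["1"] * k,
        "pos": poss or list(range(0, 1000 * k, 1000)),
        "ea": "A", "ra": "G",
        "eaf": eafs if eafs is not None else [0.3] * k,
        "beta": betas if betas is not None else [0.1] * k,
        "se": 0.01, "p": ps, "n": 1000,
    })


class TestScan:
    def test_recovers_generating_betas(self, big_cohort):
        scan = snp_exposure_scan(big_cohort, ["age", "sex"])
        truth = dict(zip(big_cohort.config.variant_ids, big_cohort.config.snp_effects))
        for _, row in scan.iterrows():
            assert abs(row["beta"] - truth[row["id"]]) < 3 * row["se"]

    def test_strongest_instrument_matches_fixture_scale(self, big_cohort):
        scan = snp_exposure_scan(big_cohort, ["age", "sex"]).set_index("id")
        assert scan.loc["rs2794520", "beta"] == pytest.approx(0.247, abs=0.02)

    def test_null_exposure_gives_uniform_p_values(self):
        rng = np.random.default_rng(31)
        n, k = 2000, 300
        g = rng.binomial(2, 0.3, size=(n, k)).astype(float)
        ids = [f"n{j}" for j in range(k)]
        cohort = CohortData(
            dosages=pd.DataFrame(g, columns=ids),
            covariates=pd.DataFrame({"age": rng.normal(57, 8, n)}),
            exposure=pd.Series(rng.standard_normal(n)),
            survival=pd.DataFrame({"time": np.ones(n), "event": 0, "cause": None}),
            variants=pd.DataFrame({"id": ids, "chrom": "1", "pos": range(k),
                                   "ea": "A", "ra": "G", "eaf": 0.3}),
        )
        scan = snp_exposure_scan(cohort)
        assert kstest(scan["p"], "uniform").pvalue > 0.01

    def test_orthogonalized_covariate_leaves_beta_unchanged(self):
        rng = np.random.default_rng(33)
        n = 500
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        x = 0.3 * g[:, 0] + rng.standard_normal(n)
        raw_cov = rng.standard_normal(n)
        design = np.column_stack([np.ones(n), g[:, 0]])
        coef, *_ = np.linalg.lstsq(design, raw_cov, rcond=None)
        ortho = raw_cov - design @ coef  # orthogonal to dosage and intercept
        base = CohortData(
            dosages=pd.DataFrame(g, columns=["v0"]),
            covariates=pd.DataFrame({"c": ortho}),
            exposure=pd.Series(x),
            survival=pd.DataFrame({"time": np.ones(n), "event": 0, "cause": None}),
            variants=pd.DataFrame({"id": ["v0"], "chrom": "1", "pos": [1],
                                   "ea": "A", "ra": "G", "eaf": 0.4}),
        )
        beta_plain = snp_exposure_scan(base)["beta"][0]
        beta_adj = snp_exposure_scan(base, ["c"])["beta"][0]
        assert beta_adj == pytest.approx(beta_plain, abs=1e-6)

    def test_beta_equivariance_under_exposure_scaling(self):
        c = simulate_cohort(SimConfig(n_subjects=2000, seed=35))
        doubled = CohortData(dosages=c.dosages, covariates=c.covariates,
                             exposure=2.0 * c.exposure, survival=c.survival,
                             variants=c.variants)
        a = snp_exposure_scan(c)
        b = snp_exposure_scan(doubled)
        np.testing.assert_allclose(b["beta"], 2 * a["beta"], rtol=1e-10)
        np.testing.assert_allclose(b["se"], 2 * a["se"], rtol=1e-10)
        np.testing.assert_allclose(b["p"], a["p"], rtol=1e-8)


class TestFilters:
    @pytest.mark.parametrize("eaf, kept", [(0.096, True), (0.03, False),
                                           (0.97, False), (0.05, True)])
    def test_maf_filter_boundaries(self, eaf, kept):
        scan = _scan_frame([1e-10], eafs=[eaf])
        assert (len(maf_filter(scan, 0.05)) == 1) is kept

    def test_significance_strict_inequality(self):
        scan = _scan_frame([5e-8, 7.23e-200, 1e-7])
        out = significance_filter(scan, 5e-8)
        assert list(out["id"]) == ["v1"]

    def test_filters_commute(self):
        scan = _scan_frame([1e-10, 5e-8, 1e-9, 0.5],
                           eafs=[0.3, 0.2, 0.02, 0.4])
        a = maf_filter(significance_filter(scan, 5e-8), 0.05)
        b = significance_filter(maf_filter(scan, 0.05), 5e-8)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_scan_passes_through(self):
        empty = _scan_frame([])
        assert len(significance_filter(empty, 5e-8)) == 0


class TestClumping:
    def test_single_variant_kept(self):
        scan = _scan_frame([1e-9])
        g = pd.DataFrame({"v0": np.random.default_rng(0).binomial(2, 0.3, 500)})
        assert list(ld_clump(scan, g)["id"]) == ["v0"]

    def test_perfect_ld_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(41)
        g0 = rng.binomial(2, 0.3, 2000).astype(float)
        g = pd.DataFrame({"v0": g0, "v1": g0})  # r^2 = 1
        scan = _scan_frame([1e-8, 1e-12])
        out = ld_clump(scan, g)
        assert list(out["id"]) == ["v1"]

    def test_window_limits_comparisons(self):
        rng = np.random.default_rng(43)
        g0 = rng.binomial(2, 0.3, 2000).astype(float)
        g = pd.DataFrame({"v0": g0, "v1": g0})
        scan = _scan_frame([1e-8, 1e-12], poss=[0, 20_000_000_000])
        assert len(ld_clump(scan, g, window_kb=10_000)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_ld_blocks(self, seed):
        from crpmr.simulate import simulate_genotypes
        rng = np.random.default_rng(seed)
        k = 20
        g = simulate_genotypes(3000, rng.uniform(0.1, 0.5, k), ld_rho=0.6,
                               ld_blocks=[5, 5, 5, 5], seed=seed)
        gdf = pd.DataFrame(g, columns=[f"v{i}" for i in range(k)])
        chroms = ["1"] * 10 + ["2"] * 10
        poss = list(range(0, 10 * 500_000, 500_000)) * 2
        scan = _scan_frame(list(rng.uniform(1e-12, 1e-6, k)),
                           chroms=chroms, poss=poss)
        ours = sorted(ld_clump(scan, gdf, r2_threshold=0.05)["id"])
        oracle = brute_force_clump(scan, gdf, r2_threshold=0.05, window_kb=10_000)
        assert ours == oracle

    def test_retained_set_mutually_below_threshold(self):
        from crpmr.simulate import simulate_genotypes
        g = simulate_genotypes(3000, [0.3] * 10, ld_rho=0.5, seed=47)
        gdf = pd.DataFrame(g, columns=[f"v{i}" for i in range(10)])
        scan = _scan_frame(list(np.random.default_rng(47).uniform(0, 1e-8, 10)),
                           poss=list(range(0, 10_000, 1000)))
        out = ld_clump(scan, gdf, r2_threshold=0.05)
        kept = list(out["id"])
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                r = np.corrcoef(gdf[a], gdf[b])[0, 1]
                assert r * r < 0.05

    def test_missing_genotypes_error(self):
        scan = _scan_frame([1e-9])
        with pytest.raises(ValidationError, match="v0"):
            ld_clump(scan, pd.DataFrame({"other": [0, 1, 2]}))


class TestDiscoveryReplication:
    def test_true_signals_replicate(self):
        # 13 candidates, 7 with strong replication support
        disc = _scan_frame([1e-10] * 13)
        repl = disc.copy()
        repl.loc[7:, "beta"] = 0.0001
        repl.loc[7:, "p"] = 0.9
        repl.loc[:6, "p"] = 1e-6
        out = discovery_replication(disc, repl)
        assert list(out["id"]) == [f"v{i}" for i in range(7)]

    def test_opposite_direction_excluded_despite_small_p(self):
        disc = _scan_frame([1e-10])
        repl = disc.copy()
        repl["beta"] = -0.1
        repl["p"] = 1e-10
        assert len(discovery_replication(disc, repl)) == 0

    def test_vacuous_rule_retains_all(self):
        disc = _scan_frame([1e-10, 1e-9])
        repl = disc.copy()
        repl["p"] = 0.99
        repl["beta"] = [-0.1, 0.1]
        rule = ReplicationRule(alpha=1.0, require_direction=False)
        assert len(discovery_replication(disc, repl, rule)) == 2

    def test_candidate_absent_from_replication_warned_and_excluded(self):
        disc = _scan_frame([1e-10, 1e-9])
        repl = _scan_frame([1e-6]).assign(id=["v0"])
        with pytest.warns(UserWarning, match="v1"):
            out = discovery_replication(disc, repl, ReplicationRule(alpha=1.0))
        assert list(out["id"]) == ["v0"]


class TestPooledReestimate:
    def test_duplicated_cohort_shrinks_se(self):
        c = simulate_cohort(SimConfig(n_subjects=3000, seed=51))
        single = snp_exposure_scan(c).set_index("id")
        pooled = pooled_reestimate([c, c], list(c.dosages.columns)).to_dataframe()
        pooled = pooled.set_index("id")
        for vid in single.index:
            assert pooled.loc[vid, "se_x"] == pytest.approx(
                single.loc[vid, "se"] / np.sqrt(2), rel=0.02)
            assert pooled.loc[vid, "beta_x"] == pytest.approx(
                single.loc[vid, "beta"], rel=1e-9)

    def test_pooled_beta_between_cohort_betas(self):
        a = simulate_cohort(SimConfig(n_subjects=4000, seed=52))
        b = simulate_cohort(SimConfig(n_subjects=4000, seed=53))
        sa = snp_exposure_scan(a).set_index("id")["beta"]
        sb = snp_exposure_scan(b).set_index("id")["beta"]
        pooled = pooled_reestimate([a, b], list(a.dosages.columns)).to_dataframe()
        for _, row in pooled.iterrows():
            lo, hi = sorted([sa[row["id"]], sb[row["id"]]])
            assert lo - 1e-9 <= row["beta_x"] <= hi + 1e-9

    def test_empty_instrument_list_gives_empty_table(self):
        c = simulate_cohort(SimConfig(n_subjects=500, seed=54))
        assert len(pooled_reestimate([c], [])) == 0


class TestVcfIngestion:
    HEADER = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
    )

    def test_gt_fields_become_alt_dosages(self, tmp_path):
        from crpmr.gwas import dosages_from_vcf
        path = tmp_path / "g.vcf"
        path.write_text(
            self.HEADER
            + "1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            + "1\t200\trsB\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n")
        df = dosages_from_vcf(str(path))
        np.testing.assert_allclose(df["rsA"], [0.0, 1.0, 2.0])
        assert df["rsB"][0] == 1.0 and np.isnan(df["rsB"][1])

    def test_multiallelic_record_rejected(self, tmp_path):
        from crpmr.gwas import dosages_from_vcf
        path = tmp_path / "m.vcf"
        path.write_text(
            self.HEADER
            + "1\t100\trsA\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/1\n")
        with pytest.raises(ValidationError, match="multiallelic"):
            dosages_from_vcf(str(path))


class TestInstrumentStrength:
    def test_wald_f(self):
        assert f_statistic(0.1, 0.05) == pytest.approx(4.0)
        assert f_statistic(0.0, 0.3) == 0.0

    def test_weakest_fixture_instrument_f_in_plausible_band(self, table1):
        rec = table1.get("rs71086917")
        x = rec.exposure
        f = f_statistic(x.beta, x.se_or_recovered())
        assert 60 <= f <= 70

    def test_r2_based_convention(self):
        # F = (n-2) R^2 / (1-R^2)
        assert f_statistic_r2(0.5, 4) == pytest.approx(2.0)

    def test_variance_explained_hits_target(self, big_cohort):
        r2 = variance_explained(big_cohort, covariates=["age", "sex"])
        assert 0.035 <= r2 <= 0.045

    def test_exact_linear_exposure_gives_unit_r2(self):
        c = simulate_cohort(SimConfig(n_subjects=1000, seed=55))
        exact = CohortData(dosages=c.dosages, covariates=c.covariates,
                           exposure=pd.Series(c.dosages.to_numpy() @
                                              np.arange(1.0, 8.0)),
                           survival=c.survival, variants=c.variants)
        assert variance_explained(exact) == pytest.approx(1.0, abs=1e-10)

    def test_null_r2_near_k_over_n(self):
        c = simulate_cohort(SimConfig(n_subjects=2000, seed=56))
        null = CohortData(dosages=c.dosages, covariates=c.covariates,
                          exposure=pd.Series(
                              np.random.default_rng(56).standard_normal(2000)),
                          survival=c.survival, variants=c.variants)
        r2 = variance_explained(null)
        assert r2 < 3 * 7 / 2000

    def test_more_predictors_than_subjects_rejected(self):
        c = simulate_cohort(SimConfig(n_subjects=5, seed=57))
        with pytest.raises(ValidationError):
            variance_explained(c)
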