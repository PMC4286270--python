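"""Per-SNP fits, joint test, lambda, thresholds, and the genome scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwis import (
    CHI2_2DF_MEDIAN,
    GenotypePanel,
    SimConfig,
    UntestableSNP,
    bonferroni_threshold,
    build_design,
    compute_maf,
    fit_snp,
    genome_scan,
    joint_test,
    lambda_gc,
    simulate_cohort,
)

STAT_COLS = [
    "beta_main", "se_main", "beta_int", "se_int", "cov_main_int",
    "p_main", "p_int", "chi2_joint", "p_joint",
]


class TestComputeMaf:
    @pytest.mark.parametrize(
        "dosages, expected",
        [([0, 0, 0], 0.0), ([0, 1, 2, 1], 0.5), ([0, 0, 0, 1], 0.125),
         ([2, 2, 2, 1], 0.125)],
    )
    def test_forced_arithmetic(self, dosages, expected):
        assert compute_maf(dosages) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_maf([0, 1, 2.5])

    def test_missing_ignored(self):
        assert compute_maf([0, 1, np.nan, 1]) == pytest.approx(1 / 3)


class TestFitSnp:
    def test_noiseless_fit_recovers_coefficients_exactly(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        truth = np.array([1.0, -2.0, 0.5, 3.0])
        res = fit_snp(X @ truth, X, main_index=2, int_index=3)
        assert res["rss"] == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(res["beta"], truth, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        y = rng.normal(size=20)
        res = fit_snp(y, X, main_index=2, int_index=3)
        # independent oracle: explicit normal equations
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        rss = float((y - X @ beta) @ (y - X @ beta))
        cov = rss / (20 - 4) * XtX_inv
        np.testing.assert_allclose(res["beta"], beta, atol=1e-8)
        assert res["se_main"] == pytest.approx(np.sqrt(cov[2, 2]), abs=1e-8)
        assert res["se_int"] == pytest.approx(np.sqrt(cov[3, 3]), abs=1e-8)
        assert res["cov_main_int"] == pytest.approx(cov[2, 3], abs=1e-8)

    def test_matches_statsmodels_on_realistic_design(self, small_sim):
        sm = pytest.importorskip("statsmodels.api")
        y = small_sim.cohort["annual_decline"].to_numpy()
        X, _ = build_design(small_sim.cohort, small_sim.panel.dosages[:, 5])
        res = fit_snp(y, X)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res["beta"], ols.params, rtol=1e-8)
        np.testing.assert_allclose(
            res["se_int"], np.sqrt(ols.cov_params()[-1, -1]), rtol=1e-8
        )

    def test_constant_dosage_flagged_untestable(self, rng):
        X = np.column_stack(
            [np.ones(30), rng.normal(size=30), np.full(30, 1.0), rng.normal(size=30)]
        )
        with pytest.raises(UntestableSNP):
            fit_snp(rng.normal(size=30), X, main_index=2, int_index=3)

    def test_t_reference_larger_p_than_normal(self, rng):
        X = np.column_stack([np.ones(15), rng.normal(size=(15, 2))])
        y = rng.normal(size=15)
        pn = fit_snp(y, X, main_index=1, int_index=2)["p_int"]
        pt = fit_snp(y, X, main_index=1, int_index=2, use_t=True)["p_int"]
        assert pt > pn


class TestJointTest:
    def test_null_point(self):
        chi2, p = joint_test(0.0, 0.0, np.eye(2))
        assert chi2 == 0.0 and p == 1.0

    def test_diagonal_covariance_reduces_to_sum_of_z_squares(self):
        V = np.diag([0.04, 0.25])
        chi2, _ = joint_test(0.4, 1.0, V)
        assert chi2 == pytest.approx((0.4 / 0.2) ** 2 + (1.0 / 0.5) ** 2)

    def test_correlated_covariance_matches_matrix_inversion_oracle(self):
        V = np.array([[0.04, 0.015], [0.015, 0.09]])
        b = np.array([0.3, -0.2])
        chi2, p = joint_test(b[0], b[1], V)
        oracle = float(b @ np.linalg.inv(V) @ b)
        assert chi2 == pytest.approx(oracle, abs=1e-10)
        assert p == pytest.approx(float(stats.chi2.sf(oracle, 2)), abs=1e-12)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            joint_test(0.1, 0.1, np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValueError):
            joint_test(0.1, 0.1, np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestLambdaGc:
    def test_values_at_null_median_give_unity(self):
        assert lambda_gc(np.full(101, CHI2_2DF_MEDIAN)) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_scale_equivariance(self, rng):
        v = rng.chisquare(2, size=1001)
        assert lambda_gc(2 * v) == pytest.approx(2 * lambda_gc(v))

    def test_monte_carlo_null_draws_near_unity(self, rng):
        v = rng.chisquare(2, size=100_001)
        assert 0.98 <= lambda_gc(v) <= 1.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc([])


class TestBonferroni:
    def test_discovery_threshold_for_one_million_tests(self):
        assert bonferroni_threshold(0.05, 1_000_000) == pytest.approx(
            5e-8, rel=1e-12
        )

    def test_replication_threshold_for_two_tests(self):
        assert bonferroni_threshold(0.05, 2) == 0.025

    def test_single_test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestGenomeScan:
    def test_streaming_engine_equals_naive_per_snp_fit(self, planted_sim):
        fast, _ = genome_scan(planted_sim.panel, planted_sim.cohort, engine="fast")
        naive, _ = genome_scan(planted_sim.panel, planted_sim.cohort, engine="naive")
        for col in STAT_COLS:
            np.testing.assert_allclose(
                fast[col], naive[col], atol=1e-8, rtol=1e-8, err_msg=col
            )

    def test_planted_interaction_is_top_ranked(self, planted_sim):
        res, summary = genome_scan(planted_sim.panel, planted_sim.cohort)
        assert res.loc[res["snp_id"] == "snp000005", "rank_int"].iloc[0] == 1
        assert set(summary.hits["snp_id"]) <= set(
            res.loc[res["p_int"] < summary.genomewide_alpha, "snp_id"]
        )

    def test_subject_permutation_invariance(self, planted_sim):
        res, _ = genome_scan(planted_sim.panel, planted_sim.cohort)
        perm = np.random.default_rng(1).permutation(planted_sim.panel.n_subjects)
        panel = GenotypePanel(
            planted_sim.panel.dosages[perm], planted_sim.panel.snp_meta.copy()
        )
        cohort = planted_sim.cohort.iloc[perm].reset_index(drop=True)
        res_p, _ = genome_scan(panel, cohort)
        for col in STAT_COLS:
            np.testing.assert_allclose(res[col], res_p[col], atol=1e-9)

    def test_allele_flip_changes_sign_not_significance(self, planted_sim):
        res, _ = genome_scan(planted_sim.panel, planted_sim.cohort)
        dos = planted_sim.panel.dosages.copy()
        dos[:, 5] = 2 - dos[:, 5]
        meta = planted_sim.panel.snp_meta.copy()
        meta["maf"] = np.minimum(dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2)
        flipped, _ = genome_scan(GenotypePanel(dos, meta), planted_sim.cohort)
        row, frow = res.iloc[5], flipped.iloc[5]
        assert frow["beta_main"] == pytest.approx(-row["beta_main"], abs=1e-9)
        assert frow["beta_int"] == pytest.approx(-row["beta_int"], abs=1e-9)
        assert frow["p_int"] == pytest.approx(row["p_int"], abs=1e-9)
        assert frow["p_joint"] == pytest.approx(row["p_joint"], abs=1e-9)

    def test_single_snp_scan_has_rank_one(self, planted_sim):
        panel = GenotypePanel(
            planted_sim.panel.dosages[:, [5]],
            planted_sim.panel.snp_meta.iloc[[5]].reset_index(drop=True),
        )
        res, _ = genome_scan(panel, planted_sim.cohort)
        assert res[["rank_main", "rank_int", "rank_joint"]].iloc[0].tolist() == [
            1.0, 1.0, 1.0,
        ]

    def test_maf_filter_excludes_rare_variants(self, small_sim):
        res, summary = genome_scan(small_sim.panel, small_sim.cohort,
                                   maf_floor=0.2)
        assert (res["maf"] >= 0.2).all()
        assert summary.n_filtered_maf == (
            small_sim.panel.snp_meta["maf"] < 0.2
        ).sum()

    def test_no_surviving_snps_is_an_error(self):
        config = SimConfig(n_subjects=200, n_snps=8, block_size=4,
                           maf_min=0.05, maf_max=0.15, seed=67)
        sim = simulate_cohort(config)
        with pytest.raises(ValueError, match="MAF filter"):
            genome_scan(sim.panel, sim.cohort, maf_floor=0.4)

    def test_ranks_are_permutations(self, small_sim):
        res, _ = genome_scan(small_sim.panel, small_sim.cohort)
        tested = res[~res["untestable"]]
        m = len(tested)
        for col in ("rank_main", "rank_int", "rank_joint"):
            assert sorted(tested[col]) == list(range(1, m + 1))

    def test_missing_dosages_complete_case_per_snp(self, small_sim):
        dos = small_sim.panel.dosages.copy()
        drop = np.random.default_rng(3).choice(len(dos), size=20, replace=False)
        dos[drop, 7] = np.nan
        meta = small_sim.panel.snp_meta.copy()
        f = np.nanmean(dos, axis=0) / 2
        meta["maf"] = np.minimum(f, 1 - f)
        res, _ = genome_scan(GenotypePanel(dos, meta), small_sim.cohort)
        assert res.loc[7, "n_used"] == len(dos) - 20
        # other SNPs keep the full sample
        assert res.loc[6, "n_used"] == len(dos)

    def test_row_misalignment_rejected(self, small_sim):
        with pytest.raises(ValueError, match="row-aligned"):
            genome_scan(small_sim.panel, small_sim.cohort.iloc[:-1])
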