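"""Candidate selection, replication, sensitivity models, stratified slopes."""

import numpy as np
import pandas as pd
import pytest

from gwis import (
    GenotypePanel,
    SimConfig,
    genome_scan,
    pool_samples,
    replicate,
    select_candidates,
    sensitivity_suite,
    simulate_cohort,
    stratified_analysis,
)
from gwis.simulate import build_haplotype_pools
from gwis.two_stage import CI_MULTIPLIER


def _planted(seed, n=800, beta_int=0.25, pools=None, **kw):
    config = SimConfig(n_subjects=n, n_snps=24, block_size=8,
                       haplotype_pool_size=8, causal_index=4,
                       beta_int_true=beta_int, maf_min=0.15, seed=seed, **kw)
    return simulate_cohort(config, pools=pools)


class TestSelectCandidates:
    def test_single_significant_snp_selected_alone(self, planted_sim):
        res, _ = genome_scan(planted_sim.panel, planted_sim.cohort)
        cands = select_candidates(res, planted_sim.panel)
        assert cands[0] == "snp000005"

    def test_top_snp_always_returned_even_without_hits(self, small_sim):
        res, _ = genome_scan(small_sim.panel, small_sim.cohort)
        cands = select_candidates(res, small_sim.panel)
        top = res.sort_values(["p_int", "chrom", "pos"]).iloc[0]["snp_id"]
        assert cands == [top]

    def test_perfectly_correlated_duplicate_is_pruned(self, planted_sim):
        # duplicate the hit column: r2 = 1 with the leader -> pruned
        dos = np.column_stack(
            [planted_sim.panel.dosages, planted_sim.panel.dosages[:, 5]]
        )
        meta = planted_sim.panel.snp_meta.copy()
        dup = meta.iloc[5].copy()
        dup["snp_id"], dup["pos"] = "snp_dup", int(meta["pos"].max()) + 1
        meta = pd.concat([meta, dup.to_frame().T], ignore_index=True)
        f = dos.mean(axis=0) / 2
        meta["maf"] = np.minimum(f, 1 - f)
        meta["pos"] = meta["pos"].astype(int)
        panel = GenotypePanel(dos, meta)
        res, _ = genome_scan(panel, planted_sim.cohort)
        cands = select_candidates(res, panel, r2_ceiling=0.95)
        assert len([c for c in cands if c in ("snp000005", "snp_dup")]) == 1


class TestReplicate:
    def test_confidence_interval_uses_normal_multiplier(self, planted_sim):
        table = replicate(["snp000005"], planted_sim.panel, planted_sim.cohort)
        row = table.iloc[0]
        assert row["ci_low"] == pytest.approx(
            row["coefficient"] - CI_MULTIPLIER * row["se"], abs=1e-12
        )
        assert row["ci_high"] == pytest.approx(
            row["coefficient"] + CI_MULTIPLIER * row["se"], abs=1e-12
        )

    def test_reported_interval_arithmetic_matches_published_convention(self):
        # a coefficient of 0.0742 with SE 0.0281 must print CI (0.0191, 0.1293)
        lo, hi = 0.0742 - 1.96 * 0.0281, 0.0742 + 1.96 * 0.0281
        assert lo == pytest.approx(0.0191, abs=5e-5)
        assert hi == pytest.approx(0.1293, abs=5e-5)

    def test_bonferroni_pass_flag_for_two_tests(self, planted_sim):
        table = replicate(
            ["snp000005", "snp000006"], planted_sim.panel, planted_sim.cohort,
            k=2, alpha=0.05,
        )
        for _, row in table.iterrows():
            assert row["passed"] == (row["p_int"] < 0.025)

    def test_missing_candidate_error_names_snp(self, planted_sim):
        with pytest.raises(KeyError, match="snp999999"):
            replicate(["snp999999"], planted_sim.panel, planted_sim.cohort)

    def test_discovery_refit_reproduces_scan_statistics(self, planted_sim):
        res, _ = genome_scan(planted_sim.panel, planted_sim.cohort)
        table = replicate(["snp000005"], planted_sim.panel, planted_sim.cohort)
        row = res[res["snp_id"] == "snp000005"].iloc[0]
        assert table.iloc[0]["coefficient"] == pytest.approx(
            row["beta_int"], abs=1e-9
        )
        assert table.iloc[0]["p_int"] == pytest.approx(row["p_int"], abs=1e-9)

    def test_null_replication_pass_rate_calibrated(self):
        # candidates tested in null cohorts pass at ~alpha/k
        passes, reps = 0, 400
        base = SimConfig(n_subjects=150, n_snps=4, block_size=4,
                         haplotype_pool_size=8, maf_min=0.3, seed=0)
        pools = build_haplotype_pools(base)
        for r in range(reps):
            config = SimConfig(n_subjects=150, n_snps=4, block_size=4,
                               haplotype_pool_size=8, maf_min=0.3,
                               seed=60_000 + r)
            sim = simulate_cohort(config, pools=pools)
            table = replicate(["snp000001"], sim.panel, sim.cohort,
                              k=2, alpha=0.05, use_t=True)
            passes += int(table.iloc[0]["passed"])
        rate = passes / reps
        sd = np.sqrt(0.025 * 0.975 / reps)
        assert abs(rate - 0.025) <= 3 * sd


class TestSensitivitySuite:
    def test_no_confounding_noiseless_variants_agree(self):
        # generating effects only on covariates shared by both variants
        config = SimConfig(
            n_subjects=500, n_snps=8, block_size=8, haplotype_pool_size=8,
            causal_index=2, beta_main_true=0.5, beta_int_true=0.1,
            maf_min=0.2, noise_sd=0.0, seed=71,
            covariate_effects={"intercept": -30.0, "age": -0.5,
                               "cumulative_exposure": -0.05},
        )
        sim = simulate_cohort(config)
        table = sensitivity_suite(
            ["snp000002"], sim.panel, sim.cohort, variants=["full", "minimal"]
        )
        coefs = table["coefficient"].to_numpy()
        assert coefs[0] == pytest.approx(coefs[1], abs=1e-6)
        assert coefs[0] == pytest.approx(0.1, abs=1e-6)

    def test_omitting_a_planted_confounder_shifts_coefficient(self):
        # plant a confounder of the interaction term: weight change tracks
        # dosage x exposure, and weight change has a negative effect on
        # decline, so omitting it biases beta_int downward by a known amount
        from gwis.simulate import simulate_phenotype

        config = SimConfig(n_subjects=2000, n_snps=8, block_size=8,
                           haplotype_pool_size=8, causal_index=2,
                           beta_int_true=0.1, maf_min=0.3, noise_sd=5.0,
                           seed=73)
        sim = simulate_cohort(config)
        cohort = sim.cohort.copy()
        g = sim.panel.dosages[:, 2]
        ge = g * cohort["cumulative_exposure"].to_numpy()
        cohort["weight_change"] = (
            cohort["weight_change"] + 0.05 * (ge - ge.mean())
        )
        cohort["annual_decline"] = simulate_phenotype(
            sim.panel, cohort, config
        )
        full = replicate(["snp000002"], sim.panel, cohort,
                         model_variant="full")
        dropped = replicate(["snp000002"], sim.panel, cohort,
                            model_variant="no_weight_change")
        # omitted-variable bias: gamma_wc * 0.05 = -0.8 * 0.05 = -0.04
        assert (
            dropped.iloc[0]["coefficient"]
            < full.iloc[0]["coefficient"] - 0.02
        )
        assert full.iloc[0]["coefficient"] == pytest.approx(0.1, abs=0.02)

    def test_unknown_variant_label_rejected(self, planted_sim):
        with pytest.raises(ValueError, match="unknown model variant"):
            sensitivity_suite(["snp000005"], planted_sim.panel,
                              planted_sim.cohort, variants=["bogus"])

    def test_output_order_follows_variant_list(self, planted_sim):
        variants = ["minimal", "full", "age_squared"]
        table = sensitivity_suite(["snp000005"], planted_sim.panel,
                                  planted_sim.cohort, variants=variants)
        assert table["variant"].tolist() == variants


class TestStratified:
    def test_strata_partition_analyzed_subjects(self, planted_sim):
        table = stratified_analysis("snp000005", planted_sim.panel,
                                    planted_sim.cohort)
        assert table["n"].sum() == planted_sim.panel.n_subjects

    def test_all_major_homozygotes_flags_empty_carrier_stratum(self, small_sim):
        dos = np.zeros_like(small_sim.panel.dosages)
        meta = small_sim.panel.snp_meta.copy()
        meta["maf"] = 0.0
        panel = GenotypePanel(dos, meta)
        table = stratified_analysis("snp000000", panel, small_sim.cohort)
        carrier = table[table["stratum"] == "minor_allele_carrier"].iloc[0]
        assert carrier["n"] == 0 and carrier["empty"]
        assert np.isnan(carrier["exposure_slope"])

    def test_positive_interaction_makes_major_slope_lower(self):
        # with beta_int > 0 the exposure effect concentrates in the
        # major-homozygote stratum (slope below the carriers')
        wins = 0
        for r in range(25):
            sim = _planted(80_000 + r, n=800, beta_int=0.2)
            table = stratified_analysis("snp000004", sim.panel, sim.cohort)
            major = table.set_index("stratum").loc["major_homozygote"]
            carrier = table.set_index("stratum").loc["minor_allele_carrier"]
            wins += int(major["exposure_slope"] < carrier["exposure_slope"])
        assert wins >= 23  # >= 90% of replicates

    def test_null_slopes_agree_within_two_pooled_ses(self):
        inside = 0
        reps = 20
        for r in range(reps):
            sim = _planted(90_000 + r, n=600, beta_int=0.0)
            table = stratified_analysis("snp000004", sim.panel, sim.cohort)
            t = table.set_index("stratum")
            se = {
                s: (t.loc[s, "ci_high"] - t.loc[s, "ci_low"]) / (2 * CI_MULTIPLIER)
                for s in ("major_homozygote", "minor_allele_carrier")
            }
            diff = abs(
                t.loc["major_homozygote", "exposure_slope"]
                - t.loc["minor_allele_carrier", "exposure_slope"]
            )
            pooled = np.hypot(se["major_homozygote"], se["minor_allele_carrier"])
            inside += int(diff < 2 * pooled)
        assert inside >= 0.95 * reps

    def test_pooled_samples_carry_indicator(self, planted_sim):
        pools = planted_sim.pools
        config2 = SimConfig(n_subjects=200, n_snps=40, block_size=8,
                            haplotype_pool_size=8, causal_index=5,
                            beta_int_true=0.3, maf_min=0.15, seed=18)
        rep = simulate_cohort(config2, pools=pools, id_prefix="R")
        panel, cohort = pool_samples([planted_sim.panel, rep.panel],
                                     [planted_sim.cohort, rep.cohort])
        assert len(cohort) == planted_sim.panel.n_subjects + 200
        assert set(cohort["sample_indicator"]) == {0.0, 1.0}
        table = stratified_analysis(
            "snp000005", panel, cohort,
            extra_covariates=("sample_indicator",),
        )
        assert table["n"].sum() == len(cohort)
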