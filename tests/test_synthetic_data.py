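import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiprs.genotype_qc import hwe_exact_test, hwe_pvalues
from epiprs.synthetic_data import (ArtifactSpec, SimulationConfig,
                                   _draw_population, inject_qc_artifacts,
                                   simulate_annotations, simulate_cohort,
                                   simulate_summary_stats, simulate_trios,
                                   simulate_true_effects)


class TestTrueEffects:
    def test_zero_heritability_gives_zero_effects(self, cfg_small):
        cfg = dataclasses.replace(cfg_small, h2_liability=0.0)
        eff = simulate_true_effects(cfg)
        assert np.all(eff.a == 0)

    def test_effect_variance_sums_to_h2(self, cfg_small):
        for h2 in (0.1, 0.3, 0.8):
            cfg = dataclasses.replace(cfg_small, h2_liability=h2, m_snps=1000)
            eff = simulate_true_effects(cfg)
            total = np.sum(2 * eff.p * (1 - eff.p) * eff.a**2)
            assert total == pytest.approx(h2, abs=1e-6)

    def test_determinism_and_seed_sensitivity(self, cfg_small):
        a = simulate_true_effects(cfg_small)
        b = simulate_true_effects(cfg_small)
        np.testing.assert_array_equal(a.a, b.a)
        np.testing.assert_array_equal(a.p, b.p)
        c = simulate_true_effects(dataclasses.replace(cfg_small, seed=43))
        assert not np.array_equal(a.a, c.a)

    def test_maf_range_respected(self, cfg_small):
        eff = simulate_true_effects(cfg_small)
        lo, hi = cfg_small.maf_range
        assert np.all((eff.p >= lo) & (eff.p <= hi))


class TestSummaryStats:
    def test_se_formula_and_monotonicity(self, effects, cfg_small):
        ss = simulate_summary_stats(effects, 5000, seed=1)
        expected_se = 1 / np.sqrt(2 * effects.p * (1 - effects.p) * 5000)
        np.testing.assert_allclose(ss["se"], expected_se)
        # rarer SNP => larger se
        order = np.argsort(np.minimum(effects.p, 1 - effects.p))
        assert ss["se"].to_numpy()[order[0]] >= ss["se"].to_numpy()[order[-1]]

    def test_large_discovery_recovers_true_effects(self, effects):
        ss = simulate_summary_stats(effects, 10_000_000, seed=2)
        np.testing.assert_allclose(ss["beta"], effects.a, atol=0.01)

    def test_null_pvalues_uniform_at_5pct(self):
        cfg = SimulationConfig(m_snps=10_000, h2_liability=0.0, seed=9)
        eff = simulate_true_effects(cfg)
        ss = simulate_summary_stats(eff, 5000, seed=9)
        frac = (ss["p"] < 0.05).mean()
        # binomial 99.9% band around 0.05 for 10,000 draws
        assert abs(frac - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / 10_000)


class TestCohort:
    def test_requested_counts_and_labels(self, cohort, cfg_small):
        g, samples = cohort
        assert (samples["phenotype"] == "case").sum() == cfg_small.n_cases
        assert (samples["phenotype"] == "control").sum() == cfg_small.n_controls
        assert g.n_samples == len(samples)
        # screen status: positive/negative only for cases, unknown for controls
        cases = samples[samples["phenotype"] == "case"]
        ctrls = samples[samples["phenotype"] == "control"]
        assert set(cases["screen_status"]) <= {"positive", "negative"}
        assert set(ctrls["screen_status"]) == {"unknown"}
        assert (cases["screen_status"] == "positive").equals(cases["carrier"])

    def test_no_major_variant_means_no_screen_positives(self, effects, cfg_small):
        cfg = dataclasses.replace(cfg_small, gamma_major=0.0, carrier_freq=0.0)
        _, samples = simulate_cohort(effects, cfg)
        assert (samples["screen_status"] == "positive").sum() == 0

    def test_determinism(self, effects, cfg_small):
        g1, s1 = simulate_cohort(effects, cfg_small)
        g2, s2 = simulate_cohort(effects, cfg_small)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(s1, s2)

    def test_unascertained_prevalence_matches_k(self, effects, cfg_small):
        cfg = dataclasses.replace(cfg_small, prevalence_k=0.01,
                                  gamma_major=0.0, carrier_freq=0.0)
        rng = np.random.default_rng(5)
        _, _, _, case = _draw_population(rng, effects, cfg, 100_000)
        frac = case.mean()
        assert abs(frac - 0.01) < 4 * np.sqrt(0.01 * 0.99 / 100_000)

    def test_liability_variance_includes_major_effect(self, effects, cfg_small):
        cfg = dataclasses.replace(cfg_small, gamma_major=3.0, carrier_freq=0.05)
        rng = np.random.default_rng(6)
        _, _, liability, _ = _draw_population(rng, effects, cfg, 100_000)
        expected = 1 + cfg.gamma_major**2 * cfg.carrier_freq * (1 - cfg.carrier_freq)
        assert liability.var() == pytest.approx(expected, rel=0.03)

    def test_infeasible_ascertainment_raises(self, effects, cfg_small):
        from epiprs import synthetic_data as sd
        cfg = dataclasses.replace(cfg_small, prevalence_k=1e-4, n_cases=10**6)
        old = sd._MAX_BATCHES
        sd._MAX_BATCHES = 3
        try:
            with pytest.raises(RuntimeError, match="batches"):
                simulate_cohort(effects, cfg)
        finally:
            sd._MAX_BATCHES = old

    def test_hwe_holds_in_unascertained_genotypes(self):
        # exact-test p-values approximately uniform over many SNPs
        cfg = SimulationConfig(m_snps=1500, seed=17)
        eff = simulate_true_effects(cfg)
        rng = np.random.default_rng(17)
        g = rng.binomial(2, eff.p, size=(800, cfg.m_snps))
        pvals = np.array([
            hwe_exact_test(int((g[:, j] == 0).sum()), int((g[:, j] == 1).sum()),
                           int((g[:, j] == 2).sum()))
            for j in range(cfg.m_snps)])
        # exact-test p-values are discrete and conservative: stochastically
        # larger than uniform; one-sided KS (above the uniform CDF) must pass
        d_plus = stats.ks_1samp(pvals, stats.uniform.cdf,
                                alternative="greater").statistic
        assert d_plus < stats.ksone.isf(0.01, cfg.m_snps)


class TestTrios:
    def test_mendelian_transmission_bounds(self, effects, cfg_small):
        g, samples, trios = simulate_trios(effects, cfg_small)
        idx = {s: i for i, s in enumerate(g.sample_ids)}
        for _, t in trios.iterrows():
            fa = g.dosages[idx[t["father_id"]]]
            mo = g.dosages[idx[t["mother_id"]]]
            ch = g.dosages[idx[t["child_id"]]]
            lower = (fa == 2).astype(float) + (mo == 2).astype(float)
            upper = 2 - (fa == 0).astype(float) - (mo == 0).astype(float)
            assert np.all(ch >= lower) and np.all(ch <= upper)

    def test_unascertained_transmission_is_symmetric(self, effects, cfg_small):
        cfg = dataclasses.replace(cfg_small, n_trios=2000, ascertain_trios=False)
        g, samples, trios = simulate_trios(effects, cfg)
        score = pd.Series(g.dosages @ effects.a, index=g.sample_ids)
        idx = trios
        dev = (score.loc[idx["child_id"]].to_numpy()
               - (score.loc[idx["father_id"]].to_numpy()
                  + score.loc[idx["mother_id"]].to_numpy()) / 2)
        se = dev.std(ddof=1) / np.sqrt(len(dev))
        assert abs(dev.mean()) < 4 * se

    def test_ascertained_children_overtransmit_polygenic_score(self, effects, cfg_small):
        cfg = dataclasses.replace(cfg_small, n_trios=2000, gamma_major=0.0,
                                  carrier_freq=0.0)
        g, samples, trios = simulate_trios(effects, cfg)
        score = pd.Series(g.dosages @ effects.a, index=g.sample_ids)
        dev = (score.loc[trios["child_id"]].to_numpy()
               - (score.loc[trios["father_id"]].to_numpy()
                  + score.loc[trios["mother_id"]].to_numpy()) / 2)
        assert dev.mean() > 4 * dev.std(ddof=1) / np.sqrt(len(dev))
        assert set(samples.loc[samples["id"].isin(trios["child_id"]),
                               "phenotype"]) == {"case"}

    def test_determinism(self, effects, cfg_small):
        g1, s1, t1 = simulate_trios(effects, cfg_small)
        g2, s2, t2 = simulate_trios(effects, cfg_small)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(t1, t2)


class TestAnnotations:
    def test_carriers_get_exactly_one_qualifying_record(self, cohort, cfg_small):
        _, samples = cohort
        snvs, cnvs, truth = simulate_annotations(samples, cfg_small)
        n_cases = (samples["phenotype"] == "case").sum()
        assert len(truth) == n_cases
        carriers = samples.loc[samples["carrier"] & (samples["phenotype"] == "case"),
                               "id"]
        pos = truth[truth["status"] == "positive"]
        assert set(pos["case_id"]) == set(carriers)
        # one record per case across the two tables
        per_case = pd.concat([snvs["case_id"], cnvs["case_id"]]).value_counts()
        assert (per_case == 1).all()

    def test_decoys_violate_exactly_one_rule(self, cohort, cfg_small):
        from epiprs.variant_screen import cnv_failed_rules, snv_failed_rules
        _, samples = cohort
        snvs, cnvs, truth = simulate_annotations(samples, cfg_small)
        decoys = truth[truth["status"] == "negative"]
        snv_by_case = snvs.set_index("case_id")
        for _, d in decoys.iterrows():
            if d["decoy_rule"] == "cnv_short_no_overlap":
                rec = cnvs.set_index("case_id").loc[d["case_id"]]
                assert len(cnv_failed_rules(rec)) == 3  # no OR clause satisfied
            else:
                rec = snv_by_case.loc[d["case_id"]]
                assert len(snv_failed_rules(rec)) == 1


class TestArtifacts:
    def test_zero_rates_leave_matrix_unchanged(self, cohort):
        g, _ = cohort
        degraded, flags = inject_qc_artifacts(g, ArtifactSpec())
        np.testing.assert_array_equal(degraded.dosages, g.dosages)
        assert all(len(v) == 0 for v in flags.values())

    def test_hwe_artifact_fails_exact_test(self, cohort):
        g, _ = cohort
        degraded, flags = inject_qc_artifacts(
            g, ArtifactSpec(frac_hwe_violating_variants=0.05, seed=3))
        cols = degraded.variants["id"].tolist()
        for vid in flags["variants_hwe"]:
            j = cols.index(vid)
            c0, c1, c2 = (int((np.rint(degraded.dosages[:, j]) == k).sum())
                          for k in (0, 1, 2))
            assert hwe_exact_test(c0, c1, c2) < 1e-5

    def test_missingness_artifact_lowers_call_rate(self, cohort):
        g, _ = cohort
        spec = ArtifactSpec(frac_missing_variants=0.05, missing_rate=0.03, seed=4)
        degraded, flags = inject_qc_artifacts(g, spec)
        cols = degraded.variants["id"].tolist()
        cr = degraded.call_rate()
        for vid in flags["variants_missing"]:
            assert cr[cols.index(vid)] < 1.0
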