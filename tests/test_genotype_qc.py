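from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from epiprs.genotype_qc import (QCThresholds, compute_pcs, filter_samples,
                                filter_variants, flag_pc_outliers,
                                hwe_exact_test, ld_prune)
from epiprs.io_formats import GenotypeMatrix
from epiprs.synthetic_data import ArtifactSpec, inject_qc_artifacts


def hwe_enumeration_oracle(n_hom_a: int, n_het: int, n_hom_b: int) -> Fraction:
    """Exact-rational HWE p: integer weights w(h) = 2^h n! / (nAA! h! nBB!)
    share a common denominator, so the p-value is a ratio of integer sums."""
    n = n_hom_a + n_het + n_hom_b
    n_a, n_b = 2 * n_hom_a + n_het, 2 * n_hom_b + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return Fraction(1)
    ws = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        ws[h] = (2**h) * factorial(n) // (
            factorial(hom_rare) * factorial(h) * factorial(hom_common))
    w_obs = ws[n_het]
    return Fraction(sum(w for w in ws.values() if w <= w_obs), sum(ws.values()))


def _matrix(dosages, ids=None, info=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "id": ids or [f"v{j}" for j in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1) * 1000,
        "a1": "A", "a2": "G"})
    if info is not None:
        variants["info"] = info
    return GenotypeMatrix(sample_ids=[f"S{i}" for i in range(n)],
                          variants=variants, dosages=dosages)


class TestHWEExactTest:
    def test_modal_configuration_gives_p_one(self):
        # 25/50/25 is the most probable heterozygote configuration
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_against_enumeration_oracle_spot_checks(self):
        for counts in [(57, 14, 50), (3, 4, 5), (0, 10, 0), (20, 1, 20),
                       (7, 0, 7), (1, 2, 47)]:
            expected = float(hwe_enumeration_oracle(*counts))
            assert abs(hwe_exact_test(*counts) - expected) < 1e-12

    def test_extreme_het_excess_is_significant(self):
        assert hwe_exact_test(0, 100, 0) < 1e-5

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 5)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestFilterVariants:
    def test_clean_matrix_untouched(self, cohort):
        g, _ = cohort
        out, report = filter_variants(g)
        assert out.n_variants == g.n_variants
        assert report.n_removed == 0

    def test_rules_remove_targeted_variants_in_order(self):
        rng = np.random.default_rng(0)
        n = 300
        clean = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        low_cr = rng.binomial(2, 0.3, size=n).astype(float)
        low_cr[: int(0.03 * n)] = np.nan  # call rate 0.97
        low_maf = np.zeros(n)
        low_maf[:3] = 1.0  # maf 0.005
        hwe_bad = np.ones(n)  # all heterozygous
        g = _matrix(np.column_stack([clean[:, 0], low_cr, low_maf, hwe_bad,
                                     clean[:, 1]]),
                    ids=["ok1", "cr", "maf", "hwe", "ok2"],
                    info=[1.0, 1.0, 1.0, 1.0, 0.5])
        out, report = filter_variants(g)
        assert report.removed["call_rate"] == ["cr"]
        assert report.removed["maf"] == ["maf"]
        assert report.removed["hwe"] == ["hwe"]
        assert report.removed["info"] == ["ok2"]  # INFO 0.5 < 0.9
        assert out.variants["id"].tolist() == ["ok1"]

    def test_first_matching_rule_wins(self):
        # a variant failing both call rate and MAF is attributed to call rate
        col = np.zeros(200)
        col[:10] = np.nan
        g = _matrix(col[:, None], ids=["both"])
        _, report = filter_variants(g)
        assert report.removed["call_rate"] == ["both"]
        assert report.removed["maf"] == []

    def test_idempotence_and_conservation(self, cohort):
        g, _ = cohort
        degraded, _ = inject_qc_artifacts(
            g, ArtifactSpec(frac_missing_variants=0.1, missing_rate=0.05,
                            frac_low_maf_variants=0.1,
                            frac_hwe_violating_variants=0.1, seed=5))
        once, rep1 = filter_variants(degraded)
        twice, rep2 = filter_variants(once)
        assert rep2.n_removed == 0
        assert once.variants["id"].tolist() == twice.variants["id"].tolist()
        assert rep1.n_removed + len(rep1.retained) == degraded.n_variants

    def test_all_removed_warns_not_raises(self):
        g = _matrix(np.ones((100, 2)))  # all-het: HWE fails... but MAF=0.5 ok
        with pytest.warns(UserWarning, match="all variants removed"):
            out, _ = filter_variants(g)
        assert out.n_variants == 0


class TestFilterSamples:
    def test_low_call_rate_sample_removed(self, cohort):
        g, _ = cohort
        degraded, flags = inject_qc_artifacts(
            g, ArtifactSpec(frac_missing_samples=0.02, seed=6))
        out, report = filter_samples(degraded)
        assert set(report.removed["call_rate"]) == set(flags["samples_missing"])

    def test_het_outlier_removed(self, cohort):
        g, _ = cohort
        degraded, flags = inject_qc_artifacts(
            g, ArtifactSpec(frac_het_outlier_samples=0.01, seed=7))
        out, report = filter_samples(degraded)
        assert set(flags["samples_het_outlier"]) <= set(report.removed["heterozygosity"])

    def test_identical_samples_degenerate_sd_guard(self):
        g = _matrix(np.tile([0.0, 1.0, 2.0], (5, 1)))
        out, report = filter_samples(g)
        assert report.removed["heterozygosity"] == []
        assert out.n_samples == 5

    def test_too_few_samples_skips_het_step(self):
        g = _matrix(np.array([[0.0, 1.0], [1.0, 2.0]]))
        with pytest.warns(UserWarning, match="fewer than 3"):
            _, report = filter_samples(g)
        assert report.removed["heterozygosity"] == []


class TestLDPrune:
    def test_unlinked_snps_all_retained(self, cohort):
        g, _ = cohort
        kept = ld_prune(g, window_snps=50, step=5, r2_max=0.2)
        assert kept == g.variants["id"].tolist()

    def test_duplicated_column_one_removed(self, rng):
        base = rng.binomial(2, 0.4, size=200).astype(float)
        other = rng.binomial(2, 0.4, size=200).astype(float)
        g = _matrix(np.column_stack([base, base, other]), ids=["a", "b", "c"])
        kept = ld_prune(g, window_snps=10, step=1, r2_max=0.1)
        assert "c" in kept
        assert sum(v in kept for v in ("a", "b")) == 1

    def test_three_mutually_correlated_one_retained(self, rng):
        base = rng.binomial(2, 0.4, size=500).astype(float)
        g = _matrix(np.column_stack([base, base, base]), ids=["a", "b", "c"])
        kept = ld_prune(g, window_snps=10, step=1, r2_max=0.1)
        # brute-force all-pairs check: no retained pair with r2 > threshold
        assert len(kept) == 1
        idx = [g.variants["id"].tolist().index(v) for v in kept]
        for i in idx:
            for j in idx:
                if i < j:
                    r = np.corrcoef(g.dosages[:, i], g.dosages[:, j])[0, 1]
                    assert r * r <= 0.1

    def test_lower_maf_member_removed(self, rng):
        common = rng.binomial(2, 0.5, size=2000).astype(float)
        # rarer proxy: perfect copy with some hom-alt set to het (lowers MAF)
        rare = common.copy()
        rare[rare == 2] = 1.0
        g = _matrix(np.column_stack([common, rare]), ids=["common", "rare"])
        r2 = np.corrcoef(common, rare)[0, 1] ** 2
        assert r2 > 0.5
        kept = ld_prune(g, window_snps=10, step=1, r2_max=0.5)
        assert kept == ["common"]


class TestPCA:
    def test_two_populations_separate_on_pc1(self, rng):
        m = 150
        p1 = rng.uniform(0.1, 0.5, size=m)
        p2 = np.clip(p1 + rng.choice([-0.25, 0.25], size=m), 0.02, 0.98)
        g1 = rng.binomial(2, p1, size=(60, m)).astype(float)
        g2 = rng.binomial(2, p2, size=(60, m)).astype(float)
        g = _matrix(np.vstack([g1, g2]))
        pcs = compute_pcs(g, 2)
        a, b = pcs["pc1"].iloc[:60], pcs["pc1"].iloc[60:]
        within = max(a.std(), b.std())
        assert abs(a.mean() - b.mean()) > 3 * within

    def test_orthogonality(self, cohort):
        g, _ = cohort
        pcs = compute_pcs(g, 4).to_numpy()
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_identical_samples_rank_zero(self):
        g = _matrix(np.tile([0.0, 1.0, 2.0, 1.0], (6, 1)))
        with pytest.warns(UserWarning):
            pcs = compute_pcs(g, 2)
        assert pcs.shape[1] == 0

    def test_npcs_beyond_rank_truncated(self, rng):
        g = _matrix(rng.binomial(2, 0.4, size=(4, 30)).astype(float))
        with pytest.warns(UserWarning, match="rank"):
            pcs = compute_pcs(g, 4)
        assert pcs.shape[1] <= 3  # rank <= n_samples - 1 after centering

    def test_sign_convention_largest_loading_positive(self, cohort):
        g, _ = cohort
        pcs = compute_pcs(g, 3)
        for col in pcs.columns:
            v = pcs[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestPCOutliers:
    def test_homogeneous_cohort_no_outliers(self, rng):
        pcs = pd.DataFrame({"pc1": rng.normal(size=100),
                            "pc2": rng.normal(size=100)},
                           index=[f"S{i}" for i in range(100)])
        assert flag_pc_outliers(pcs) == []

    def test_displaced_sample_flagged(self, rng):
        v = rng.normal(size=100)
        med, mad = np.median(v), np.median(np.abs(v - np.median(v)))
        v[0] = med + 10 * 1.4826 * mad
        pcs = pd.DataFrame({"pc1": v, "pc2": rng.normal(size=100)},
                           index=[f"S{i}" for i in range(100)])
        assert flag_pc_outliers(pcs, sd_limit=6) == ["S0"]

    def test_threshold_nesting(self, rng):
        pcs = pd.DataFrame({"pc1": rng.standard_cauchy(size=200),
                            "pc2": rng.normal(size=200)},
                           index=[f"S{i}" for i in range(200)])
        loose = set(flag_pc_outliers(pcs, sd_limit=8))
        tight = set(flag_pc_outliers(pcs, sd_limit=6))
        assert loose <= tight

    def test_zero_mad_flags_nothing(self):
        pcs = pd.DataFrame({"pc1": [0.0] * 10, "pc2": [1.0] * 10},
                           index=[f"S{i}" for i in range(10)])
        assert flag_pc_outliers(pcs) == []
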