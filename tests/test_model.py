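"""Weighted-least-squares engine: stratum weights, fits, joint tests,
scan behaviour and diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

import gwis


def _toy_cohort(n, seed=0, sd_ratio=1.0, beta_int=0.0, beta_snp=0.0, maf=0.3):
    cfg = gwis.kare_config(n_samples=n, maf_vector=np.array([maf]),
                           sigma_nonsmoker=4.0, sigma_smoker=4.0 * sd_ratio,
                           beta_snp=beta_snp, beta_int=beta_int, seed=seed)
    cohort = gwis.simulate_cohort(cfg)
    genotypes = gwis.simulate_genotypes(cfg)
    cohort = gwis.simulate_phenotype(cohort, genotypes, 0, cfg)
    return cohort, genotypes


class TestStratumWeights:
    def test_hand_dataset_matches_per_stratum_ols_variances(self):
        cohort = pd.DataFrame({
            "sample_id": list("abcdefghijklmnop"),
            "fev1_fvc": [82.0, 78.5, 90.0, 74.0, 80.0, 69.0, 77.0, 85.0,
                         81.0, 76.0, 88.0, 72.5, 79.0, 83.0, 70.5, 86.0],
            "age": [45, 50, 55, 60, 48, 52, 58, 62, 47, 51, 56, 61, 49, 53, 59, 63],
            "sex": [0, 1, 0, 1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0],
            "bmi": [22, 25, 27, 23, 24, 26, 21, 28, 23, 22, 26, 25, 27, 21, 24, 29],
            "smoking_status": ["never"] * 8 + ["current"] * 8,
            "pack_years": [0.0] * 8 + [10, 25, 5, 40, 15, 30, 8, 20],
            "stratum": ["nonsmoker"] * 8 + ["smoker"] * 8,
        })
        w = gwis.estimate_stratum_weights(cohort)
        for label, rows in (("nonsmoker", slice(0, 8)), ("smoker", slice(8, 16))):
            sub = cohort.iloc[rows]
            cols = ["age", "sex", "bmi"]
            x = sub[cols].to_numpy(float)
            x = np.column_stack([np.ones(len(sub)), x, x[:, 0] * x[:, 1]])
            if label == "smoker":
                x = np.column_stack([x, sub["pack_years"].to_numpy(float)])
            fit = sm.OLS(sub["fev1_fvc"].to_numpy(), x).fit()
            expected = fit.ssr / fit.df_resid
            got = getattr(w, f"sigma2_{label}")
            assert got == pytest.approx(expected, rel=1e-10)
        assert w.weights.loc["a"] == pytest.approx(1 / w.sigma2_nonsmoker)
        assert w.weights.loc["p"] == pytest.approx(1 / w.sigma2_smoker)

    def test_variance_ratio_recovery(self):
        cohort, _ = _toy_cohort(30_000, seed=1, sd_ratio=2.0)
        w = gwis.estimate_stratum_weights(cohort)
        assert w.variance_ratio == pytest.approx(4.0, rel=0.1)

    def test_small_stratum_errors_with_name(self):
        cohort, _ = _toy_cohort(400, seed=2)
        tiny = pd.concat([cohort[cohort["stratum"] == "nonsmoker"],
                          cohort[cohort["stratum"] == "smoker"].head(3)])
        with pytest.raises(ValueError, match="smoker"):
            gwis.estimate_stratum_weights(tiny.reset_index(drop=True))


class TestWeightedFit:
    def test_equal_weights_reduce_to_ols(self):
        cohort, genotypes = _toy_cohort(300, seed=3)
        x = gwis.build_design(cohort, dosage=genotypes.dosages[:, 0])
        y = cohort["fev1_fvc"].to_numpy()
        ours = gwis.fit_weighted_model(y, x, np.full(len(y), 1.0))
        ref = sm.OLS(y, x.to_numpy()).fit()
        np.testing.assert_allclose(ours.params, ref.params, rtol=1e-10)
        np.testing.assert_allclose(ours.bse, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(ours.pvalues, ref.pvalues, rtol=1e-8, atol=1e-300)

    def test_weight_rescaling_leaves_inference_unchanged(self):
        cohort, genotypes = _toy_cohort(250, seed=4, sd_ratio=2.0)
        x = gwis.build_design(cohort, dosage=genotypes.dosages[:, 0])
        y = cohort["fev1_fvc"].to_numpy()
        w = gwis.estimate_stratum_weights(cohort).weights.loc[
            cohort["sample_id"]].to_numpy()
        a = gwis.fit_weighted_model(y, x, w)
        b = gwis.fit_weighted_model(y, x, 7.3 * w)
        np.testing.assert_allclose(a.params, b.params, rtol=1e-10)
        np.testing.assert_allclose(a.bse, b.bse, rtol=1e-10)
        null_a = gwis.fit_weighted_model(y, x.drop(columns=["snp", "snp_py"]), w)
        null_b = gwis.fit_weighted_model(y, x.drop(columns=["snp", "snp_py"]), 7.3 * w)
        ja = gwis.joint_test(a, null_a)
        jb = gwis.joint_test(b, null_b)
        assert ja.lr_stat == pytest.approx(jb.lr_stat, rel=1e-10)

    def test_matches_brute_force_minimizer_of_weighted_rss(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"const": 1.0, "z": rng.normal(size=8),
                          "g": rng.integers(0, 3, 8).astype(float)})
        y = rng.normal(size=8)
        w = np.repeat([0.5, 2.0], 4)
        ours = gwis.fit_weighted_model(y, x, w)

        def wrss(beta):
            r = y - x.to_numpy() @ beta
            return float((w * r**2).sum())

        res = optimize.minimize(wrss, np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000})
        np.testing.assert_allclose(ours.params, res.x, atol=1e-6)
        assert ours.wrss == pytest.approx(res.fun, rel=1e-10)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            gwis.fit_weighted_model(np.zeros(3), np.ones((3, 1)), np.array([1, 0, 1]))


class TestJointTest:
    def test_zero_extra_columns_give_zero_statistic_and_p_one(self):
        cohort, _ = _toy_cohort(120, seed=6)
        x = gwis.build_design(cohort)
        y = cohort["fev1_fvc"].to_numpy()
        w = np.ones(len(y))
        null = gwis.fit_weighted_model(y, x, w)
        x_aug = x.copy()
        x_aug["snp"] = 0.0
        x_aug["snp_py"] = 0.0
        with pytest.warns(UserWarning, match="rank deficient"):
            full = gwis.fit_weighted_model(y, x_aug, w)
        jt = gwis.joint_test(full, null)
        assert jt.statistic == pytest.approx(0.0, abs=1e-10)
        assert jt.p_value == pytest.approx(1.0)

    def test_nesting_violation_detected(self):
        cohort, genotypes = _toy_cohort(100, seed=7)
        x = gwis.build_design(cohort, dosage=genotypes.dosages[:, 0])
        y = cohort["fev1_fvc"].to_numpy()
        w = np.ones(len(y))
        full = gwis.fit_weighted_model(y, x, w)
        null = gwis.fit_weighted_model(y, x.drop(columns=["snp", "snp_py"]), w)
        with pytest.raises(ValueError, match="nesting"):
            gwis.joint_test(null, full)  # reversed roles

    def test_lr_and_f_pvalues_agree_at_large_n(self):
        cohort, genotypes = _toy_cohort(2000, seed=8, sd_ratio=2.0,
                                        beta_snp=0.4, beta_int=-0.01)
        w = gwis.estimate_stratum_weights(cohort)
        rec = gwis.scan_genome(cohort, genotypes, None, w).iloc[0]
        lg_lr = -np.log10(rec["p_joint_lr"])
        lg_f = -np.log10(rec["p_joint_f"])
        assert lg_lr == pytest.approx(lg_f, rel=0.10)


class TestScan:
    def test_permutation_of_samples_leaves_records_unchanged(self):
        cohort, genotypes = _toy_cohort(300, seed=9, sd_ratio=1.5)
        w = gwis.estimate_stratum_weights(cohort)
        base = gwis.scan_genome(cohort, genotypes, None, w)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort))
        cohort_p = cohort.iloc[perm].reset_index(drop=True)
        base_p = gwis.scan_genome(cohort_p, genotypes, None, w)
        for col in ["beta_snp", "se_snp", "p_snp", "beta_int", "p_int", "p_lr"]:
            np.testing.assert_allclose(base_p[col], base[col], rtol=1e-8)

    def test_monomorphic_variant_flagged_non_estimable(self):
        cohort, genotypes = _toy_cohort(200, seed=10)
        genotypes.dosages[:, 0] = 2.0
        w = gwis.estimate_stratum_weights(cohort)
        rec = gwis.scan_genome(cohort, genotypes, None, w)
        assert not rec.loc[0, "estimable"]
        assert np.isnan(rec.loc[0, "p_lr"])

    def test_missing_dosages_use_per_snp_complete_case(self):
        cohort, genotypes = _toy_cohort(400, seed=11)
        genotypes.dosages[:25, 0] = np.nan
        w = gwis.estimate_stratum_weights(cohort)
        rec = gwis.scan_genome(cohort, genotypes, None, w)
        assert rec.loc[0, "n_used"] == 375
        # oracle: explicit WLS on the complete-case rows
        use = ~np.isnan(genotypes.dosages[:, 0])
        sub = cohort[use].reset_index(drop=True)
        x = gwis.build_design(sub, dosage=genotypes.dosages[use, 0])
        wt = w.weights.loc[sub["sample_id"]].to_numpy()
        ref = sm.WLS(sub["fev1_fvc"].to_numpy(), x.to_numpy(), weights=wt).fit()
        assert rec.loc[0, "beta_snp"] == pytest.approx(ref.params[-2], rel=1e-8)
        assert rec.loc[0, "p_snp"] == pytest.approx(ref.pvalues[-2], rel=1e-6)

    def test_null_scan_rarely_reaches_genome_wide_significance(self):
        cfg = gwis.kare_config(n_samples=600, maf_vector=np.linspace(0.1, 0.5, 2000),
                               sigma_nonsmoker=4.0, sigma_smoker=6.0, seed=12)
        cohort = gwis.simulate_phenotype(gwis.simulate_cohort(cfg), None, None, cfg)
        genotypes = gwis.simulate_genotypes(cfg)
        w = gwis.estimate_stratum_weights(cohort)
        rec = gwis.scan_genome(cohort, genotypes, None, w)
        assert rec["significant"].sum() == 0

    def test_power_2df_beats_main_effect_test_under_pure_interaction(self):
        # with beta_snp = 0 and beta_int != 0, the joint test should reject
        # more often than the SNP-main-effect Wald test
        alpha = 0.05
        hits_joint = hits_main = 0
        reps = 40
        for r in range(reps):
            cohort, genotypes = _toy_cohort(1200, seed=100 + r,
                                            beta_snp=0.0, beta_int=-0.03)
            w = gwis.estimate_stratum_weights(cohort)
            rec = gwis.scan_genome(cohort, genotypes, None, w).iloc[0]
            hits_joint += rec["p_lr"] < alpha
            hits_main += rec["p_snp"] < alpha
        assert hits_joint > hits_main


class TestDiagnostics:
    def test_lambda_near_one_for_uniform_pvalues(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=50_000)
        assert gwis.genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_halving_pvalues_inflates_lambda(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=10_000)
        assert gwis.genomic_inflation(p / 2) > gwis.genomic_inflation(p)

    def test_fixed_list_matches_direct_median_ratio(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0.01, 1.0, size=101)
        expected = np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1)
        with pytest.warns(UserWarning):
            got = gwis.genomic_inflation(p[:99])
        assert gwis.genomic_inflation(p) == pytest.approx(expected, rel=1e-12)
        assert got > 0

    def test_aic_prefers_weighted_under_heteroscedasticity(self):
        cohort, genotypes = _toy_cohort(2000, seed=16, sd_ratio=2.0)
        x = gwis.build_design(cohort, dosage=genotypes.dosages[:, 0])
        y = cohort["fev1_fvc"].to_numpy()
        w = gwis.estimate_stratum_weights(cohort).weights.loc[
            cohort["sample_id"]].to_numpy()
        weighted = gwis.fit_weighted_model(y, x, w)
        unweighted = gwis.fit_weighted_model(y, x, np.ones(len(y)))
        delta, preferred = gwis.aic_compare(weighted, unweighted)
        assert preferred == "weighted"
        assert delta > 0

    def test_identical_weights_give_zero_aic_difference(self):
        cohort, genotypes = _toy_cohort(300, seed=17)
        x = gwis.build_design(cohort, dosage=genotypes.dosages[:, 0])
        y = cohort["fev1_fvc"].to_numpy()
        w = np.full(len(y), 2.0)
        delta, _ = gwis.aic_compare(gwis.fit_weighted_model(y, x, w),
                                    gwis.fit_weighted_model(y, x, w))
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_qq_manhattan_tables(self):
        records = pd.DataFrame({
            "id": [f"v{i}" for i in range(5)],
            "chrom": [1, 1, 1, 2, 2],
            "pos": [100, 200, 300, 50, 150],
            "p_lr": [0.5, 0.01, 0.2, 0.9, 0.05],
        })
        out = gwis.qq_manhattan_export(records)
        qq = out["qq"]
        assert len(qq) == 5
        np.testing.assert_allclose(
            qq["expected"], -np.log10((np.arange(1, 6) - 0.5) / 5))
        assert (np.diff(qq["observed"]) <= 1e-12).all()
        man = out["manhattan"]
        # chromosome 1 spans 300, so chromosome 2 is offset by 300
        assert man.loc[man["id"] == "v3", "cumulative_pos"].item() == 350
        assert man.loc[man["id"] == "v0", "cumulative_pos"].item() == 100
        assert out["genomewide_line"] == 5e-8

    def test_single_chromosome_cumulative_equals_position(self):
        records = pd.DataFrame({
            "id": ["a", "b"], "chrom": [3, 3], "pos": [10, 99],
            "p_lr": [0.4, 0.6]})
        man = gwis.qq_manhattan_export(records)["manhattan"]
        np.testing.assert_array_equal(man["cumulative_pos"], man["pos"])
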