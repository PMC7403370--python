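"""End-to-end synthetic experiments built from the library primitives.

These are the canonical study-scale pipelines: a global-null
heteroscedastic genome scan for calibration diagnostics, marginal
calibration of the default discovery-style cohort, and replicate-level
recovery of SNP main and interaction effects. They exist so that scripts,
examples and tests all exercise the identical code path.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import model, popstruct, qc, simulate

__all__ = [
    "null_calibration_scan",
    "kare_marginals",
    "recovery_experiment",
]


def null_calibration_scan(n_samples: int = 2000, n_variants: int = 20000,
                          sd_ratio: float = 2.0, seed: int = 0,
                          n_pcs: int = 10, maf_low: float = 0.1,
                          maf_high: float = 0.5) -> dict:
    """Global-null heteroscedastic scan: QC, PCs, weights, 2-df tests.

    Simulates a discovery-style cohort with ``sigma_smoker = sd_ratio *
    sigma_nonsmoker`` and zero SNP effects, runs variant QC, computes the
    GRM-derived PCs, estimates stratum weights, scans every variant and
    returns the records plus the genomic inflation factor of the joint-test
    p-values.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_variants)
    cfg = simulate.kare_config(
        n_samples=n_samples, maf_vector=maf, ld_rho=0.0,
        beta_snp=0.0, beta_int=0.0,
        sigma_nonsmoker=4.0, sigma_smoker=4.0 * sd_ratio,
        seed=int(rng.integers(2**31)),
    )
    cohort = simulate.simulate_cohort(cfg)
    genotypes = simulate.simulate_genotypes(cfg)
    cohort = simulate.simulate_phenotype(cohort, None, None, cfg)
    cohort = qc.eligibility_filter(cohort)
    genotypes = genotypes.take_samples(
        pd.Index(genotypes.sample_ids).get_indexer(cohort["sample_id"]))
    genotypes, vreport = qc.apply_variant_qc(genotypes)
    pcs = None
    if n_pcs:
        grm = popstruct.compute_grm(genotypes)
        pcs = popstruct.compute_pcs(grm, k=n_pcs)
    weights = model.estimate_stratum_weights(cohort, pcs)
    records = model.scan_genome(cohort, genotypes, pcs, weights, flavor="lr")
    ok = records["p_lr"].notna()
    lam = model.genomic_inflation(records.loc[ok, "p_lr"])
    return {
        "records": records, "lambda": lam, "weights": weights,
        "qc_report": vreport, "n_samples": len(cohort),
        "n_variants_tested": int(ok.sum()), "config": cfg,
    }


def kare_marginals(seed: int = 0, n_samples: int = 7473) -> dict:
    """Default discovery-style cohort, intercept-calibrated, eligibility-
    filtered; returns the phenotype and pack-years marginals."""
    cfg = simulate.kare_config(n_samples=n_samples, seed=seed)
    cohort = simulate.simulate_cohort(cfg)
    cfg = dataclasses.replace(
        cfg, intercept=simulate.calibrate_intercept(cohort, cfg))
    cohort = simulate.simulate_phenotype(cohort, None, None, cfg)
    eligible = qc.eligibility_filter(cohort)
    ever = eligible["smoking_status"].isin(["former", "current"])
    # pack-years marginal is a property of the generated cohort (pre-filter
    # composition is essentially unchanged by the phenotype filter)
    ever_all = cohort["smoking_status"].isin(["former", "current"])
    fev = eligible["fev1_fvc"]
    py = cohort.loc[ever_all, "pack_years"]
    return {
        "mean_fev1_fvc": float(fev.mean()),
        "se_fev1_fvc": float(fev.std(ddof=1) / np.sqrt(len(fev))),
        "sd_fev1_fvc": float(fev.std(ddof=1)),
        "n_eligible": int(len(eligible)),
        "mean_packyears_ever": float(py.mean()),
        "se_packyears_ever": float(py.std(ddof=1) / np.sqrt(len(py))),
        "sd_packyears_ever": float(py.std(ddof=1)),
        "n_ever": int(len(py)),
        "frac_never": float((cohort["smoking_status"] == "never").mean()),
        "cohort": cohort, "eligible": eligible,
    }


def recovery_experiment(beta_snp: float, beta_int: float, maf: float = 0.15,
                        n_replicates: int = 200, n_samples: int = 7473,
                        seed: int = 0) -> dict:
    """Monte-Carlo recovery of SNP main and interaction coefficients.

    Each replicate simulates a discovery-style cohort with one causal
    variant, estimates stratum weights and fits the full weighted model;
    no PCs are included because the generator has no population structure.
    The eligibility filter is NOT applied here: truncating on the phenotype
    attenuates regression coefficients by construction, so the generating
    value is the estimand only on the untruncated cohort. Returns the
    replicate means and Monte-Carlo standard errors.
    """
    ss = np.random.SeedSequence([seed, 101])
    child_seeds = ss.generate_state(n_replicates) % (2**31)
    est_snp = np.empty(n_replicates)
    est_int = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = simulate.kare_config(
            n_samples=n_samples, maf_vector=np.array([maf]),
            beta_snp=beta_snp, beta_int=beta_int, seed=int(child_seeds[r]))
        cohort = simulate.simulate_cohort(cfg)
        genotypes = simulate.simulate_genotypes(cfg)
        cohort = simulate.simulate_phenotype(cohort, genotypes, 0, cfg)
        weights = model.estimate_stratum_weights(cohort)
        rec = model.scan_genome(cohort, genotypes, None, weights).iloc[0]
        est_snp[r] = rec["beta_snp"]
        est_int[r] = rec["beta_int"]
    return {
        "mean_beta_snp": float(est_snp.mean()),
        "mc_se_beta_snp": float(est_snp.std(ddof=1) / np.sqrt(n_replicates)),
        "mean_beta_int": float(est_int.mean()),
        "mc_se_beta_int": float(est_int.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
        "estimates": pd.DataFrame({"beta_snp": est_snp, "beta_int": est_int}),
    }
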