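"""Synthetic cohorts with the structure a gene-by-smoking interaction scan assumes.

The generator emulates a middle-aged East-Asian population cohort with
spirometry: a never/former/current smoking mixture, pack-years of smoking
with a positive-support distribution among ever-smokers, and an FEV1/FVC
phenotype (ratio x 100) whose residual spread differs between smokers and
non-smokers. Genotypes are drawn block-wise from a thresholded latent
Gaussian model so that the target minor-allele frequency is met exactly in
expectation while within-block linkage disequilibrium is tunable.

Phenotypes follow the linear model

    y = b0 + b_age*age + b_sex*sex + b_bmi*BMI + b_agesex*age*sex
        + b_py*packyears + beta_snp*g + beta_int*g*packyears + eps,

with ``eps ~ N(0, sigma_stratum^2)`` where the stratum is non-smoker vs
smoker. Everything is driven by a single :class:`SimulationConfig` and a
seed; identical configs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeSet

__all__ = [
    "SimulationConfig",
    "kare_config",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_phenotype",
    "inject_missingness",
    "soften_calls",
    "calibrate_intercept",
    "attach_stratum",
]

SMOKING_LEVELS = ("never", "former", "current")

#: Default covariate effects on FEV1/FVC (percentage points). Age and BMI
#: slopes are at the scale reported for healthy adult cohorts (~0.1 points
#: lost per year of age); the pack-years slope is the population-average
#: smoking effect absorbed by the exposure main term.
DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.10,
    "sex": -0.60,
    "bmi": -0.08,
    "age_sex": 0.0,
    "pack_years": -0.045,
}


@dataclass
class SimulationConfig:
    """All generative parameters for one synthetic study.

    Defaults emulate the discovery cohort of a Korean population study of
    healthy lung function: n = 7,473; smoking mixture 63.8 / 15.3 / 20.9 %
    (never / former / current); pack-years mean 22.8, SD 17.2 among
    ever-smokers; age 52.0 +- 8.9 y; 44.3 % male; BMI 24.7 +- 3.1 kg/m^2;
    marginal FEV1/FVC 81.4 +- 5.4.
    """

    n_samples: int = 7473
    smoking_proportions: tuple[float, float, float] = (0.638, 0.153, 0.209)
    packyears_mean: float = 22.8      # mean of pack-years among ever-smokers
    packyears_sd: float = 17.2        # SD of pack-years among ever-smokers
    age_mean: float = 52.0
    age_sd: float = 8.9
    male_fraction: float = 0.443
    bmi_mean: float = 24.7
    bmi_sd: float = 3.1
    maf_vector: np.ndarray | None = None   # per-variant MAF in [0.05, 0.5]
    ld_block_size: int = 1
    ld_rho: float = 0.0               # latent AR(1) correlation within a block
    beta_snp: float = 0.0             # phenotype points per minor allele
    beta_int: float = 0.0             # points per allele per pack-year
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    intercept: float | None = None    # None -> resolved so E[FEV1/FVC] = phenotype_mean
    phenotype_mean: float = 81.4      # marginal target used when intercept is None
    sigma_nonsmoker: float = 5.0      # residual SD, non-smoker stratum
    sigma_smoker: float = 5.8         # residual SD, smoker stratum
    missing_rate: float = 0.0
    smoker_stratum: str = "ever"      # 'ever' (never vs former+current) or 'current'
    subpop_fraction: float = 0.0      # optional 2nd subpopulation (PCA testing only)
    subpop_delta: float = 0.0         # additive MAF shift of the 2nd subpopulation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        props = np.asarray(self.smoking_proportions, dtype=float)
        if props.shape != (3,) or (props < 0).any():
            raise ValueError("smoking_proportions must be 3 nonnegative numbers")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("smoking_proportions must sum to 1")
        if self.sigma_nonsmoker < 0 or self.sigma_smoker < 0:
            raise ValueError("residual SDs must be nonnegative")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.smoker_stratum not in ("ever", "current"):
            raise ValueError("smoker_stratum must be 'ever' or 'current'")
        if self.maf_vector is not None:
            maf = np.asarray(self.maf_vector, dtype=float)
            if maf.size and ((maf < 0.05 - 1e-12) | (maf > 0.5 + 1e-12)).any():
                raise ValueError("every MAF must lie in [0.05, 0.5]")

    def resolved_intercept(self) -> float:
        """Intercept implied by ``phenotype_mean`` when none is given.

        Uses the population expectations of the covariates; SNP terms are
        not included (they shift the mean by ``beta_snp*2*MAF`` etc., which
        is negligible for the calibrations this default serves).
        """
        if self.intercept is not None:
            return float(self.intercept)
        p_never = self.smoking_proportions[0]
        e_py = (1.0 - p_never) * self.packyears_mean
        ce = self.covariate_effects
        expected = (
            ce.get("age", 0.0) * self.age_mean
            + ce.get("sex", 0.0) * self.male_fraction
            + ce.get("bmi", 0.0) * self.bmi_mean
            + ce.get("age_sex", 0.0) * self.age_mean * self.male_fraction
            + ce.get("pack_years", 0.0) * e_py
        )
        return float(self.phenotype_mean - expected)


def kare_config(**overrides) -> SimulationConfig:
    """Default configuration emulating the discovery cohort (KARE-like)."""
    return SimulationConfig(**overrides)


# ----------------------------------------------------------------------
# pack-years: truncated normal whose *truncated* moments match the target
# ----------------------------------------------------------------------

@lru_cache(maxsize=64)
def _packyears_family(mean: float, sd: float) -> tuple:
    """Positive-support pack-years distribution with the given mean/SD.

    Primary family: normal truncated at 0 whose TRUNCATED moments match the
    target, solved by moment matching. That family's coefficient of
    variation is bounded above by 1 (the exponential-like limit of a far
    left-shifted parent), so targets with sd >= mean fall back to a gamma
    with the same two moments.
    """
    if sd >= 0.995 * mean:  # infeasible for a zero-truncated normal
        shape = (mean / sd) ** 2
        return ("gamma", shape, sd**2 / mean)

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - solver is robust for sane inputs
        raise RuntimeError(f"truncated-normal moment matching failed: {sol.message}")
    mu, log_sigma = sol.x
    return ("truncnorm", float(mu), float(np.exp(log_sigma)))


def attach_stratum(cohort: pd.DataFrame, smoker_stratum: str = "ever") -> pd.DataFrame:
    """Set the weighting stratum column from smoking status.

    'ever' pools former+current as smokers; 'current' treats only current
    smokers as the smoker stratum (the health-checkup cohort rule).
    """
    if smoker_stratum == "ever":
        smoker = cohort["smoking_status"].isin(["former", "current"])
    elif smoker_stratum == "current":
        smoker = cohort["smoking_status"] == "current"
    else:
        raise ValueError("smoker_stratum must be 'ever' or 'current'")
    cohort = cohort.copy()
    cohort["stratum"] = np.where(smoker, "smoker", "nonsmoker")
    return cohort


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw sample ids, demographics, smoking status and pack-years.

    The phenotype column ``fev1_fvc`` is created but left NaN; it is filled
    by :func:`simulate_phenotype`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    status = rng.choice(SMOKING_LEVELS, size=n, p=np.asarray(config.smoking_proportions))
    pack_years = np.zeros(n)
    ever = status != "never"
    n_ever = int(ever.sum())
    if n_ever:
        family = _packyears_family(config.packyears_mean, config.packyears_sd)
        if family[0] == "truncnorm":
            _, mu, sigma = family
            a = (0.0 - mu) / sigma
            pack_years[ever] = stats.truncnorm.rvs(
                a, np.inf, loc=mu, scale=sigma, size=n_ever, random_state=rng)
        else:
            _, shape, scale = family
            pack_years[ever] = stats.gamma.rvs(
                shape, scale=scale, size=n_ever, random_state=rng)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = (rng.random(n) < config.male_fraction).astype(int)  # 1 = male
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:06d}" for i in range(n)],
            "fev1_fvc": np.nan,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking_status": status,
            "pack_years": pack_years,
        }
    )
    return attach_stratum(cohort, config.smoker_stratum)


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig, chrom: int = 1,
                       pos_start: int = 10_000, pos_step: int = 1_000) -> GenotypeSet:
    """Block-wise LD genotypes via a thresholded latent-Gaussian haplotype model.

    Within each block of ``ld_block_size`` variants the latent standard
    normals of one haplotype follow an AR(1) with lag-one correlation
    ``ld_rho``; a haplotype carries the minor allele at variant ``j`` when
    its latent value falls below ``Phi^{-1}(MAF_j)``, so the MAF target is
    hit exactly in expectation. Dosages are sums of two independent
    haplotypes. An optional second subpopulation with MAF shifted by
    ``subpop_delta`` supports principal-component testing.
    """
    if config.maf_vector is None or len(np.asarray(config.maf_vector)) == 0:
        raise ValueError("maf_vector must be non-empty")
    maf = np.asarray(config.maf_vector, dtype=float)
    m = maf.size
    n = config.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))

    subpop = np.zeros(n, dtype=int)
    if config.subpop_fraction > 0:
        subpop[rng.random(n) < config.subpop_fraction] = 1
    maf_by_pop = np.vstack([maf, np.clip(maf + config.subpop_delta, 0.01, 0.99)])
    thr = stats.norm.ppf(maf_by_pop)  # (2, m)

    block = max(int(config.ld_block_size), 1)
    rho = config.ld_rho
    dosages = np.zeros((n, m))
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        if rho > 0 and block > 1:
            for j in range(1, m):
                if j % block != 0:  # j stays inside its block
                    z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        dosages += z < thr[subpop, :]

    variants = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": pos_start + pos_step * np.arange(m),
            "minor": "A",
            "major": "C",
        }
    )
    gset = GenotypeSet(dosages=dosages, variants=variants,
                       sample_ids=[f"S{i + 1:06d}" for i in range(n)],
                       subpop=subpop if config.subpop_fraction > 0 else None)
    gset.annotate()
    if config.missing_rate > 0:
        gset = inject_missingness(gset, config.missing_rate,
                                  seed=np.random.SeedSequence([config.seed, 23]))
    return gset


def simulate_phenotype(cohort: pd.DataFrame, genotypes: GenotypeSet | None,
                       causal_index: int | None, config: SimulationConfig) -> pd.DataFrame:
    """Fill ``fev1_fvc`` from the linear model with stratum-specific noise.

    ``genotypes``/``causal_index`` may be None when both SNP effects are
    zero. Missing causal dosages are mean-imputed for generation; a
    monomorphic causal variant triggers a warning but still simulates.
    """
    n = len(cohort)
    if genotypes is None or causal_index is None:
        if config.beta_snp != 0 or config.beta_int != 0:
            raise ValueError("non-zero SNP effects require genotypes and causal_index")
        g = np.zeros(n)
    else:
        if not 0 <= causal_index < genotypes.n_variants:
            raise IndexError("causal_index out of range")
        g = genotypes.dosages[:, causal_index].copy()
        if np.isnan(g).any():
            g[np.isnan(g)] = np.nanmean(g)
        if np.nanstd(g) == 0:
            warnings.warn("causal variant is monomorphic; SNP effects are unidentifiable")

    ce = config.covariate_effects
    lp = (
        config.resolved_intercept()
        + ce.get("age", 0.0) * cohort["age"].to_numpy()
        + ce.get("sex", 0.0) * cohort["sex"].to_numpy()
        + ce.get("bmi", 0.0) * cohort["bmi"].to_numpy()
        + ce.get("age_sex", 0.0) * (cohort["age"] * cohort["sex"]).to_numpy()
        + ce.get("pack_years", 0.0) * cohort["pack_years"].to_numpy()
        + config.beta_snp * g
        + config.beta_int * g * cohort["pack_years"].to_numpy()
    )
    sigma = np.where(cohort["stratum"].to_numpy() == "smoker",
                     config.sigma_smoker, config.sigma_nonsmoker)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    out = cohort.copy()
    out["fev1_fvc"] = lp + sigma * rng.standard_normal(n)
    return out


def calibrate_intercept(cohort: pd.DataFrame, config: SimulationConfig,
                        target_mean: float | None = None,
                        min_ratio: float = 70.0) -> float:
    """Intercept making the expected phenotype mean of ELIGIBLE subjects hit
    the target.

    Eligibility truncates the phenotype at ``min_ratio`` from below, which
    raises the retained mean; this solves, by a deterministic root-find on
    per-sample truncated-normal means, for the intercept under which

        E[ y | y >= min_ratio ]  =  target_mean

    given the realized covariates of ``cohort`` (SNP terms must be zero or
    negligible). Returns the intercept value.
    """
    if target_mean is None:
        target_mean = config.phenotype_mean
    ce = config.covariate_effects
    lp0 = (
        ce.get("age", 0.0) * cohort["age"].to_numpy()
        + ce.get("sex", 0.0) * cohort["sex"].to_numpy()
        + ce.get("bmi", 0.0) * cohort["bmi"].to_numpy()
        + ce.get("age_sex", 0.0) * (cohort["age"] * cohort["sex"]).to_numpy()
        + ce.get("pack_years", 0.0) * cohort["pack_years"].to_numpy()
    )
    sigma = np.where(cohort["stratum"].to_numpy() == "smoker",
                     config.sigma_smoker, config.sigma_nonsmoker)

    def retained_mean_gap(c: float) -> float:
        mu = lp0 + c
        z = (min_ratio - mu) / sigma
        keep = stats.norm.sf(z)                      # P(y_i >= min_ratio)
        contrib = mu * keep + sigma * stats.norm.pdf(z)  # E[y_i ; y_i >= cut]
        return contrib.sum() / keep.sum() - target_mean

    lo = target_mean - lp0.mean() - 30.0
    hi = target_mean - lp0.mean() + 30.0
    return float(optimize.brentq(retained_mean_gap, lo, hi, xtol=1e-10))


# ----------------------------------------------------------------------
# perturbations
# ----------------------------------------------------------------------

def inject_missingness(genotypes: GenotypeSet, rate: float, seed=0) -> GenotypeSet:
    """Set each dosage missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = genotypes.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(out.dosages.shape) < rate
        out.dosages[mask] = np.nan
        if out.probs is not None:
            out.probs[mask, :] = np.nan
        out.annotate()
    return out


def soften_calls(genotypes: GenotypeSet, certainty: float, ) -> GenotypeSet:
    """Turn hard calls into probability triplets with the given certainty.

    The true genotype class receives probability ``certainty``; the
    remaining mass is split equally over the two other classes. Dosages
    become expected dosages ``p_AB + 2 p_BB``, so downstream regression and
    INFO computation see properly soft calls.
    """
    if not (1 / 3 < certainty <= 1):
        raise ValueError("certainty must be in (1/3, 1]")
    g = genotypes.dosages
    nonmiss = ~np.isnan(g)
    if not np.all(np.isclose(g[nonmiss] % 1, 0)):
        raise ValueError("soften_calls requires hard-call dosages {0,1,2}")
    n, m = g.shape
    probs = np.full((n, m, 3), np.nan)
    rest = (1.0 - certainty) / 2.0
    calls = np.where(nonmiss, np.rint(g), -1).astype(int)
    for k in range(3):
        layer = np.where(calls == k, certainty, rest)
        layer[~nonmiss] = np.nan
        probs[:, :, k] = layer
    out = genotypes.copy()
    out.probs = probs
    exp_dos = probs[:, :, 1] + 2.0 * probs[:, :, 2]
    out.dosages = np.where(nonmiss, exp_dos, np.nan)
    out.annotate()
    return out
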