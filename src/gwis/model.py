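"""Weighted-least-squares engine for gene-by-smoking interaction scans.

Residual spread of FEV1/FVC differs between smokers and non-smokers, so
per-SNP regressions use inverse-variance weights estimated once per
stratum (two-stage feasible WLS; the weights are then treated as known).
For each variant the model

    y ~ const + age + sex + BMI + age*sex + pack_years + PC1..PCk
        + SNP + SNP*pack_years,      eps ~ N(0, sigma^2 / w_i)

is fitted by WLS and the joint null H0: beta_SNP = beta_SNPxPY = 0 is
tested with 2 degrees of freedom, by likelihood ratio (chi-square) or by
F test. Wald tests for the individual coefficients, AIC comparison against
the unweighted fit, and genomic-inflation / QQ / Manhattan diagnostics
round out the engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeSet
from .popstruct import PCScores

__all__ = [
    "StratumWeights", "WeightedFit", "JointTest",
    "build_design", "estimate_stratum_weights", "fit_weighted_model",
    "joint_test", "scan_genome", "genomic_inflation", "aic_compare",
    "qq_manhattan_export", "GENOME_WIDE_ALPHA",
]

GENOME_WIDE_ALPHA = 5e-8
#: median of the chi-square(1) distribution
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

BASE_COVARIATES = ["age", "sex", "bmi", "age_sex", "pack_years"]


def build_design(cohort: pd.DataFrame, pcs: PCScores | np.ndarray | None = None,
                 dosage: np.ndarray | None = None) -> pd.DataFrame:
    """Design frame: const, age, sex, BMI, age*sex, pack-years, PCs and,
    when ``dosage`` is given, SNP and SNP x pack-years columns."""
    x = pd.DataFrame(index=cohort.index)
    x["const"] = 1.0
    x["age"] = cohort["age"].to_numpy(float)
    x["sex"] = cohort["sex"].to_numpy(float)
    x["bmi"] = cohort["bmi"].to_numpy(float)
    x["age_sex"] = x["age"] * x["sex"]
    x["pack_years"] = cohort["pack_years"].to_numpy(float)
    if pcs is not None:
        scores = pcs.scores if isinstance(pcs, PCScores) else np.asarray(pcs)
        for k in range(scores.shape[1]):
            x[f"PC{k + 1}"] = scores[:, k]
    if dosage is not None:
        x["snp"] = np.asarray(dosage, dtype=float)
        x["snp_py"] = x["snp"] * x["pack_years"]
    return x


# ----------------------------------------------------------------------
# stage 1: stratum variances
# ----------------------------------------------------------------------

@dataclass
class StratumWeights:
    """Inverse residual-variance weights by smoking stratum."""

    sigma2_nonsmoker: float
    sigma2_smoker: float
    weights: pd.Series          # per sample, indexed by sample_id
    rule: str = "ever"          # stratum definition used

    @property
    def variance_ratio(self) -> float:
        return self.sigma2_smoker / self.sigma2_nonsmoker


def estimate_stratum_weights(cohort: pd.DataFrame,
                             pcs: PCScores | np.ndarray | None = None) -> StratumWeights:
    """Residual variances from stratum-specific OLS of the null model.

    Within each stratum the phenotype is regressed on the null-model
    covariates (no SNP terms); constant columns within a stratum (e.g.
    pack-years among never-smokers) are dropped. The per-sample weight is
    the reciprocal of its stratum's unbiased residual variance, so weights
    are SNP-independent and estimated once per scan.
    """
    y = cohort["fev1_fvc"].to_numpy(float)
    x = build_design(cohort, pcs)
    strata = cohort["stratum"].to_numpy()
    sigma2 = {}
    for label in ("nonsmoker", "smoker"):
        rows = strata == label
        if not rows.any():
            raise ValueError(f"stratum '{label}' is empty")
        xs = x.loc[rows]
        keep = [c for c in xs.columns if c == "const" or xs[c].nunique() > 1]
        xs = xs[keep].to_numpy()
        ys = y[rows]
        beta, rss, rank, _ = np.linalg.lstsq(xs, ys, rcond=None)
        if xs.shape[0] <= rank:
            raise ValueError(f"stratum '{label}' smaller than its design rank")
        resid = ys - xs @ beta
        sigma2[label] = float(resid @ resid) / (xs.shape[0] - rank)
    w = np.where(strata == "smoker", 1.0 / sigma2["smoker"], 1.0 / sigma2["nonsmoker"])
    rule = "current" if (cohort["smoking_status"].eq("former")
                         & cohort["stratum"].eq("nonsmoker")).any() else "ever"
    return StratumWeights(
        sigma2_nonsmoker=sigma2["nonsmoker"], sigma2_smoker=sigma2["smoker"],
        weights=pd.Series(w, index=cohort["sample_id"].to_numpy()), rule=rule)


# ----------------------------------------------------------------------
# stage 2: weighted fit
# ----------------------------------------------------------------------

@dataclass
class WeightedFit:
    """A fitted weighted regression (weights treated as known)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series          # two-sided t-based Wald p
    wrss: float                 # weighted residual sum of squares
    sigma2: float               # unbiased scale WRSS / (n - p)
    loglik: float               # profiled Gaussian log-likelihood
    aic: float                  # 2*(p + 1) - 2*loglik (1 variance parameter)
    n: int
    n_params: int
    rank: int
    weights: np.ndarray = field(repr=False)
    rank_deficient: bool = False

    @property
    def df_resid(self) -> int:
        return self.n - self.n_params


def fit_weighted_model(y, design, weights) -> WeightedFit:
    """WLS fit ``beta = (X'WX)^-1 X'Wy`` with fixed positive weights.

    Standard errors use the unbiased scale ``WRSS / (n - p)``; the
    log-likelihood profiles the ML variance ``WRSS / n`` and includes the
    fixed-weight term ``0.5 * sum(log w_i)``, so likelihood-ratio
    statistics between nested fits sharing the same weights reduce to
    ``n * log(WRSS0 / WRSS1)``. Rank-deficient designs are fitted by
    minimum-norm least squares and flagged; their non-identified columns
    get zero SEs and NaN p-values.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        x = design.to_numpy(dtype=float)
    else:
        x = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(x.shape[1])]
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    n, p = x.shape
    sw = np.sqrt(w)
    xw = x * sw[:, None]
    yw = y * sw
    beta, _, rank, _ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    wrss = float(resid @ resid)
    deficient = rank < p
    if deficient:
        warnings.warn("design is rank deficient; some coefficients are not estimable")
    xtx_inv = np.linalg.pinv(xw.T @ xw)
    df = n - rank
    sigma2 = wrss / df if df > 0 else np.nan
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    loglik = (-0.5 * n * (np.log(2 * np.pi) + np.log(wrss / n) + 1.0)
              + 0.5 * np.log(w).sum())
    aic = 2.0 * (rank + 1) - 2.0 * loglik
    return WeightedFit(
        params=pd.Series(beta, index=names), bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names), wrss=wrss, sigma2=float(sigma2),
        loglik=float(loglik), aic=float(aic), n=n, n_params=p, rank=int(rank),
        weights=w, rank_deficient=deficient)


@dataclass
class JointTest:
    """2-df joint test of the SNP and SNP x pack-years coefficients."""

    statistic: float
    p_value: float
    flavor: str
    lr_stat: float
    p_lr: float
    f_stat: float
    p_f: float


def joint_test(full: WeightedFit, null: WeightedFit, flavor: str = "lr") -> JointTest:
    """Test the 2-extra-parameter full model against its null.

    LR: ``n * log(WRSS0 / WRSS1)`` against chi-square(2).
    F: ``((WRSS0 - WRSS1)/2) / (WRSS1 / (n - p_full))`` against F(2, n-p).
    Both are always computed; ``flavor`` picks the headline statistic.
    """
    if flavor not in ("lr", "f"):
        raise ValueError("flavor must be 'lr' or 'f'")
    if full.n != null.n:
        raise ValueError("full and null fits use different samples")
    if not np.allclose(full.weights, null.weights):
        raise ValueError("full and null fits use different weights")
    wrss0, wrss1 = null.wrss, full.wrss
    if wrss1 > wrss0 * (1 + 1e-10) + 1e-10:
        raise ValueError("nesting violated: full model fits worse than null")
    wrss1 = min(wrss1, wrss0)
    n = full.n
    lr = n * np.log(wrss0 / wrss1) if wrss1 > 0 else np.inf
    p_lr = float(stats.chi2.sf(lr, 2))
    df2 = n - full.n_params
    if wrss1 > 0 and df2 > 0:
        f_stat = ((wrss0 - wrss1) / 2.0) / (wrss1 / df2)
        p_f = float(stats.f.sf(f_stat, 2, df2))
    else:
        f_stat, p_f = np.inf, 0.0
    stat, p = (lr, p_lr) if flavor == "lr" else (f_stat, p_f)
    return JointTest(statistic=float(stat), p_value=float(p), flavor=flavor,
                     lr_stat=float(lr), p_lr=p_lr, f_stat=float(f_stat), p_f=p_f)


# ----------------------------------------------------------------------
# genome scan
# ----------------------------------------------------------------------

def scan_genome(cohort: pd.DataFrame, genotypes: GenotypeSet,
                pcs: PCScores | np.ndarray | None = None,
                weights: StratumWeights | np.ndarray | None = None,
                flavor: str = "lr") -> pd.DataFrame:
    """Per-variant weighted scan with 2-df joint tests.

    Rows of ``cohort`` are matched to genotype samples by ``sample_id``;
    per SNP, samples missing that SNP are dropped (complete case) and the
    null fit is cached per missingness pattern. Returns one row per
    variant with Table-2-style columns; variants whose SNP/interaction
    block is numerically non-identifiable are flagged ``estimable=False``.
    """
    if flavor not in ("lr", "f"):
        raise ValueError("flavor must be 'lr' or 'f'")
    if weights is None:
        weights = estimate_stratum_weights(cohort, pcs)
    row_of = {sid: i for i, sid in enumerate(genotypes.sample_ids)}
    try:
        rows = np.array([row_of[s] for s in cohort["sample_id"]])
    except KeyError as e:  # pragma: no cover - user error path
        raise ValueError(f"cohort sample {e} absent from genotypes") from e
    g_all = genotypes.dosages[rows, :]
    x_df = build_design(cohort, pcs)
    x = x_df.to_numpy(dtype=float)
    y = cohort["fev1_fvc"].to_numpy(float)
    if isinstance(weights, StratumWeights):
        w = weights.weights.loc[cohort["sample_id"]].to_numpy(float)
    else:
        w = np.asarray(weights, dtype=float)
    py = cohort["pack_years"].to_numpy(float)
    n, m = g_all.shape
    p_null = x.shape[1]
    p_full = p_null + 2

    miss = np.isnan(g_all)
    groups: dict[bytes, list[int]] = {}
    for j in range(m):
        groups.setdefault(miss[:, j].tobytes(), []).append(j)
    out = {c: np.full(m, np.nan) for c in
           ["maf", "beta_snp", "se_snp", "p_snp", "beta_int", "se_int",
            "p_int", "statistic", "p_lr", "lr_stat", "p_joint_lr",
            "f_stat", "p_joint_f"]}
    n_used = np.zeros(m, dtype=int)
    estimable = np.zeros(m, dtype=bool)

    for cols in groups.values():
        cols = np.asarray(cols)
        use = ~miss[:, cols[0]]
        nr = int(use.sum())
        n_used[cols] = nr
        if nr <= p_full:
            continue
        sw = np.sqrt(w[use])
        xw = x[use] * sw[:, None]
        yw = y[use] * sw
        q, _ = np.linalg.qr(xw)
        y_res = yw - q @ (q.T @ yw)
        wrss0 = float(y_res @ y_res)
        gd = g_all[np.ix_(use, cols)]
        gw = gd * sw[:, None]
        gpw = gd * (py[use] * sw)[:, None]
        g_res = gw - q @ (q.T @ gw)
        gp_res = gpw - q @ (q.T @ gpw)
        s11 = np.einsum("ij,ij->j", g_res, g_res)
        s22 = np.einsum("ij,ij->j", gp_res, gp_res)
        s12 = np.einsum("ij,ij->j", g_res, gp_res)
        b1 = g_res.T @ y_res
        b2 = gp_res.T @ y_res
        det = s11 * s22 - s12**2
        scale = np.maximum(s11 * s22, 1e-300)
        ok = (s11 > 1e-10) & (s22 > 1e-10) & (det / scale > 1e-12)
        estimable[cols] = ok
        det_safe = np.where(ok, det, 1.0)
        beta1 = (s22 * b1 - s12 * b2) / det_safe
        beta2 = (s11 * b2 - s12 * b1) / det_safe
        expl = np.clip(b1 * beta1 + b2 * beta2, 0.0, wrss0)
        wrss1 = wrss0 - expl
        df = nr - p_full
        sigma2 = wrss1 / df
        se1 = np.sqrt(np.clip(sigma2 * s22 / det_safe, 0, None))
        se2 = np.sqrt(np.clip(sigma2 * s11 / det_safe, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = 2 * stats.t.sf(np.abs(beta1 / se1), df)
            p2 = 2 * stats.t.sf(np.abs(beta2 / se2), df)
            lr = nr * np.log(wrss0 / np.maximum(wrss1, 1e-300))
        p_lr = stats.chi2.sf(lr, 2)
        f_stat = (expl / 2.0) / sigma2
        p_f = stats.f.sf(f_stat, 2, df)
        freq = gd.mean(axis=0) / 2.0
        vals = {
            "maf": np.minimum(freq, 1 - freq), "beta_snp": beta1, "se_snp": se1,
            "p_snp": p1, "beta_int": beta2, "se_int": se2, "p_int": p2,
            "lr_stat": lr, "p_joint_lr": p_lr, "f_stat": f_stat, "p_joint_f": p_f,
            "statistic": lr if flavor == "lr" else f_stat,
            "p_lr": p_lr if flavor == "lr" else p_f,
        }
        for name, arr in vals.items():
            out[name][cols] = np.where(ok, arr, np.nan)
        out["maf"][cols] = np.minimum(freq, 1 - freq)  # maf reported regardless

    records = pd.DataFrame({
        "id": genotypes.variants["id"], "chrom": genotypes.variants["chrom"],
        "pos": genotypes.variants["pos"], "maf": out["maf"], "n_used": n_used,
        "beta_snp": out["beta_snp"], "se_snp": out["se_snp"], "p_snp": out["p_snp"],
        "beta_int": out["beta_int"], "se_int": out["se_int"], "p_int": out["p_int"],
        "statistic": out["statistic"], "p_lr": out["p_lr"],
        "lr_stat": out["lr_stat"], "p_joint_lr": out["p_joint_lr"],
        "f_stat": out["f_stat"], "p_joint_f": out["p_joint_f"],
        "flavor": flavor, "estimable": estimable,
    })
    records["significant"] = records["p_lr"] < GENOME_WIDE_ALPHA
    return records


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def genomic_inflation(p_values) -> float:
    """Inflation factor lambda: median 1-df chi-square quantile of the
    p-values over the null median 0.4549..."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        warnings.warn("fewer than 100 p-values; lambda estimate is unstable")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def aic_compare(weighted: WeightedFit, unweighted: WeightedFit
                ) -> tuple[float, str]:
    """AIC difference (unweighted - weighted) and the preferred model.

    The unweighted fit must be the same mean structure with unit weights
    so the two Gaussian likelihoods are on the same data scale.
    """
    if weighted.n != unweighted.n:
        raise ValueError("fits use different numbers of rows")
    delta = unweighted.aic - weighted.aic
    return float(delta), ("weighted" if delta > 0 else "unweighted")


def qq_manhattan_export(records: pd.DataFrame, p_col: str = "p_lr") -> dict:
    """Numeric tables behind QQ and Manhattan plots.

    QQ: sorted observed -log10 p against expected quantiles ``(i-0.5)/m``.
    Manhattan: cumulative genome coordinate (per-chromosome offsets) and
    -log10 p, with the genome-wide reference line at 5e-8.
    """
    if records.empty:
        raise ValueError("no records")
    ok = records[p_col].notna()
    p = records.loc[ok, p_col].to_numpy(float)
    m = p.size
    order = np.argsort(p)
    qq = pd.DataFrame({
        "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m),
        "observed": -np.log10(p[order]),
    })
    rec = records.loc[ok].copy()
    offsets, cum = {}, 0
    for chrom, grp in rec.groupby("chrom", sort=True):
        offsets[chrom] = cum
        cum += int(grp["pos"].max())
    rec["cumulative_pos"] = rec["pos"] + rec["chrom"].map(offsets)
    manhattan = rec[["id", "chrom", "pos", "cumulative_pos"]].copy()
    manhattan["neglog10_p"] = -np.log10(rec[p_col].to_numpy(float))
    return {"qq": qq, "manhattan": manhattan.reset_index(drop=True),
            "genomewide_line": GENOME_WIDE_ALPHA}
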