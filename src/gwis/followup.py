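"""Replication across cohorts, SNP-exposure independence, and effect-
modification summaries.

Replication re-runs the weighted interaction model for a candidate list in
an independent cohort under that cohort's own eligibility rule: the
discovery-style rule keeps all eligible smokers and pools former+current
into the smoker stratum, while the health-checkup rule excludes former
smokers (their enrolment correlates with cessation counselling, which
would bias the exposure) and restricts to age > 40. A candidate is deemed
replicated for a term when its coefficient has the discovery direction and
p < 0.05; the 2-df overall effect is additionally flagged at p < 0.1.

SNP-exposure independence is the precondition for reading a significant
interaction as effect modification: a logistic regression of smoking
status on dosage and a linear regression of pack-years on dosage should
both be null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotypes import GenotypeSet
from .model import (StratumWeights, build_design, estimate_stratum_weights,
                    fit_weighted_model, joint_test)
from .popstruct import PCScores
from .qc import eligibility_filter
from .simulate import attach_stratum

__all__ = [
    "CohortRule", "KARE_RULE", "ARIRANG_RULE", "GENIE_RULE",
    "replicate_candidates", "independence_tests",
    "predicted_trajectories", "boxplot_summary",
]


@dataclass(frozen=True)
class CohortRule:
    """Eligibility and stratum conventions of one cohort."""

    name: str
    min_ratio: float = 70.0
    min_age: float | None = None
    exclude_former: bool = False
    smoker_stratum: str = "ever"     # weighting stratum definition


KARE_RULE = CohortRule("KARE")
ARIRANG_RULE = CohortRule("ARIRANG")
GENIE_RULE = CohortRule("GENIE", min_age=40.0, exclude_former=True,
                        smoker_stratum="current")


def replicate_candidates(candidates, cohort: pd.DataFrame, genotypes: GenotypeSet,
                         pcs: PCScores | np.ndarray | None = None,
                         cohort_rule: CohortRule = KARE_RULE,
                         discovery_directions: dict | None = None,
                         flavor: str = "lr") -> pd.DataFrame:
    """Per-candidate weighted fits in a replication cohort.

    ``candidates`` is an iterable of variant ids (or a DataFrame with an
    ``id`` column). ``discovery_directions`` optionally maps variant id to
    ``(sign_snp, sign_int)`` from the discovery scan; replication then also
    requires the same sign. Candidates absent from ``genotypes`` are
    returned with ``tested=False``. PCs, when supplied, must be aligned to
    the FULL cohort rows; they are subset together with the cohort.
    """
    if isinstance(candidates, pd.DataFrame):
        candidate_ids = candidates["id"].tolist()
    else:
        candidate_ids = list(candidates)
    scores = pcs.scores if isinstance(pcs, PCScores) else pcs
    keep = eligibility_filter(cohort, min_ratio=cohort_rule.min_ratio,
                              min_age=cohort_rule.min_age,
                              exclude_former=cohort_rule.exclude_former)
    keep = attach_stratum(keep, cohort_rule.smoker_stratum)
    if scores is not None:
        pos = cohort.reset_index(drop=True)["sample_id"]
        lookup = pd.Series(np.arange(len(pos)), index=pos)
        scores = np.asarray(scores)[lookup.loc[keep["sample_id"]].to_numpy()]
    weights = estimate_stratum_weights(keep, scores)

    row_of = {s: i for i, s in enumerate(genotypes.sample_ids)}
    rows = np.array([row_of[s] for s in keep["sample_id"]])
    id_to_col = {vid: j for j, vid in enumerate(genotypes.variants["id"])}

    y = keep["fev1_fvc"].to_numpy(float)
    w = weights.weights.loc[keep["sample_id"]].to_numpy(float)
    results = []
    for vid in candidate_ids:
        rec = {"cohort": cohort_rule.name, "id": vid, "tested": False,
               "n_used": 0, "beta_snp": np.nan, "se_snp": np.nan,
               "p_snp": np.nan, "beta_int": np.nan, "se_int": np.nan,
               "p_int": np.nan, "p_lr": np.nan}
        j = id_to_col.get(vid)
        if j is None:
            results.append(rec)
            continue
        g = genotypes.dosages[rows, j]
        use = ~np.isnan(g)
        sub = keep.loc[use.nonzero()[0]] if not use.all() else keep
        x_null = build_design(sub, None if scores is None else scores[use])
        x_full = x_null.copy()
        x_full["snp"] = g[use]
        x_full["snp_py"] = g[use] * sub["pack_years"].to_numpy(float)
        try:
            null_fit = fit_weighted_model(y[use], x_null, w[use])
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                full_fit = fit_weighted_model(y[use], x_full, w[use])
            jt = joint_test(full_fit, null_fit, flavor=flavor)
        except (Warning, ValueError, np.linalg.LinAlgError):
            results.append(rec)
            continue
        rec.update(tested=True, n_used=int(use.sum()),
                   beta_snp=full_fit.params["snp"], se_snp=full_fit.bse["snp"],
                   p_snp=full_fit.pvalues["snp"],
                   beta_int=full_fit.params["snp_py"],
                   se_int=full_fit.bse["snp_py"],
                   p_int=full_fit.pvalues["snp_py"], p_lr=jt.p_value)
        results.append(rec)
    out = pd.DataFrame(results)

    def same_dir(row, term, sign_idx):
        if discovery_directions is None or row["id"] not in discovery_directions:
            return True
        sign = discovery_directions[row["id"]][sign_idx]
        return np.sign(row[term]) == np.sign(sign)

    out["replicated_snp"] = out.apply(
        lambda r: bool(r["tested"] and r["p_snp"] < 0.05 and same_dir(r, "beta_snp", 0)),
        axis=1)
    out["replicated_int"] = out.apply(
        lambda r: bool(r["tested"] and r["p_int"] < 0.05 and same_dir(r, "beta_int", 1)),
        axis=1)
    out["replicated_overall_05"] = out["tested"] & (out["p_lr"] < 0.05)
    out["replicated_overall_10"] = out["tested"] & (out["p_lr"] < 0.1)
    return out


def independence_tests(dosages, cohort: pd.DataFrame, adjusted: bool = False,
                       smoker_definition: str = "ever") -> dict:
    """SNP-smoking independence diagnostics.

    Logistic regression of binary smoking status (per ``smoker_definition``:
    'ever' = former+current vs never, 'current' = current vs never, former
    excluded) on dosage, and linear regression of pack-years on dosage.
    ``adjusted`` adds age and sex. Returns Wald p-values of the SNP term.
    """
    g = np.asarray(dosages, dtype=float)
    if np.nanstd(g) == 0:
        raise ValueError("constant dosage: independence tests are non-estimable")
    df = cohort.copy()
    df["snp"] = g
    df = df.dropna(subset=["snp"])
    if smoker_definition == "ever":
        df["smoker"] = df["smoking_status"].isin(["former", "current"]).astype(int)
    elif smoker_definition == "current":
        df = df[df["smoking_status"] != "former"]
        df["smoker"] = (df["smoking_status"] == "current").astype(int)
    else:
        raise ValueError("smoker_definition must be 'ever' or 'current'")
    if df["smoker"].nunique() < 2:
        raise ValueError("both smoking classes must be present")

    cols = ["snp"] + (["age", "sex"] if adjusted else [])
    x = sm.add_constant(df[cols].astype(float))
    p_status = np.nan
    status_flag = "ok"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit = sm.Logit(df["smoker"].to_numpy(), x).fit(disp=0)
        p_status = float(logit.pvalues["snp"])
        if not np.isfinite(p_status):
            status_flag = "non_estimable"
    except Exception:
        status_flag = "separation"
    lin = sm.OLS(df["pack_years"].to_numpy(float), x).fit()
    return {
        "p_status": p_status, "status_flag": status_flag,
        "p_packyears": float(lin.pvalues["snp"]),
        "smoker_definition": smoker_definition, "adjusted": adjusted,
        "n": int(len(df)),
    }


def predicted_trajectories(fit, packyears_grid, genotype_levels=(0, 1, 2),
                           covariate_profile: dict | None = None) -> pd.DataFrame:
    """Predicted phenotype by genotype along a pack-years grid.

    Evaluates the fitted linear predictor at a fixed covariate profile
    (defaults to zero for any covariate not supplied), varying genotype and
    pack-years; the slope in pack-years for genotype ``g`` is exactly
    ``beta_packyears + beta_int * g``. ``fit`` must contain ``snp`` and
    ``snp_py`` terms.
    """
    params = fit.params if hasattr(fit, "params") else pd.Series(fit)
    for term in ("snp", "snp_py"):
        if term not in params.index:
            raise ValueError(f"fit lacks the '{term}' term")
    grid = np.asarray(packyears_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("pack-years grid is empty")
    profile = dict(covariate_profile or {})
    base = 0.0
    for name, value in params.items():
        if name in ("snp", "snp_py", "pack_years"):
            continue
        if name == "const":
            base += value
        else:
            base += value * profile.get(name, 0.0)
    rows = []
    b_py = params.get("pack_years", 0.0)
    for g in genotype_levels:
        pred = (base + params["snp"] * g
                + (b_py + params["snp_py"] * g) * grid)
        for py, yhat in zip(grid, pred):
            rows.append({"genotype": g, "pack_years": py, "predicted": yhat})
    return pd.DataFrame(rows)


def boxplot_summary(cohort: pd.DataFrame, dosages, age_bins) -> pd.DataFrame:
    """Group means/quartiles of the phenotype by genotype, smoking status
    and age bin (the numeric table behind grouped boxplots). Groups with no
    observations appear with n = 0 and NaN statistics."""
    df = cohort.copy()
    df["genotype"] = np.rint(np.asarray(dosages, dtype=float))
    df = df.dropna(subset=["genotype", "fev1_fvc"])
    df["age_bin"] = pd.cut(df["age"], bins=age_bins)
    rows = []
    statuses = list(pd.unique(cohort["smoking_status"]))
    for g in sorted(df["genotype"].unique()):
        for status in statuses:
            for interval in df["age_bin"].cat.categories:
                grp = df[(df["genotype"] == g)
                         & (df["smoking_status"] == status)
                         & (df["age_bin"] == interval)]["fev1_fvc"]
                rec = {"genotype": int(g), "smoking_status": status,
                       "age_bin": str(interval), "n": int(len(grp))}
                if len(grp):
                    rec.update(mean=grp.mean(), q1=grp.quantile(0.25),
                               median=grp.median(), q3=grp.quantile(0.75))
                else:
                    rec.update(mean=np.nan, q1=np.nan, median=np.nan, q3=np.nan)
                rows.append(rec)
    return pd.DataFrame(rows)
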