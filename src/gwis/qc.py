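"""Variant- and sample-level quality control for genotype data.

Implements the standard GWAS pre-analysis filters: the Hardy-Weinberg
exact test (Wigginton-style, conditioning on allele counts and summing the
probabilities of heterozygote configurations no more probable than the one
observed), minor-allele-frequency and call-rate filters, the IMPUTE-style
INFO score for genotype probability triplets, and cohort eligibility rules
(FEV1/FVC >= 70, optional minimum age, optional exclusion of former
smokers). Filter boundaries are strict as conventionally printed: a variant
fails when hwe_p < 1e-5, MAF < 0.05, call rate < 0.95 or INFO < 0.5;
values exactly at a threshold pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeSet

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "compute_maf",
    "impute_info",
    "apply_variant_qc",
    "apply_sample_qc",
    "eligibility_filter",
]

#: log-weight comparisons tolerate this much float noise so that exactly
#: tied heterozygote configurations are always included
_HWE_LOG_EPS = 1e-9


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg p-value from genotype counts.

    Conditions on the observed allele counts and sums, over all feasible
    heterozygote counts, the probabilities that are <= the probability of
    the observed configuration (plain exact test, no mid-p correction).
    Monomorphic tables return 1.0.
    """
    counts = (int(n_aa), int(n_ab), int(n_bb))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("at least one genotype required")
    # minor allele count (swap labels if needed)
    r = 2 * min(n_aa, n_bb) + n_ab
    if r == 0:
        return 1.0
    # feasible heterozygote counts share the parity of r
    h = np.arange(r % 2, min(r, 2 * n - r) + 1, 2)
    hom_minor = (r - h) // 2
    hom_major = n - h - hom_minor
    logw = (
        h * np.log(2.0)
        - gammaln(h + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    obs = logw[np.searchsorted(h, n_ab)]
    keep = logw <= obs + _HWE_LOG_EPS
    logw -= logw.max()
    w = np.exp(logw)
    p = w[keep].sum() / w.sum()
    return float(min(p, 1.0))


def compute_maf(dosages) -> float:
    """Minor-allele frequency ``min(f, 1-f)`` with ``f = mean(dosage)/2``
    over non-missing entries."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing")
    f = d.mean() / 2.0
    return float(min(f, 1.0 - f))


def impute_info(triplets) -> float:
    """IMPUTE-style INFO score from genotype probability triplets.

    With per-sample expected dosage ``e_i = p_AB + 2 p_BB`` and second
    moment ``f_i = p_AB + 4 p_BB``, and estimated allele frequency
    ``theta = sum(e_i) / 2N``, the score is

        1 - sum(f_i - e_i^2) / (2 N theta (1 - theta)),

    i.e. one minus the average imputation uncertainty relative to binomial
    variance. Returns 1 by convention when theta is 0 or 1; clamped to
    [0, 1].
    """
    p = np.asarray(triplets, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("triplets must be an (N, 3) array")
    if np.isnan(p).any():
        raise ValueError("triplets contain missing values")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each triplet must sum to 1")
    n = p.shape[0]
    e = p[:, 1] + 2.0 * p[:, 2]
    f = p[:, 1] + 4.0 * p[:, 2]
    theta = e.sum() / (2.0 * n)
    if theta <= 1e-12 or theta >= 1 - 1e-12:
        return 1.0
    score = 1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta))
    return float(np.clip(score, 0.0, 1.0))


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Filter thresholds; all comparisons are strict (< fails)."""

    hwe_p_min: float = 1e-5
    maf_min: float = 0.05
    variant_call_rate_min: float = 0.95
    sample_missing_max: float = 0.05
    info_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "variant_call_rate_min",
                     "sample_missing_max", "info_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class QCReport:
    """Per-axis pass/fail table plus removal counts."""

    axis: str                       # 'variant' or 'sample'
    table: pd.DataFrame             # id, pass, reasons (';'-joined)
    removed_by: dict = field(default_factory=dict)
    n_input: int = 0
    n_removed: int = 0
    n_surviving: int = 0

    def summary(self) -> str:
        lines = [f"{self.axis} QC: {self.n_input} in, "
                 f"{self.n_removed} removed, {self.n_surviving} surviving"]
        for reason, k in sorted(self.removed_by.items()):
            lines.append(f"  failed {reason}: {k}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def apply_variant_qc(genotypes: GenotypeSet,
                     thresholds: QCThresholds = QCThresholds(),
                     annotate: bool = True) -> tuple[GenotypeSet, QCReport]:
    """Drop variants failing any of: HWE, MAF, call-rate, INFO (INFO only
    when probability triplets are present)."""
    if genotypes.n_variants == 0:
        raise ValueError("empty genotype set")
    if annotate:
        genotypes.annotate()
    v = genotypes.variants
    checks = {
        "hwe": v["hwe_p"].to_numpy() < thresholds.hwe_p_min,
        "maf": v["maf"].to_numpy() < thresholds.maf_min,
        "call_rate": v["call_rate"].to_numpy() < thresholds.variant_call_rate_min,
    }
    if genotypes.probs is not None:
        checks["info"] = v["info"].to_numpy() < thresholds.info_min
    fail_any = np.zeros(genotypes.n_variants, dtype=bool)
    reasons = [[] for _ in range(genotypes.n_variants)]
    removed_by = {}
    for name, failed in checks.items():
        failed = np.asarray(failed) & ~np.isnan(
            v[{"hwe": "hwe_p", "maf": "maf",
               "call_rate": "call_rate", "info": "info"}[name]].to_numpy())
        removed_by[name] = int(failed.sum())
        fail_any |= failed
        for j in np.flatnonzero(failed):
            reasons[j].append(name)
    table = pd.DataFrame({
        "id": v["id"],
        "pass": ~fail_any,
        "reasons": [";".join(r) for r in reasons],
    })
    report = QCReport(axis="variant", table=table, removed_by=removed_by,
                      n_input=genotypes.n_variants,
                      n_removed=int(fail_any.sum()),
                      n_surviving=int((~fail_any).sum()))
    return genotypes.take_variants(~fail_any), report


def apply_sample_qc(genotypes: GenotypeSet,
                    thresholds: QCThresholds = QCThresholds()
                    ) -> tuple[GenotypeSet, QCReport]:
    """Drop samples whose genotype missingness exceeds the threshold.

    Missingness is computed on the variants present at call time (run
    before variant QC so that bad variants still count, which is the
    documented order of this pipeline).
    """
    miss = np.isnan(genotypes.dosages).mean(axis=1)
    failed = miss > thresholds.sample_missing_max  # strictly greater fails
    table = pd.DataFrame({
        "id": genotypes.sample_ids,
        "pass": ~failed,
        "reasons": ["missingness" if f else "" for f in failed],
    })
    report = QCReport(axis="sample", table=table,
                      removed_by={"missingness": int(failed.sum())},
                      n_input=genotypes.n_samples,
                      n_removed=int(failed.sum()),
                      n_surviving=int((~failed).sum()))
    return genotypes.take_samples(~failed), report


def eligibility_filter(cohort: pd.DataFrame, min_ratio: float = 70.0,
                       min_age: float | None = None,
                       exclude_former: bool = False) -> pd.DataFrame:
    """Cohort eligibility: FEV1/FVC >= min_ratio, optional age > min_age,
    optional exclusion of former smokers."""
    if cohort["fev1_fvc"].isna().all():
        raise ValueError("phenotype must be present before eligibility filtering")
    keep = cohort["fev1_fvc"] >= min_ratio
    if min_age is not None:
        keep &= cohort["age"] > min_age
    if exclude_former:
        keep &= cohort["smoking_status"] != "former"
    out = cohort.loc[keep].reset_index(drop=True)
    if out.empty:
        import warnings
        warnings.warn("eligibility filter removed every subject")
    return out
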