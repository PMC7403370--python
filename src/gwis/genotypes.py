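"""Genotype container shared by the simulator, IO and QC layers.

A :class:`GenotypeSet` bundles a sample-by-variant dosage matrix (minor-allele
counts in ``[0, 2]``, ``NaN`` for missing) with per-variant metadata and,
optionally, genotype probability triplets ``(p_AA, p_AB, p_BB)`` where ``B``
is the minor allele. All per-variant summary statistics (MAF, call rate,
Hardy-Weinberg exact p, imputation INFO) are derived quantities and are
refreshed via :meth:`GenotypeSet.annotate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypeSet"]

#: columns every variant-metadata frame carries
VARIANT_COLUMNS = [
    "id", "chrom", "pos", "minor", "major",
    "maf", "call_rate", "hwe_p", "info",
]


@dataclass
class GenotypeSet:
    """Sample x variant dosages plus per-variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array of minor-allele dosages in
        ``[0, 2]``; missing entries are ``NaN``.
    variants
        Per-variant metadata frame with at least ``id``, ``chrom``, ``pos``,
        ``minor``, ``major``; summary columns are filled by :meth:`annotate`.
    sample_ids
        Length ``n_samples`` identifiers.
    probs
        Optional ``(n_samples, n_variants, 3)`` genotype probability
        triplets summing to 1 along the last axis.
    subpop
        Optional integer subpopulation labels (simulator only).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]
    probs: np.ndarray | None = None
    subpop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant metadata length does not match dosage columns")
        ok = np.isnan(self.dosages) | ((self.dosages >= -1e-9) & (self.dosages <= 2 + 1e-9))
        if not ok.all():
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != (n, m, 3):
                raise ValueError("probs must have shape (n_samples, n_variants, 3)")
        self.variants = self.variants.reset_index(drop=True)
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                self.variants[col] = np.nan

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "GenotypeSet":
        return GenotypeSet(
            dosages=self.dosages.copy(),
            variants=self.variants.copy(),
            sample_ids=list(self.sample_ids),
            probs=None if self.probs is None else self.probs.copy(),
            subpop=None if self.subpop is None else self.subpop.copy(),
        )

    # ------------------------------------------------------------------
    def annotate(self) -> "GenotypeSet":
        """Recompute per-variant MAF, call rate, HWE p and INFO in place."""
        from .qc import compute_maf, hwe_exact_test, impute_info

        g = self.dosages
        n = self.n_samples
        miss = np.isnan(g)
        call_rate = 1.0 - miss.mean(axis=0)
        maf = np.full(self.n_variants, np.nan)
        hwe = np.full(self.n_variants, np.nan)
        info = np.full(self.n_variants, np.nan)
        for j in range(self.n_variants):
            col = g[~miss[:, j], j]
            if col.size == 0:
                continue
            maf[j] = compute_maf(col)
            # HWE needs genotype classes; use best-guess calls
            calls = np.rint(col).astype(int)
            n_bb = int((calls == 2).sum())
            n_ab = int((calls == 1).sum())
            n_aa = int((calls == 0).sum())
            hwe[j] = hwe_exact_test(n_aa, n_ab, n_bb)
            if self.probs is not None:
                trip = self.probs[:, j, :]
                trip = trip[~np.isnan(trip).any(axis=1)]
                if len(trip):
                    info[j] = impute_info(trip)
        self.variants["maf"] = maf
        self.variants["call_rate"] = call_rate
        self.variants["hwe_p"] = hwe
        self.variants["info"] = info
        return self

    # ------------------------------------------------------------------
    def take_variants(self, index) -> "GenotypeSet":
        """Subset to the given variant positions (boolean mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeSet(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            probs=None if self.probs is None else self.probs[:, index, :],
            subpop=self.subpop,
        )

    def take_samples(self, index) -> "GenotypeSet":
        """Subset to the given sample positions (boolean mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeSet(
            dosages=self.dosages[index, :],
            variants=self.variants.copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            probs=None if self.probs is None else self.probs[index, :, :],
            subpop=None if self.subpop is None else self.subpop[index],
        )
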