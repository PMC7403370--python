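"""Genetic relationship matrix and principal-component covariates.

The GRM is the standard standardized-genotype cross-product
``G = Z Z' / M`` where column ``j`` of ``Z`` is ``(g_j - 2 f_j) /
sqrt(2 f_j (1 - f_j))`` over the ``M`` polymorphic variants; missing
dosages are mean-imputed (set to ``2 f_j``, i.e. zero after centering).
Its leading eigenvectors are the PC scores used as regression covariates
to absorb population substructure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .genotypes import GenotypeSet

__all__ = ["PCScores", "compute_grm", "compute_pcs"]


@dataclass
class PCScores:
    """Top-k eigenpairs of a GRM; columns of ``scores`` are unit-norm."""

    scores: np.ndarray        # (n_samples, k)
    eigenvalues: np.ndarray   # descending

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def compute_grm(genotypes: GenotypeSet) -> np.ndarray:
    """Standardized-dosage GRM over polymorphic variants."""
    g = genotypes.dosages
    n, m = g.shape
    if n < 2:
        raise ValueError("GRM needs at least two samples")
    freq = np.nanmean(g, axis=0) / 2.0
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    if not poly.any():
        raise ValueError("no polymorphic variants")
    g = g[:, poly]
    freq = freq[poly]
    z = (g - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))
    z = np.nan_to_num(z, nan=0.0)  # mean imputation: centered missing -> 0
    grm = z @ z.T / z.shape[1]
    return (grm + grm.T) / 2.0


def compute_pcs(grm: np.ndarray, k: int = 10) -> PCScores:
    """Top-k eigenpairs of a symmetric GRM with a deterministic sign
    convention (the largest-magnitude loading of each PC is positive)."""
    n = grm.shape[0]
    if grm.shape != (n, n):
        raise ValueError("grm must be square")
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("grm must be symmetric")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    vals, vecs = linalg.eigh(grm, subset_by_index=[n - k, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for i in range(k):
        j = np.argmax(np.abs(vecs[:, i]))
        if vecs[j, i] < 0:
            vecs[:, i] = -vecs[:, i]
    return PCScores(scores=vecs, eigenvalues=vals)
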