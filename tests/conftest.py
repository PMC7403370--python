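"""Shared fixtures: a small simulated study and a hand-built QC fixture."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

import gwis


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact-rational Hardy-Weinberg exact-test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    totals, weights each by ``2^h * n! / (h! hom_minor! hom_major!)`` (the
    conditional distribution given allele counts), and sums the weights
    that do not exceed the observed configuration's weight. Pure integer
    arithmetic, so ties are handled exactly.
    """
    n = n_aa + n_ab + n_bb
    r = 2 * min(n_aa, n_bb) + n_ab
    if r == 0:
        return Fraction(1)
    weights = {}
    for h in range(r % 2, min(r, 2 * n - r) + 1, 2):
        hom_minor = (r - h) // 2
        hom_major = n - h - hom_minor
        weights[h] = (2**h * factorial(n)
                      // (factorial(h) * factorial(hom_minor) * factorial(hom_major)))
    obs = weights[n_ab]
    return Fraction(sum(w for w in weights.values() if w <= obs),
                    sum(weights.values()))


@pytest.fixture(scope="session")
def small_study():
    """An 800-sample, 30-variant null study used by several test modules."""
    cfg = gwis.kare_config(n_samples=800,
                           maf_vector=np.linspace(0.10, 0.50, 30), seed=11)
    cohort = gwis.simulate_cohort(cfg)
    genotypes = gwis.simulate_genotypes(cfg)
    cohort = gwis.simulate_phenotype(cohort, None, None, cfg)
    return cfg, cohort, genotypes


def make_qc_fixture() -> gwis.GenotypeSet:
    """Five engineered variants, 200 samples: one failing each QC rule
    (HWE, MAF, call rate, INFO) and one passing everything.

    Dosages are hard calls; probability triplets are indicators except for
    the INFO-fail variant, whose triplets put 0.6 on the true class.
    """
    n = 200
    cols = {}
    # v_pass: 50/100/50, MAF 0.5, complete, certain
    cols["v_pass"] = np.repeat([0, 1, 2], [50, 100, 50]).astype(float)
    # v_hwe: 50/0/50 -> extreme heterozygote deficit
    cols["v_hwe"] = np.repeat([0, 2], [100, 100]).astype(float)
    # v_maf: 4 carriers of 400 alleles -> MAF 0.01
    cols["v_maf"] = np.repeat([0, 1], [196, 4]).astype(float)
    # v_call: 20 missing -> call rate 0.90
    v = np.repeat([0, 1, 2], [45, 90, 45]).astype(float)
    cols["v_call"] = np.concatenate([v, np.full(20, np.nan)])
    # v_info: hard calls fine, soft triplets (certainty 0.6) -> INFO ~ 0
    cols["v_info"] = np.repeat([0, 1, 2], [50, 100, 50]).astype(float)

    names = list(cols)
    g = np.column_stack([cols[c] for c in names])
    probs = np.full((n, len(names), 3), np.nan)
    for j, name in enumerate(names):
        col = g[:, j]
        for i in range(n):
            if np.isnan(col[i]):
                continue
            if name == "v_info":
                trip = np.full(3, 0.2)
                trip[int(col[i])] = 0.6
            else:
                trip = np.zeros(3)
                trip[int(col[i])] = 1.0
            probs[i, j, :] = trip
    variants = pd.DataFrame({
        "id": names, "chrom": 1, "pos": 1000 * (1 + np.arange(len(names))),
        "minor": "A", "major": "C",
    })
    gset = gwis.GenotypeSet(dosages=g, variants=variants,
                            sample_ids=[f"S{i:04d}" for i in range(n)],
                            probs=probs)
    return gset.annotate()


@pytest.fixture()
def qc_fixture():
    return make_qc_fixture()
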