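"""Readers/writers for the standard genotype and phenotype file formats.

PLINK 1 binary (bed/bim/fam, SNP-major) carries hard calls; Oxford
.gen/.sample carries genotype probability triplets; phenotypes travel as a
tab-delimited table with a fixed header. Allele 1 in the .bim is the minor
allele, so bed genotype codes map to minor-allele dosages directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet

__all__ = [
    "write_plink", "read_plink",
    "write_oxford", "read_oxford",
    "write_phenotype", "read_phenotype",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 bed, SNP-major
# bed 2-bit code -> minor-allele dosage (A1 = minor): 00 hom A1, 01 missing,
# 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2: 0, 1: 2, 0: 3}

PHENOTYPE_COLUMNS = ["sample_id", "fev1_fvc", "age", "sex", "bmi",
                     "smoking_status", "pack_years"]


# ----------------------------------------------------------------------
# PLINK bed/bim/fam
# ----------------------------------------------------------------------

def write_plink(genotypes: GenotypeSet, prefix, cohort: pd.DataFrame | None = None) -> None:
    """Write bed/bim/fam at ``prefix``. Dosages are rounded to hard calls."""
    prefix = Path(prefix)
    n, m = genotypes.dosages.shape
    g = genotypes.dosages
    codes = np.full((n, m), 1, dtype=np.uint8)  # default: missing
    nonmiss = ~np.isnan(g)
    hard = np.rint(g[nonmiss]).astype(int)
    codes[nonmiss] = np.array([_DOSAGE_TO_CODE[int(v)] for v in np.clip(hard, 0, 2)],
                              dtype=np.uint8)
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros((m, n_bytes), dtype=np.uint8)
        idx = np.arange(n)
        byte_i, shift = idx // 4, (idx % 4) * 2
        for j in range(m):
            np.add.at(buf[j], byte_i, codes[:, j] << shift)
        fh.write(buf.tobytes())

    v = genotypes.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"],
        "a1": v["minor"], "a2": v["major"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    if cohort is not None:
        cohort = cohort.set_index("sample_id").loc[genotypes.sample_ids]
        sex = np.where(cohort["sex"].to_numpy() == 1, 1, 2)
        pheno = cohort["fev1_fvc"].fillna(-9).to_numpy()
    else:
        sex = np.zeros(n, dtype=int)
        pheno = np.full(n, -9.0)
    fam = pd.DataFrame({
        "fid": genotypes.sample_ids, "iid": genotypes.sample_ids,
        "pat": 0, "mat": 0, "sex": sex, "pheno": pheno,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeSet:
    """Read bed/bim/fam into a :class:`GenotypeSet` (minor-allele dosages)."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK 1 bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    idx = np.arange(n)
    codes = (body[:, idx // 4] >> ((idx % 4) * 2)) & 0b11  # (m, n)
    dosages = _CODE_TO_DOSAGE[codes].T
    variants = pd.DataFrame({
        "id": bim["id"], "chrom": bim["chrom"], "pos": bim["pos"],
        "minor": bim["a1"], "major": bim["a2"],
    })
    gset = GenotypeSet(dosages=dosages, variants=variants,
                       sample_ids=fam["iid"].astype(str).tolist())
    gset.annotate()
    return gset


# ----------------------------------------------------------------------
# Oxford .gen/.sample (probability triplets)
# ----------------------------------------------------------------------

def write_oxford(genotypes: GenotypeSet, prefix) -> None:
    """Write .gen/.sample; allele A is the major, allele B the minor allele,
    so the expected B-dosage equals the stored minor-allele dosage."""
    if genotypes.probs is None:
        raise ValueError("genotype set has no probability triplets")
    prefix = Path(prefix)
    n, m, _ = genotypes.probs.shape
    v = genotypes.variants
    with open(prefix.with_suffix(".gen"), "w") as fh:
        for j in range(m):
            head = (f"{v['chrom'][j]} {v['id'][j]} {v['id'][j]} {v['pos'][j]} "
                    f"{v['major'][j]} {v['minor'][j]}")
            trip = genotypes.probs[:, j, :]
            trip = np.nan_to_num(trip, nan=0.0)  # missing -> 0 0 0 convention
            body = " ".join(f"{x:.6g}" for x in trip.ravel())
            fh.write(head + " " + body + "\n")
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in genotypes.sample_ids:
            fh.write(f"{sid} {sid} 0\n")


def read_oxford(gen_path, sample_path) -> GenotypeSet:
    """Read .gen/.sample; dosage is the expected minor-allele count; all-zero
    triplets are treated as missing."""
    samples = []
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    for row in lines[2:]:
        samples.append(row[1])
    n = len(samples)
    rows, meta = [], []
    with open(gen_path) as fh:
        for ln in fh:
            parts = ln.split()
            chrom, snpid, _rsid, pos, a_major, b_minor = parts[:6]
            trip = np.asarray(parts[6:], dtype=float).reshape(n, 3)
            meta.append((snpid, int(chrom), int(pos), b_minor, a_major))
            rows.append(trip)
    probs = np.stack(rows, axis=1)  # (n, m, 3)
    total = probs.sum(axis=2)
    missing = total < 1e-9
    probs[missing, :] = np.nan
    dosages = probs[:, :, 1] + 2.0 * probs[:, :, 2]
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "minor", "major"])
    gset = GenotypeSet(dosages=dosages, variants=variants, sample_ids=samples,
                       probs=probs)
    gset.annotate()
    return gset


# ----------------------------------------------------------------------
# phenotype table
# ----------------------------------------------------------------------

def write_phenotype(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS + ["stratum"] if c in cohort.columns]
    cohort[cols].to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks required columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df
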