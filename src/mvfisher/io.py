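"""Readers and writers for the standard GWAS file formats used here.

Covers PLINK binary genotypes (.bed/.bim/.fam, v1.00 SNP-major), a
plain TSV dosage matrix, phenotype/covariate TSVs keyed by FID/IID, and
the GCTA binary GRM triplet.  Also houses the exact Hardy-Weinberg test
and the SNP quality-control filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_sim import GenotypeData, Pedigree
from .grm import GRM
from .phenotype_sim import PhenotypeData

__all__ = [
    "write_plink",
    "read_plink",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "read_covariates",
    "write_grm_gcta",
    "read_grm_gcta",
    "write_grm_tsv",
    "hwe_exact_test",
    "qc_filter",
    "QCReport",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.00, SNP-major

# 2-bit PLINK codes, indexed by dosage of the A1 (counted) allele;
# missing (-1) is code 0b01.
_DOSAGE_TO_CODE = {0: 0b11, 1: 0b10, 2: 0b00, -1: 0b01}
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)


def _fam_frame(genotypes: GenotypeData) -> pd.DataFrame:
    n = genotypes.n_subjects
    ped = genotypes.pedigree
    if ped is not None:
        fid = np.array([f"FAM{f}" for f in ped.family_id])
        father = np.where(ped.role == "child",
                          [f"F{f}_P1" for f in ped.family_id], "0")
        mother = np.where(ped.role == "child",
                          [f"F{f}_P2" for f in ped.family_id], "0")
    else:
        fid = genotypes.subject_ids
        father = mother = np.repeat("0", n)
    return pd.DataFrame({
        "FID": fid,
        "IID": genotypes.subject_ids,
        "father": father,
        "mother": mother,
        "sex": 0,
        "phenotype": -9,
    })


def write_plink(genotypes: GenotypeData, prefix) -> None:
    """Write a .bed/.bim/.fam triplet.

    Chromosome/position are synthesized (chr 1, positions 1..S); alleles
    are labeled A/B with B the reference (counted, A1) allele, so a
    dosage of 2 means genotype BB.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = _fam_frame(genotypes)
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    s = genotypes.n_snps
    bim = pd.DataFrame({
        "chrom": 1,
        "snp": genotypes.snp_ids,
        "cm": 0,
        "pos": np.arange(1, s + 1),
        "a1": "B",
        "a2": "A",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    d = genotypes.dosages.astype(np.int8)
    codes = np.empty_like(d, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[d == dos] = code
    n = genotypes.n_subjects
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((s, 4 * n_bytes), dtype=np.uint8)
        padded[:, :n] = codes.T
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (
            (padded.reshape(s, n_bytes, 4) << shifts[None, None, :]).sum(axis=2)
        ).astype(np.uint8)
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypeData:
    """Read a .bed/.bim/.fam triplet; the counted allele is .bim A1.

    Missing genotype calls become dosage -1 (mean-imputed downstream).
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["FID", "IID", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype=str,
    )
    n, s = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(".bed magic number mismatch (not v1.00 SNP-major)")
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != s * n_bytes:
        raise ValueError(
            f".bed payload holds {payload.size} bytes but .fam/.bim imply "
            f"{s * n_bytes}"
        )
    codes = (
        payload.reshape(s, n_bytes)[:, :, None] >> np.array([0, 2, 4, 6])
    ) & 0b11
    dosages = _CODE_TO_DOSAGE[codes.reshape(s, -1)[:, :n]].T
    ped = None
    if (fam["father"] != "0").any():
        fam_idx = pd.factorize(fam["FID"])[0]
        role = np.where(fam["father"] != "0", "child", "parent1").astype(object)
        ped = Pedigree(
            family_id=fam_idx,
            role=role,
            parent_indices=np.full((n, 2), -1, dtype=int),
            parent_origin=np.repeat("unknown", fam_idx.max() + 1).astype(object),
        )
    return GenotypeData(
        dosages=dosages,
        subject_ids=fam["IID"].to_numpy(),
        snp_ids=bim["snp"].to_numpy(),
        pedigree=ped,
        chromosomes=bim["chrom"].to_numpy(),
    )


def write_dosage_tsv(genotypes: GenotypeData, path) -> None:
    fam = _fam_frame(genotypes)
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_ids)
    df = df.mask(df < 0)  # missing -> NA
    out = pd.concat([fam[["FID", "IID"]], df], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    if df.columns[:2].tolist() != ["FID", "IID"]:
        raise ValueError("dosage TSV must start with FID and IID columns")
    snp_cols = df.columns[2:]
    vals = df[snp_cols].to_numpy()
    dosages = np.full(vals.shape, -1, dtype=np.int8)
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            v = vals[i, j]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            fv = float(v)
            if fv not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"invalid dosage {v!r} at row {df['IID'].iloc[i]!r}, "
                    f"column {snp_cols[j]!r}: expected 0/1/2/NA"
                )
            dosages[i, j] = int(fv)
    return GenotypeData(
        dosages=dosages,
        subject_ids=df["IID"].to_numpy(),
        snp_ids=snp_cols.to_numpy(),
    )


def write_phenotypes(phenotypes: PhenotypeData, path, fids=None) -> None:
    fid = fids if fids is not None else phenotypes.subject_ids
    out = pd.DataFrame({"FID": fid, "IID": phenotypes.subject_ids})
    for j, name in enumerate(phenotypes.trait_names):
        out[name] = phenotypes.values[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table indexed by (FID, IID); trait columns numeric."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    if df.columns[:2].tolist() != ["FID", "IID"]:
        raise ValueError("phenotype TSV must start with FID and IID columns")
    return df


read_covariates = read_phenotypes


def write_grm_gcta(grm: GRM, prefix) -> None:
    """GCTA binary GRM triplet: grm.bin / grm.N.bin / grm.id
    (little-endian float32, lower triangle row by row)."""
    prefix = Path(prefix)
    n = grm.n_subjects
    il = np.tril_indices(n)
    grm.matrix[il].astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(il[0].shape, grm.n_snps_used, dtype="<f4").tofile(
        f"{prefix}.grm.N.bin"
    )
    pd.DataFrame({"FID": grm.subject_ids, "IID": grm.subject_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix) -> GRM:
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None,
                      names=["FID", "IID"], dtype=str)
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(float)
    il = np.tril_indices(n)
    if vals.size != il[0].size:
        raise ValueError("grm.bin size inconsistent with grm.id")
    k = np.zeros((n, n))
    k[il] = vals
    k = k + np.tril(k, -1).T
    n_snps = int(np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")[0])
    return GRM(matrix=k, n_snps_used=n_snps, subject_ids=ids["IID"].to_numpy())


def write_grm_tsv(grm: GRM, path) -> None:
    pd.DataFrame(
        grm.matrix, index=grm.subject_ids, columns=grm.subject_ids
    ).to_csv(path, sep="\t")


# --- QC ----------------------------------------------------------------


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton et al. style).

    Returns the probability, under HWE conditional on allele counts, of
    heterozygote counts at most as likely as the one observed.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # recurrence over heterozygote counts of the same parity as `rare`
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    h = mid
    while h >= 2:
        r = (n - (rare - h) // 2) - h  # common homozygotes at h
        probs[h - 2] = probs[h] * h * (h - 1) / (
            4.0 * ((rare - h) / 2 + 1) * (r + 1)
        )
        h -= 2
    h = mid
    while h <= rare - 2:
        rare_hom = (rare - h) // 2
        r = n - rare_hom - h
        probs[h + 2] = probs[h] * 4.0 * rare_hom * r / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    obs = probs[n_het] / total
    return min(1.0, sum(p for p in probs.values() if p / total <= obs * (1 + 1e-12)) / total)


@dataclass(frozen=True)
class QCReport:
    n_snps_in: int
    n_dropped_maf: int
    n_dropped_hwe: int
    n_dropped_missing: int
    n_snps_out: int


def qc_filter(
    genotypes: GenotypeData,
    maf_floor: float = 0.01,
    hwe_p_floor: float = 1e-5,
    missing_ceiling: float = 0.05,
) -> tuple[GenotypeData, QCReport]:
    """Drop SNPs failing MAF, exact-HWE or per-SNP missingness limits.

    A SNP is counted against the first criterion it fails, in the order
    missingness, MAF, HWE.
    """
    d = genotypes.dosages
    n = d.shape[0]
    miss_frac = (d < 0).sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        df = np.where(d < 0, np.nan, d.astype(float))
        p = np.nanmean(df, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)

    fail_miss = miss_frac >= missing_ceiling
    fail_maf = ~fail_miss & ~(maf > maf_floor)
    fail_hwe = np.zeros_like(fail_maf)
    for j in np.nonzero(~fail_miss & ~fail_maf)[0]:
        col = d[:, j]
        n_hom_ref = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 0).sum())
        if hwe_exact_test(n_het, n_hom_alt, n_hom_ref) <= hwe_p_floor:
            fail_hwe[j] = True
    keep = ~(fail_miss | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("QC removed every SNP")
    out = GenotypeData(
        dosages=d[:, keep],
        subject_ids=genotypes.subject_ids.copy(),
        snp_ids=genotypes.snp_ids[keep],
        pedigree=genotypes.pedigree,
    )
    report = QCReport(
        n_snps_in=d.shape[1],
        n_dropped_maf=int(fail_maf.sum()),
        n_dropped_hwe=int(fail_hwe.sum()),
        n_dropped_missing=int(fail_miss.sum()),
        n_snps_out=int(keep.sum()),
    )
    return out, report
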