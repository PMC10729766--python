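"""Genotype matrix I/O: PLINK additive text (.raw) and VCF, plus the
major-allele recoding used before model fitting.

Genotypes are held as integer counts of one named allele per SNP
(0 = homozygous in the other allele, 1 = heterozygous, 2 = homozygous in
the counted allele).  Model fitting expects the counted allele to be the
*minor* allele in the purebred training animals; :func:`recode_major_allele`
establishes and persists that orientation so that any later test data can
be recoded identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "CodedGenotypes",
    "read_genotypes",
    "read_raw",
    "read_vcf",
    "write_raw",
    "write_vcf",
    "recode_major_allele",
    "filter_snps",
]


@dataclass(frozen=True)
class SnpMap:
    """Per-SNP metadata: id, chromosome, 1-based physical position, the
    allele currently counted by the genotype coding, and the allele most
    frequent in the purebred training data (once recoding has run)."""

    ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    counted_allele: np.ndarray
    ref_major: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.ids)
        for name in ("chrom", "pos_bp", "counted_allele"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpMap field {name} has wrong length")
        if len(set(self.ids)) != n:
            raise ValueError("SNP ids must be unique")
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos_bp})
        for _, grp in df.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "counted_allele": self.counted_allele,
                "ref_major": self.ref_major if self.ref_major is not None else [None] * len(self),
            }
        )


@dataclass(frozen=True)
class CodedGenotypes:
    """n x p matrix of allele counts in {0, 1, 2} with SNP and sample metadata."""

    matrix: np.ndarray
    snps: SnpMap
    sample_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if m.shape[1] != len(self.snps):
            raise ValueError(f"matrix has {m.shape[1]} columns but SnpMap lists {len(self.snps)} SNPs")
        if m.shape[0] != len(self.sample_ids):
            raise ValueError("matrix row count does not match sample_ids")
        if not np.isin(m, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2 (missing calls are not accepted)")
        object.__setattr__(self, "matrix", m.astype(np.int8, copy=False))
        if self.labels is not None and len(self.labels) != m.shape[0]:
            raise ValueError("labels length does not match sample count")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def read_genotypes(path, format: str = "plink_raw") -> CodedGenotypes:
    """Read a genotype file; ``format`` is ``"plink_raw"`` or ``"vcf"``."""
    if format == "plink_raw":
        return read_raw(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}; use 'plink_raw' or 'vcf'")


def _load_sidecar(path: Path) -> dict | None:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return None


def read_raw(path) -> CodedGenotypes:
    """Read a PLINK additive-coding text file (.raw dialect).

    Expected layout: whitespace-separated, header row starting with
    FID IID (PAT MAT SEX PHENOTYPE optional), then one ``<snpid>_<allele>``
    column per SNP holding counts of ``<allele>``.  A ``<path>.json``
    sidecar written by :func:`write_raw` restores chromosome/position and
    recoding metadata; without one, SNPs are placed on a single dummy
    chromosome in column order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError(f"{path}: not a PLINK .raw file (no IID column)")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    ids, alleles = [], []
    for c in snp_cols:
        if "_" not in c:
            raise ValueError(f"{path}: SNP column {c!r} lacks the _<allele> suffix")
        snp_id, allele = c.rsplit("_", 1)
        ids.append(snp_id)
        alleles.append(allele)
    mat = df[snp_cols].to_numpy()
    if np.isnan(mat.astype(float)).any():
        raise ValueError(f"{path}: missing genotypes (NA) are not accepted")
    side = _load_sidecar(path)
    if side is not None:
        chrom = np.asarray(side["chrom"])
        pos = np.asarray(side["pos_bp"], dtype=np.int64)
        ref_major = np.asarray(side["ref_major"]) if side.get("ref_major") is not None else None
        counted = np.asarray(side.get("counted_allele", alleles))
    else:
        chrom = np.asarray(["0"] * len(ids))
        pos = np.arange(1, len(ids) + 1, dtype=np.int64)
        ref_major = None
        counted = np.asarray(alleles)
    snps = SnpMap(ids=np.asarray(ids), chrom=chrom, pos_bp=pos, counted_allele=counted, ref_major=ref_major)
    labels = list(df["FID"].astype(str)) if "FID" in df.columns else None
    return CodedGenotypes(matrix=mat.astype(np.int8), snps=snps, sample_ids=list(df["IID"].astype(str)), labels=labels)


def read_vcf(path) -> CodedGenotypes:
    """Read hard-called genotypes from a VCF (GT field; counts of ALT).

    Multi-allelic sites are skipped with a warning; missing genotypes are
    rejected because the models assume complete data.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, alts = [], [], [], []
    rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site {v.CHROM}:{v.POS} (alleles {v.REF},{','.join(v.ALT)})")
            continue
        gt = v.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        if np.any(gt == 2):
            raise ValueError(f"missing genotype at {v.CHROM}:{v.POS}; complete data required")
        counts = np.where(gt == 3, 2, gt)
        rows.append(counts.astype(np.int8))
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        alts.append(v.ALT[0])
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no biallelic sites found")
    snps = SnpMap(
        ids=np.asarray(ids),
        chrom=np.asarray(chroms),
        pos_bp=np.asarray(poss, dtype=np.int64),
        counted_allele=np.asarray(alts),
    )
    return CodedGenotypes(matrix=np.column_stack(rows), snps=snps, sample_ids=samples)


def read_phased_vcf(path) -> tuple[np.ndarray, SnpMap, list[str]]:
    """Read phased haplotypes (pipe-separated GT) back from a VCF written
    by :func:`write_vcf`: returns a 2n x p binary matrix (two consecutive
    rows per sample), the SNP map, and the sample ids."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, alts, refs = [], [], [], [], []
    cols = []
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site {v.CHROM}:{v.POS}")
            continue
        gts = np.asarray(v.genotypes)  # n x 3: allele_a, allele_b, phased
        if np.any(gts[:, :2] < 0):
            raise ValueError(f"missing genotype at {v.CHROM}:{v.POS}")
        if not np.all(gts[:, 2]):
            raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}; phased input required")
        cols.append(gts[:, :2].reshape(-1).astype(np.int8))
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        alts.append(v.ALT[0])
        refs.append(v.REF)
    vcf.close()
    snps = SnpMap(
        ids=np.asarray(ids),
        chrom=np.asarray(chroms),
        pos_bp=np.asarray(poss, dtype=np.int64),
        counted_allele=np.asarray(alts),
        ref_major=np.asarray(refs),
    )
    return np.column_stack(cols), snps, samples


def write_raw(geno: CodedGenotypes, path) -> None:
    """Write a .raw-compatible text file plus a JSON sidecar holding the
    SNP map and recoding state (counted allele, major allele per SNP)."""
    path = Path(path)
    cols = [f"{i}_{a}" for i, a in zip(geno.snps.ids, geno.snps.counted_allele)]
    fid = geno.labels if geno.labels is not None else geno.sample_ids
    df = pd.DataFrame(geno.matrix, columns=cols)
    df.insert(0, "FID", fid)
    df.insert(1, "IID", geno.sample_ids)
    df.insert(2, "PAT", 0)
    df.insert(3, "MAT", 0)
    df.insert(4, "SEX", 0)
    df.insert(5, "PHENOTYPE", -9)
    df.to_csv(path, sep=" ", index=False)
    side = {
        "chrom": [str(c) for c in geno.snps.chrom],
        "pos_bp": [int(x) for x in geno.snps.pos_bp],
        "counted_allele": [str(a) for a in geno.snps.counted_allele],
        "ref_major": None if geno.snps.ref_major is None else [str(a) for a in geno.snps.ref_major],
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(side, fh)


def write_vcf(haplotypes_by_sample: np.ndarray, snps: SnpMap, sample_ids: list[str], path) -> None:
    """Write phased haplotypes (2n x p binary matrix, sample-major row
    pairs) as a minimal VCF with pipe-separated GT fields.

    The counted allele is written as ALT so that re-reading with
    :func:`read_vcf` reproduces the coded matrix exactly.
    """
    hap = np.asarray(haplotypes_by_sample)
    if hap.shape[0] != 2 * len(sample_ids):
        raise ValueError("haplotype matrix must have two rows per sample")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crossbred\n")
        for c in pd.unique(snps.chrom):
            mask = snps.chrom == c
            fh.write(f"##contig=<ID={c},length={int(snps.pos_bp[mask].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        ref = snps.ref_major if snps.ref_major is not None else np.asarray(["A"] * len(snps))
        for j in range(len(snps)):
            gts = "\t".join(f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(len(sample_ids)))
            fh.write(
                f"{snps.chrom[j]}\t{snps.pos_bp[j]}\t{snps.ids[j]}\t{ref[j]}\t"
                f"{snps.counted_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def recode_major_allele(geno: CodedGenotypes, pb_mask: np.ndarray) -> tuple[CodedGenotypes, np.ndarray]:
    """Orient every SNP so the coded matrix counts the allele that is
    *least* frequent in the purebred training rows.

    ``pb_mask`` is a boolean row selector for the training animals.  For
    each SNP whose counted-allele frequency exceeds 0.5 in those rows, the
    column is flipped (x -> 2 - x) and the major allele recorded; at a
    frequency of exactly 0.5 the orientation as read is kept (tie-break,
    logged through :mod:`warnings`).  Returns the recoded genotypes and the
    boolean flip vector, which callers persist so that test data are
    recoded identically.  Idempotent.
    """
    pb_mask = np.asarray(pb_mask, dtype=bool)
    if pb_mask.shape[0] != geno.n:
        raise ValueError("pb_mask length must equal the number of samples")
    if not pb_mask.any():
        raise ValueError("pb_mask selects no training rows")
    freq = geno.matrix[pb_mask].mean(axis=0) / 2.0
    flip = freq > 0.5
    ties = np.flatnonzero(freq == 0.5)
    if ties.size:
        warnings.warn(f"{ties.size} SNP(s) with counted-allele frequency exactly 0.5 kept as read")
    mat = geno.matrix.copy()
    mat[:, flip] = 2 - mat[:, flip]
    counted = geno.snps.counted_allele.copy()
    # after recoding the counted allele is minor; ref_major is the other one
    ref_major = np.where(flip, geno.snps.counted_allele, _other_allele(geno.snps))
    counted = np.where(flip, _other_allele(geno.snps), counted)
    snps = replace(geno.snps, counted_allele=counted, ref_major=ref_major)
    return CodedGenotypes(matrix=mat, snps=snps, sample_ids=geno.sample_ids, labels=geno.labels), flip


def _other_allele(snps: SnpMap) -> np.ndarray:
    """Best-effort complement of the counted allele for bookkeeping: the
    major allele letter when known from ref_major, else a placeholder."""
    if snps.ref_major is not None:
        return np.where(snps.ref_major == snps.counted_allele, "N", snps.ref_major)
    return np.asarray(["N"] * len(snps))


def apply_flips(geno: CodedGenotypes, flip: np.ndarray, snps_recoded: SnpMap | None = None) -> CodedGenotypes:
    """Apply a persisted flip vector (from :func:`recode_major_allele` on
    training data) to a new dataset with the same SNP ordering."""
    flip = np.asarray(flip, dtype=bool)
    if flip.shape[0] != geno.p:
        raise ValueError("flip vector length must equal the number of SNPs")
    mat = geno.matrix.copy()
    mat[:, flip] = 2 - mat[:, flip]
    snps = snps_recoded if snps_recoded is not None else geno.snps
    return CodedGenotypes(matrix=mat, snps=snps, sample_ids=geno.sample_ids, labels=geno.labels)


def filter_snps(
    geno: CodedGenotypes, maf_min: float = 0.01, callrate_min: float = 0.9
) -> tuple[CodedGenotypes, dict]:
    """Drop SNPs below a minor-allele-frequency or call-rate threshold.

    Genotype matrices in this package are complete, so the call-rate filter
    only bites when a caller has marked missing entries (< 0) in a raw
    matrix before construction; it is kept for parity with standard chip QC
    (defaults 0.01 MAF, 0.9 call rate).  Returns the filtered genotypes and
    a report of removed counts.
    """
    if not (0 <= maf_min <= 1 and 0 <= callrate_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    freq = geno.matrix.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf >= maf_min
    keep = keep_maf  # complete data: call rate is 1 everywhere
    report = {
        "n_input": geno.p,
        "n_removed_maf": int((~keep_maf).sum()),
        "n_removed_callrate": 0,
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError("all SNPs removed by filtering; thresholds too strict for these data")
    idx = np.flatnonzero(keep)
    snps = SnpMap(
        ids=geno.snps.ids[idx],
        chrom=geno.snps.chrom[idx],
        pos_bp=geno.snps.pos_bp[idx],
        counted_allele=geno.snps.counted_allele[idx],
        ref_major=None if geno.snps.ref_major is None else geno.snps.ref_major[idx],
    )
    out = CodedGenotypes(matrix=geno.matrix[:, idx], snps=snps, sample_ids=geno.sample_ids, labels=geno.labels)
    return out, report
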