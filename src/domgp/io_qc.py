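"""Genotype I/O and quality control.

Genotypes live in a :class:`GenotypeMatrix`: an n x m matrix of additive
dosage codes counting copies of the second (A2) allele — 0 for A1A1, 1 for
the heterozygote, 2 for A2A2, with ``-1`` marking a missing call.  The
module reads and writes PLINK v1 binary filesets (bed/bim/fam, SNP-major)
and applies the standard marker quality-control cascade: individual
missingness, SNP missingness, minor allele frequency, and a Hardy–Weinberg
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "read_plink",
    "write_plink",
    "read_phenotypes",
    "write_phenotypes",
    "hwe_exact_test",
    "apply_qc",
]

#: sentinel dosage for a missing genotype call
MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK v1 2-bit genotype codes (per bit pair, first sample in the lowest
# pair): 00 = hom A1A1 (dosage 0), 01 = missing, 10 = het, 11 = hom A2A2.
_BED_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}

_BIM_COLUMNS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """n x m additive dosages plus per-SNP and per-individual metadata."""

    dosages: np.ndarray
    individual_ids: list[str]
    snp_meta: pd.DataFrame  # columns: chrom, snp_id, pos, a1, a2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.snp_meta) != m:
            raise ValueError(f"{len(self.snp_meta)} SNP records for {m} columns")
        ids = self.snp_meta["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup}")
        if (self.snp_meta["pos"] < 0).any():
            raise ValueError("negative SNP position")
        valid = np.isin(self.dosages, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2, missing}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individuals/SNPs."""
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
            individual_ids=[self.individual_ids[i] for i in rows],
            snp_meta=self.snp_meta.iloc[cols].reset_index(drop=True),
        )


@dataclass(frozen=True)
class QcThresholds:
    """Marker/individual QC cut-offs.

    Filters are strict, matching the usual reporting convention: a SNP is
    kept when MAF > ``min_maf``, missingness < ``max_snp_missing`` and HWE
    exact p > ``min_hwe_p``; an individual is removed when its missingness
    exceeds ``max_ind_missing``.
    """

    min_maf: float = 0.05
    max_snp_missing: float = 0.05
    min_hwe_p: float = 1e-6
    max_ind_missing: float = 0.10

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_snp_missing", "min_hwe_p", "max_ind_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    n_individuals_in: int
    n_snps_in: int
    individuals_removed: int
    snps_removed_missing: int
    snps_removed_maf: int
    snps_removed_hwe: int
    n_individuals_out: int
    n_snps_out: int
    removed_individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.individuals_removed + self.n_individuals_out != self.n_individuals_in:
            raise ValueError("individual counts do not partition the input")
        removed = (
            self.snps_removed_missing + self.snps_removed_maf + self.snps_removed_hwe
        )
        if removed + self.n_snps_out != self.n_snps_in:
            raise ValueError("SNP counts do not partition the input")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": [
                    "individual_missingness",
                    "snp_missingness",
                    "maf",
                    "hwe",
                    "surviving_individuals",
                    "surviving_snps",
                ],
                "count": [
                    self.individuals_removed,
                    self.snps_removed_missing,
                    self.snps_removed_maf,
                    self.snps_removed_hwe,
                    self.n_individuals_out,
                    self.n_snps_out,
                ],
            }
        )


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK v1 bed/bim/fam fileset (SNP-major) into dosages."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"), sep=r"\s+", header=None, names=_BIM_COLUMNS,
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {raw[:3]!r}")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f"{prefix}.bed: {len(raw)} bytes, expected {expected} "
            f"for {n} individuals x {m} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, lowest-order pair = first individual
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    meta = bim[["chrom", "snp_id", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages, list(fam["iid"]), meta)


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK v1 bed/bim/fam fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.dosages.shape
    lut = np.empty(256, dtype=np.uint8)  # dosage (int8 viewed as uint8) -> code
    lut[np.uint8(0)] = 0b00
    lut[np.uint8(1)] = 0b10
    lut[np.uint8(2)] = 0b11
    lut[np.uint8(np.int8(MISSING))] = 0b01
    codes = lut[geno.dosages.T.astype(np.uint8)]  # m x n
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    Path(str(prefix) + ".bed").write_bytes(_BED_MAGIC + packed.tobytes())

    bim = geno.snp_meta.copy()
    bim.insert(2, "cm", 0)
    bim[_BIM_COLUMNS].to_csv(
        Path(str(prefix) + ".bim"), sep="\t", header=False, index=False
    )
    fam = pd.DataFrame(
        {
            "fid": geno.individual_ids,
            "iid": geno.individual_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the tab-delimited phenotype/covariate table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: no 'id' column")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test probability.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts as probable or less probable than the observed
    one (the Wigginton/Cutler/Abecasis formulation used by PLINK, without
    the mid-p correction).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # possible heterozygote counts share the parity of n_rare
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    if het_max < het_min:  # monomorphic
        return 1.0
    hets = np.arange(het_min, het_max + 1, 2)
    # unnormalized probabilities via the recurrence
    # P(h+2)/P(h) = [ (n_rare-h)(2n-n_rare-h) ] / [ (h+2)(h+1) ] ... derived
    # from the hypergeometric-form conditional distribution.
    probs = np.empty(len(hets), dtype=float)
    probs[0] = 1.0
    for i in range(1, len(hets)):
        h = hets[i - 1]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[i] = probs[i - 1] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[(hets == n_Aa).argmax()] if n_Aa in hets else None
    if p_obs is None:  # observed het count inconsistent with allele counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------


def _snp_stats(dosages: np.ndarray):
    missing = dosages == MISSING
    n_obs = (~missing).sum(axis=0)
    d = np.where(missing, 0, dosages)
    n_aa = ((dosages == 2)).sum(axis=0)
    n_het = ((dosages == 1)).sum(axis=0)
    n_AA = ((dosages == 0)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    miss_rate = missing.mean(axis=0)
    return n_obs, n_AA, n_het, n_aa, p, maf, miss_rate


def apply_qc(
    geno: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC cascade and return survivors plus an itemized report.

    Filter order: (1) individual missingness, (2) SNP missingness, (3) MAF,
    (4) HWE exact test.  Each removed SNP is attributed to the first
    criterion it fails; per-SNP statistics use non-missing calls computed
    after step (1).
    """
    n_in, m_in = geno.dosages.shape

    ind_miss = (geno.dosages == MISSING).mean(axis=1)
    keep_ind = ind_miss <= thresholds.max_ind_missing
    removed_ids = [
        iid for iid, k in zip(geno.individual_ids, keep_ind) if not k
    ]
    d = geno.dosages[keep_ind]
    if d.shape[0] == 0:
        raise ValueError("QC removed every individual")

    n_obs, n_AA, n_het, n_aa, p, maf, miss_rate = _snp_stats(d)

    fail_missing = (miss_rate >= thresholds.max_snp_missing) | (n_obs == 0)
    fail_maf = ~fail_missing & ~(maf > thresholds.min_maf)
    candidates_hwe = ~fail_missing & ~fail_maf
    fail_hwe = np.zeros(m_in, dtype=bool)
    for j in np.flatnonzero(candidates_hwe):
        if hwe_exact_test(int(n_AA[j]), int(n_het[j]), int(n_aa[j])) <= thresholds.min_hwe_p:
            fail_hwe[j] = True
    keep_snp = ~(fail_missing | fail_maf | fail_hwe)
    if not keep_snp.any():
        raise ValueError("QC removed every SNP")

    out = GenotypeMatrix(
        dosages=d[:, keep_snp].copy(),
        individual_ids=[i for i, k in zip(geno.individual_ids, keep_ind) if k],
        snp_meta=geno.snp_meta.loc[keep_snp].reset_index(drop=True),
    )
    report = QcReport(
        n_individuals_in=n_in,
        n_snps_in=m_in,
        individuals_removed=int((~keep_ind).sum()),
        snps_removed_missing=int(fail_missing.sum()),
        snps_removed_maf=int(fail_maf.sum()),
        snps_removed_hwe=int(fail_hwe.sum()),
        n_individuals_out=out.n_individuals,
        n_snps_out=out.n_snps,
        removed_individual_ids=removed_ids,
    )
    return out, report
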