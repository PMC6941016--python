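"""Additive (G) and dominance (D) genomic relationship matrices.

The additive matrix follows the cross-product of centered dosages,
``G = M M' / sum_i 2 p_i q_i``, where column *i* of M holds the dosage of
the second allele centered by twice its frequency.  The dominance matrix
uses the heterozygosity coding centered by its Hardy–Weinberg expectation,
``h = 1 - 2pq`` for a heterozygote and ``-2pq`` for either homozygote,
scaled by ``sum_i 2 p_i q_i (1 - 2 p_i q_i)``.  With sample allele
frequencies and unrelated, non-inbred individuals both matrices have
expected diagonal 1 and expected off-diagonal 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, LinAlgError

from .io_qc import MISSING, GenotypeMatrix

__all__ = [
    "MarkerCodings",
    "RelationshipMatrix",
    "allele_frequencies",
    "marker_codings",
    "build_G",
    "build_D",
    "stabilize",
    "write_grm",
    "read_grm",
]

_BLOCK = 2048  # SNP columns per streaming block


@dataclass
class MarkerCodings:
    """Centered additive (M) and heterozygosity (H) codings."""

    freqs: np.ndarray  # per-SNP frequency of the second allele
    M: np.ndarray
    H: np.ndarray


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    kind: str  # "additive" | "dominance"
    scale_denominator: float
    freqs_used: np.ndarray
    ridge: float = 0.0
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "dominance"):
            raise ValueError(f"unknown kind {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.values[np.ix_(rows, cols)]


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Observed frequency of the second (A2) allele per SNP."""
    d = geno.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = geno.snp_meta["snp_id"].iloc[int(np.argmax(n_obs == 0))]
        raise ValueError(f"SNP {bad} has no non-missing calls")
    return np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)


def marker_codings(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> MarkerCodings:
    """Build the centered M and H codings (missing calls contribute 0)."""
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    d = geno.dosages.astype(float)
    miss = geno.dosages == MISSING
    two_pq = 2.0 * p * (1.0 - p)
    M = np.where(miss, 0.0, d - 2.0 * p)
    H = np.where(miss, 0.0, (geno.dosages == 1) - two_pq)
    return MarkerCodings(freqs=p, M=M, H=H)


def _crossprod(geno: GenotypeMatrix, p: np.ndarray, kind: str) -> np.ndarray:
    """Streamed n x n cross-product of the centered coding."""
    n, m = geno.dosages.shape
    out = np.zeros((n, n))
    for start in range(0, m, _BLOCK):
        sl = slice(start, min(start + _BLOCK, m))
        block = geno.subset(cols=np.arange(sl.start, sl.stop))
        cod = marker_codings(block, p[sl])
        W = cod.M if kind == "additive" else cod.H
        out += W @ W.T
    return out


def build_G(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """Additive genomic relationship matrix M M' / sum 2pq."""
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: sum 2pq = 0")
    values = _crossprod(geno, p, "additive") / denom
    return RelationshipMatrix(values, "additive", denom, p, ids=list(geno.individual_ids))


def build_D(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """Dominance genomic relationship matrix H H' / sum 2pq(1-2pq)."""
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    two_pq = 2.0 * p * (1.0 - p)
    denom = float(np.sum(two_pq * (1.0 - two_pq)))
    if denom <= 0:
        raise ValueError("sum 2pq(1-2pq) = 0; dominance matrix undefined")
    values = _crossprod(geno, p, "dominance") / denom
    return RelationshipMatrix(values, "dominance", denom, p, ids=list(geno.individual_ids))


def stabilize(rel: RelationshipMatrix, ridge: float = 1e-6) -> RelationshipMatrix:
    """Add ``ridge`` to the diagonal and verify positive definiteness."""
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    values = rel.values if ridge == 0 else rel.values + ridge * np.eye(rel.n)
    try:
        cholesky(values, lower=True)
    except LinAlgError as exc:
        raise ValueError(
            f"matrix not positive definite at ridge={ridge}; increase the ridge"
        ) from exc
    return RelationshipMatrix(
        values=values,
        kind=rel.kind,
        scale_denominator=rel.scale_denominator,
        freqs_used=rel.freqs_used,
        ridge=rel.ridge + ridge,
        ids=list(rel.ids),
    )


# ---------------------------------------------------------------------------
# GCTA-compatible GRM files (lower triangle, float32) + TSV for small n
# ---------------------------------------------------------------------------


def write_grm(rel: RelationshipMatrix, prefix: str | Path, tsv: bool = False) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = rel.n
    tri = rel.values[np.tril_indices(n)]
    Path(str(prefix) + ".grm.bin").write_bytes(tri.astype(np.float32).tobytes())
    ids = rel.ids or [str(i) for i in range(n)]
    pd.DataFrame({"fid": ids, "iid": ids}).to_csv(
        Path(str(prefix) + ".grm.id"), sep="\t", header=False, index=False
    )
    if tsv:
        pd.DataFrame(rel.values, index=ids, columns=ids).to_csv(
            Path(str(prefix) + ".grm.tsv"), sep="\t"
        )


def read_grm(prefix: str | Path, kind: str = "additive") -> RelationshipMatrix:
    prefix = Path(prefix)
    ids = pd.read_csv(
        Path(str(prefix) + ".grm.id"), sep="\t", header=None, names=["fid", "iid"],
        dtype=str,
    )
    n = len(ids)
    tri = np.frombuffer(Path(str(prefix) + ".grm.bin").read_bytes(), dtype=np.float32)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin size inconsistent with {n} ids")
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, -1).T
    return RelationshipMatrix(
        values, kind, scale_denominator=np.nan, freqs_used=np.array([]),
        ids=list(ids["iid"]),
    )
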