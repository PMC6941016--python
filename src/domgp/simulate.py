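"""Synthetic genotypes and phenotypes with known additive/dominance architecture.

The generator emulates a beef-cattle association/prediction cohort: a
thousand-odd animals genotyped on a dense autosomal SNP panel (scaled down
to 10^3–10^4 markers), with Hardy–Weinberg genotype frequencies at MAF ≥
0.05, optional full-sib family structure, and Gaussian phenotypes composed
of fixed effects (slaughter year, sex, entry body weight, fattening days),
breeding values, dominance deviations, and residual noise.

True breeding values use the centered additive dosage coding and true
dominance deviations the heterozygosity coding centered by 2pq — the same
codings the relationship matrices are built from — so variance-component
models downstream are correctly specified.  The three random parts are
orthogonalised in-sample and rescaled so the realized variance fractions
equal the configured heritabilities exactly, which makes parameter-recovery
tolerances tight and interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix, write_plink, write_phenotypes

__all__ = [
    "FixedEffectSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class FixedEffectSpec:
    """Levels and coefficients of the fixed part of the phenotype.

    Year and sex effects are per-level shifts (first level is the
    reference); the two covariates enter linearly.  Effects are in trait
    units; the genetic-plus-residual part of the trait is simulated with
    unit variance, so the defaults give the fixed part a visible but not
    dominating share.
    """

    year_effects: tuple[float, ...] = (0.0, 0.2, -0.1, 0.3, 0.15, -0.2)
    sex_effects: tuple[float, ...] = (0.0, 0.5)
    entry_weight_range: tuple[float, float] = (150.0, 250.0)
    entry_weight_coeff: float = 0.01
    fattening_days_range: tuple[int, int] = (120, 240)
    fattening_days_coeff: float = 0.005


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 1233
    n_snps: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_families: int = 0
    sibs_per_family: int = 0
    n_qtl_additive: int = 100
    n_qtl_dominance: int = 50
    h2_additive: float = 0.42
    h2_dominance: float = 0.158
    fixed_effects: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not (0.0 <= self.h2_additive < 1 and 0.0 <= self.h2_dominance < 1):
            raise ValueError("heritabilities must be in [0, 1)")
        if self.h2_additive + self.h2_dominance >= 1.0:
            raise ValueError("h2_additive + h2_dominance must be < 1")
        if min(self.n_individuals, self.n_snps) <= 0:
            raise ValueError("counts must be positive")
        if min(self.n_families, self.sibs_per_family, self.missing_rate) < 0:
            raise ValueError("counts and rates must be nonnegative")
        if max(self.n_qtl_additive, self.n_qtl_dominance) > self.n_snps:
            raise ValueError("more QTL requested than SNPs")
        if self.n_families * self.sibs_per_family > self.n_individuals:
            raise ValueError("family offspring exceed n_individuals")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # id, trait, year, sex, entry_weight, fattening_days
    true_breeding_values: np.ndarray
    true_dominance_deviations: np.ndarray
    true_qtl_table: pd.DataFrame  # snp_index, snp_id, a, d
    config: SimulationConfig

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Write PLINK fileset, phenotype TSV, and QTL truth TSV."""
        prefix = Path(prefix)
        write_plink(self.genotypes, prefix)
        pheno_path = Path(str(prefix) + ".pheno.tsv")
        write_phenotypes(self.phenotypes, pheno_path)
        truth_path = Path(str(prefix) + ".qtl.tsv")
        self.true_qtl_table.to_csv(truth_path, sep="\t", index=False)
        return {
            "bed": Path(str(prefix) + ".bed"),
            "bim": Path(str(prefix) + ".bim"),
            "fam": Path(str(prefix) + ".fam"),
            "pheno": pheno_path,
            "qtl": truth_path,
        }


def _mendelian_offspring(parent1: np.ndarray, parent2: np.ndarray, rng) -> np.ndarray:
    """Offspring dosages by independent transmission of one allele per parent."""
    def gamete(par: np.ndarray) -> np.ndarray:
        # hom 0 -> allele 0; hom 2 -> allele 1; het -> Bernoulli(1/2)
        draw = rng.random(par.shape) < 0.5
        return np.where(par == 1, draw.astype(np.int8), (par // 2).astype(np.int8))

    return gamete(parent1) + gamete(parent2)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None,
    inject_missing: bool = True,
) -> GenotypeMatrix:
    """Draw SNP genotypes under HWE with optional full-sib families."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_individuals, config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    n_off = config.n_families * config.sibs_per_family
    parts = []
    if n_off:
        for _ in range(config.n_families):
            parents = rng.binomial(2, p, size=(2, m)).astype(np.int8)
            sibs = np.stack(
                [
                    _mendelian_offspring(parents[0], parents[1], rng)
                    for _ in range(config.sibs_per_family)
                ]
            )
            parts.append(sibs)
    n_unrel = n - n_off
    if n_unrel:
        parts.append(rng.binomial(2, p, size=(n_unrel, m)).astype(np.int8))
    dosages = np.vstack(parts)

    if inject_missing and config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)

    fam_labels = np.concatenate(
        [np.repeat(np.arange(config.n_families), config.sibs_per_family),
         np.full(n_unrel, -1)]
    ).astype(int)
    ids = [
        f"fam{f}_ind{i}" if f >= 0 else f"ind{i}"
        for i, f in enumerate(fam_labels)
    ]
    meta = pd.DataFrame(
        {
            "chrom": np.repeat("1", m),
            "snp_id": [f"snp{j}" for j in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(dosages, ids, meta)


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Remove in-sample projections of v onto each (already centered) basis vector."""
    v = v - v.mean()
    for b in basis:
        nb = b @ b
        if nb > 0:
            v = v - (v @ b) / nb * b
    return v


def _scale_to_var(v: np.ndarray, target_var: float, what: str) -> np.ndarray:
    if target_var == 0:
        return np.zeros_like(v)
    s = v.std()
    if s == 0:
        raise ValueError(f"cannot reach nonzero variance target for {what}: zero raw variance")
    return v * (np.sqrt(target_var) / s)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Attach a trait with exact in-sample additive/dominance heritabilities.

    The genetic-plus-residual part has unit in-sample variance:
    var(breeding values) = h2_additive and var(dominance deviations) =
    h2_dominance exactly, with the three parts mutually orthogonal in-sample.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, m = geno.dosages.shape
    if n != config.n_individuals or m != config.n_snps:
        raise ValueError("genotype dimensions disagree with config")

    n_qtl = max(config.n_qtl_additive, config.n_qtl_dominance)
    qtl_idx = np.sort(rng.choice(m, size=n_qtl, replace=False)) if n_qtl else np.array([], int)
    a_raw = np.zeros(n_qtl)
    d_raw = np.zeros(n_qtl)
    a_raw[: config.n_qtl_additive] = rng.standard_normal(config.n_qtl_additive)
    d_raw[: config.n_qtl_dominance] = rng.standard_normal(config.n_qtl_dominance)

    # QTL dosages with missing calls mean-imputed (truth must not depend on
    # missingness; normally phenotypes are simulated before injection)
    dos = geno.dosages[:, qtl_idx].astype(float) if n_qtl else np.zeros((n, 0))
    if n_qtl:
        miss = geno.dosages[:, qtl_idx] == MISSING
        if miss.any():
            col_mean = np.where(miss, 0, dos).sum(0) / np.maximum((~miss).sum(0), 1)
            dos = np.where(miss, col_mean, dos)
    p = dos.mean(axis=0) / 2.0 if n_qtl else np.array([])
    two_pq = 2.0 * p * (1.0 - p)
    M = dos - 2.0 * p
    H = (np.isclose(dos, 1.0)).astype(float) - two_pq

    u_a_raw = M @ a_raw if n_qtl else np.zeros(n)
    u_d_raw = H @ d_raw if n_qtl else np.zeros(n)
    e_raw = rng.standard_normal(n)

    if config.h2_additive > 0 and u_a_raw.std() == 0:
        raise ValueError("h2_additive > 0 but additive genetic variance is zero")
    if config.h2_dominance > 0 and u_d_raw.std() == 0:
        raise ValueError("h2_dominance > 0 but dominance variance is zero")

    u_a = _scale_to_var(u_a_raw - u_a_raw.mean(), config.h2_additive, "breeding values")
    u_d = _scale_to_var(
        _orthogonalize(u_d_raw, [u_a]), config.h2_dominance, "dominance deviations"
    )
    h2_e = 1.0 - config.h2_additive - config.h2_dominance
    e = _scale_to_var(_orthogonalize(e_raw, [u_a, u_d]), h2_e, "residual")

    fe = config.fixed_effects
    year = rng.integers(0, len(fe.year_effects), size=n)
    sex = rng.integers(0, len(fe.sex_effects), size=n)
    entry_weight = rng.uniform(*fe.entry_weight_range, size=n)
    fattening_days = rng.integers(
        fe.fattening_days_range[0], fe.fattening_days_range[1] + 1, size=n
    )
    fixed_part = (
        np.asarray(fe.year_effects)[year]
        + np.asarray(fe.sex_effects)[sex]
        + fe.entry_weight_coeff * entry_weight
        + fe.fattening_days_coeff * fattening_days
    )

    trait = fixed_part + u_a + u_d + e
    pheno = pd.DataFrame(
        {
            "id": geno.individual_ids,
            "trait": trait,
            "year": year,
            "sex": sex,
            "entry_weight": entry_weight,
            "fattening_days": fattening_days,
        }
    )
    qtl_table = pd.DataFrame(
        {
            "snp_index": qtl_idx,
            "snp_id": geno.snp_meta["snp_id"].iloc[qtl_idx].to_numpy() if n_qtl else [],
            "a": a_raw,
            "d": d_raw,
        }
    )
    return SimulatedDataset(
        genotypes=geno,
        phenotypes=pheno,
        true_breeding_values=u_a,
        true_dominance_deviations=u_d,
        true_qtl_table=qtl_table,
        config=config,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genotypes then phenotypes from a single seeded RNG stream.

    Missing calls are injected only after the trait is computed, so the
    recorded truth is unaffected by missingness.
    """
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, rng, inject_missing=False)
    ds = simulate_phenotypes(geno, config, rng)
    if config.missing_rate > 0:
        mask = rng.random(geno.dosages.shape) < config.missing_rate
        dosages = np.where(mask, np.int8(MISSING), geno.dosages)
        ds.genotypes = GenotypeMatrix(dosages, geno.individual_ids, geno.snp_meta)
    return ds
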