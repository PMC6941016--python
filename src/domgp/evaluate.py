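"""Repeated k-fold cross-validation of genomic predictive ability.

Predictive ability is the correlation between predicted genetic values and
fixed-effect-corrected phenotypes of the validation individuals.  GBLUP and
GBLUP-D predict validation genetic values through the relationship-matrix
covariance between validation and training individuals; BayesA and BayesAD
predict from posterior-mean marker effects.  Relationship matrices and
marker codings are built once on all individuals (allele frequencies and
centering constants from the full data) and sub-matrixed per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayesad import BayesADHyper, build_designs, predict_genetic_values, run_chain
from .greml import TraitDesign, reml_fit
from .grm import RelationshipMatrix, build_D, build_G, stabilize
from .io_qc import GenotypeMatrix
from .simulate import SimulatedDataset

__all__ = [
    "MODELS",
    "CvPlan",
    "CvResult",
    "corrected_phenotypes",
    "make_folds",
    "cross_validate",
]

MODELS = ("GBLUP", "GBLUP-D", "BayesA", "BayesAD")

#: chain-length multiplier inside cross-validation (fidelity/runtime trade-off)
CV_CHAIN_SCALE = 0.5


@dataclass(frozen=True)
class CvPlan:
    k: int
    repeats: int
    seed: int
    assignments: np.ndarray = field(repr=False)  # repeats x n fold labels

    def folds(self, repeat: int):
        for f in range(self.k):
            val = np.flatnonzero(self.assignments[repeat] == f)
            train = np.flatnonzero(self.assignments[repeat] != f)
            yield f, train, val


@dataclass
class CvResult:
    cells: pd.DataFrame  # model, repeat, fold, r

    def summary(self) -> pd.DataFrame:
        return (
            self.cells.groupby("model")["r"]
            .agg(mean="mean", sd="std", n_folds="count")
            .reset_index()
        )

    def paired_difference(self, model_a: str, model_b: str) -> pd.DataFrame:
        a = self.cells[self.cells["model"] == model_a].set_index(["repeat", "fold"])["r"]
        b = self.cells[self.cells["model"] == model_b].set_index(["repeat", "fold"])["r"]
        return (a - b).rename("diff").reset_index()


def corrected_phenotypes(design: TraitDesign) -> np.ndarray:
    """Phenotypes minus the full-data OLS fixed-effect fit (mean ~ 0)."""
    X, y = design.X, design.y
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("X is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def make_folds(ids: list[str] | int, k: int, repeats: int, seed: int = 0) -> CvPlan:
    """Seeded random partitions with fold sizes within 1 of n/k."""
    n = ids if isinstance(ids, int) else len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    base = np.arange(n) % k  # balanced labels
    assignments = np.stack([rng.permutation(base) for _ in range(repeats)])
    return CvPlan(k=k, repeats=repeats, seed=seed, assignments=assignments)


def _predict_gblup(design, mats_full, vc, train, val, target):
    """Validation genetic values via the between-set covariance blocks."""
    n_t = len(train)
    Vt = vc.sigma_a2 * mats_full[0].submatrix(train) + vc.sigma_e2 * np.eye(n_t)
    if vc.sigma_d2 is not None:
        Vt += vc.sigma_d2 * mats_full[1].submatrix(train)
    Xt, yt = design.X[train], design.y[train]
    Vt_inv = np.linalg.inv(Vt)
    bhat = np.linalg.solve(Xt.T @ Vt_inv @ Xt, Xt.T @ Vt_inv @ yt)
    w = Vt_inv @ (yt - Xt @ bhat)
    a_val = vc.sigma_a2 * mats_full[0].submatrix(np.asarray(val), np.asarray(train)) @ w
    if target == "breeding" or vc.sigma_d2 is None:
        return a_val
    d_val = vc.sigma_d2 * mats_full[1].submatrix(np.asarray(val), np.asarray(train)) @ w
    return a_val + d_val


def cross_validate(
    dataset: SimulatedDataset | tuple[GenotypeMatrix, TraitDesign],
    models: tuple[str, ...] = ("GBLUP", "GBLUP-D"),
    plan: CvPlan | None = None,
    prediction_target: str = "breeding",
    bayes_hyper: BayesADHyper | None = None,
    h2_prior: float = 0.5,
    design: TraitDesign | None = None,
) -> CvResult:
    """Repeated k-fold CV of predictive ability for the requested models."""
    for mdl in models:
        if mdl not in MODELS:
            raise ValueError(f"unknown model {mdl!r}; choose from {MODELS}")
    if prediction_target not in ("breeding", "total"):
        raise ValueError("prediction_target must be 'breeding' or 'total'")

    if isinstance(dataset, SimulatedDataset):
        geno = dataset.genotypes
        if design is None:
            from .greml import build_trait_design

            design = build_trait_design(dataset.phenotypes)
    else:
        geno, design = dataset
    n = design.n
    plan = plan or make_folds(n, k=5, repeats=25, seed=0)

    corrected = corrected_phenotypes(design)
    need_gblup = any(m.startswith("GBLUP") for m in models)
    need_bayes = any(m.startswith("Bayes") for m in models)
    mats = None
    if need_gblup:
        G = stabilize(build_G(geno), 1e-6)
        D = stabilize(build_D(geno), 1e-6) if "GBLUP-D" in models else None
        mats = {"GBLUP": [G], "GBLUP-D": [G, D] if D is not None else None}
    designs_full = build_designs(geno) if need_bayes else None
    if need_bayes:
        from .bayesad import derive_scale

        hyper = bayes_hyper or BayesADHyper(
            n_iterations=4000, burn_in=1000, thinning=5
        )
        hyper = replace(
            hyper,
            n_iterations=max(200, int(hyper.n_iterations * CV_CHAIN_SCALE)),
            burn_in=max(50, int(hyper.burn_in * CV_CHAIN_SCALE)),
            s_alpha2=derive_scale(
                h2_prior, geno, hyper.nu_alpha, var_y=float(np.var(design.y))
            ),
        )

    rows = []
    for rep in range(plan.repeats):
        for fold, train, val in plan.folds(rep):
            cval = corrected[val]
            if np.std(cval) == 0:
                import warnings

                warnings.warn(
                    f"validation fold {rep}/{fold} has zero phenotypic variance",
                    RuntimeWarning,
                )
                for mdl in models:
                    rows.append((mdl, rep, fold, np.nan))
                continue
            d_train = design.subset(train)
            for mdl in models:
                if mdl.startswith("GBLUP"):
                    fold_mats = [
                        RelationshipMatrix(
                            m.submatrix(train), m.kind, m.scale_denominator,
                            m.freqs_used, ridge=m.ridge,
                        )
                        for m in mats[mdl]
                    ]
                    vc = reml_fit(d_train, fold_mats)
                    pred = _predict_gblup(
                        design, mats[mdl], vc, train, val, prediction_target
                    )
                else:
                    fold_designs = replace(
                        designs_full,
                        Wa=designs_full.Wa[train],
                        Wb=designs_full.Wb[train],
                    )
                    chain_seed = (hyper.seed + 10007 * rep + 101 * fold) % (2**31 - 1)
                    samples = run_chain(
                        d_train,
                        fold_designs,
                        replace(hyper, seed=chain_seed),
                        model="bayesA" if mdl == "BayesA" else "bayesAD",
                    )
                    bv, total = predict_genetic_values(
                        samples, designs_full.Wa[val], designs_full.Wb[val]
                    )
                    pred = bv if prediction_target == "breeding" else total
                r = float(np.corrcoef(pred, cval)[0, 1]) if np.std(pred) > 0 else np.nan
                rows.append((mdl, rep, fold, r))
    cells = pd.DataFrame(rows, columns=["model", "repeat", "fold", "r"])
    return CvResult(cells=cells)
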