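"""REML variance components, BLUP, heritabilities, and likelihood-ratio tests.

Fits the individual-level mixed model

    y = Xb + Za a + Zd d + e,
    a ~ N(0, G sigma_a^2),  d ~ N(0, D sigma_d^2),  e ~ N(0, I sigma_e^2)

by average-information REML with expectation–maximization fallback steps.
With G alone this is GBLUP; adding the dominance matrix D gives GBLUP-D.
The restricted log-likelihood at the optimum supports a likelihood-ratio
comparison of the two models; because the dominance variance is tested at
its zero boundary the test's null distribution is the mixture
(1/2) chi2_0 + (1/2) chi2_1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .grm import RelationshipMatrix

__all__ = [
    "TraitDesign",
    "VarianceComponents",
    "HeritabilityEstimates",
    "BlupSolution",
    "LrtResult",
    "build_trait_design",
    "reml_fit",
    "heritabilities",
    "blup_solve",
    "likelihood_ratio_test",
]

DEFAULT_CATEGORICAL = ("year", "sex")
DEFAULT_CONTINUOUS = ("entry_weight", "fattening_days")


@dataclass
class TraitDesign:
    """Phenotype vector and full-column-rank fixed-effects design."""

    y: np.ndarray
    X: np.ndarray
    column_names: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows do not match y length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient; drop aliased columns")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def subset(self, rows: np.ndarray) -> "TraitDesign":
        X = self.X[rows]
        # dummy columns can become empty (all-zero) in a subset; drop them
        keep = [0] + [
            j for j in range(1, X.shape[1]) if not np.allclose(X[:, j], X[0, j])
        ]
        return TraitDesign(
            y=self.y[rows],
            X=X[:, keep],
            column_names=[self.column_names[j] for j in keep],
            ids=[self.ids[i] for i in rows] if self.ids else [],
        )


def build_trait_design(
    pheno: pd.DataFrame,
    trait: str = "trait",
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
) -> TraitDesign:
    """Intercept + reference-level dummies + standardized covariates."""
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for c in categorical:
        if c not in pheno.columns:
            continue
        levels = sorted(pheno[c].unique())
        for lev in levels[1:]:  # first level is the reference
            cols.append((pheno[c] == lev).to_numpy(float))
            names.append(f"{c}[{lev}]")
    for c in continuous:
        if c not in pheno.columns:
            continue
        v = pheno[c].to_numpy(float)
        s = v.std()
        cols.append((v - v.mean()) / s if s > 0 else np.zeros_like(v))
        names.append(c)
    X = np.column_stack(cols)
    # drop aliased columns (e.g. a constant covariate)
    keep, r = [], 0
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > r:
            keep.append(j)
            r += 1
    return TraitDesign(
        y=pheno[trait].to_numpy(float),
        X=X[:, keep],
        column_names=[names[j] for j in keep],
        ids=list(pheno["id"]) if "id" in pheno.columns else [],
    )


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    sigma_d2: float | None = None
    logL: float = np.nan
    converged: bool = False
    n_iterations: int = 0
    trace: list[float] = field(default_factory=list)

    @property
    def components(self) -> list[float]:
        out = [self.sigma_a2]
        if self.sigma_d2 is not None:
            out.append(self.sigma_d2)
        out.append(self.sigma_e2)
        return out


@dataclass
class HeritabilityEstimates:
    h2_narrow: float
    h2_dominance: float
    h2_broad: float
    dominance_to_genetic: float


@dataclass
class BlupSolution:
    b_hat: np.ndarray
    a_hat: np.ndarray
    d_hat: np.ndarray | None = None


@dataclass
class LrtResult:
    chi2: float
    p_value: float  # boundary mixture (1/2 chi2_0 + 1/2 chi2_1)
    p_value_chi2_1: float  # plain 1-df chi-square
    df_nominal: int = 1


# ---------------------------------------------------------------------------
# Restricted likelihood machinery
# ---------------------------------------------------------------------------


def _reml_pieces(y, X, kernels, theta):
    """V, P y, log restricted likelihood, and P itself for given components."""
    n = len(y)
    V = np.zeros((n, n))
    for t, K in zip(theta, kernels):
        V += t * K
    c, low = cho_factor(V, lower=True)
    logdet_V = 2.0 * np.log(np.diag(c)).sum()
    Vinv = cho_solve((c, low), np.eye(n))
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cx = cho_factor(XtVinvX)
    logdet_XVX = 2.0 * np.log(np.diag(cx[0])).sum()
    P = Vinv - VinvX @ cho_solve(cx, VinvX.T)
    Py = P @ y
    logL = -0.5 * (logdet_V + logdet_XVX + y @ Py)
    return P, Py, logL


def restricted_loglik(
    design: TraitDesign, matrices: list[RelationshipMatrix], vc: VarianceComponents
) -> float:
    """Directly evaluated restricted log-likelihood at given components."""
    kernels = [m.values for m in matrices] + [np.eye(design.n)]
    _, _, logL = _reml_pieces(design.y, design.X, kernels, vc.components)
    return logL


def reml_fit(
    design: TraitDesign,
    matrices: list[RelationshipMatrix],
    tol_logL: float = 1e-6,
    tol_theta: float = 1e-4,
    max_iter: int = 200,
) -> VarianceComponents:
    """Average-information REML with EM fallback.

    ``matrices`` holds G alone (GBLUP) or G and D (GBLUP-D); the residual
    identity kernel is implicit.  Components are constrained nonnegative by
    clamping at 1e-8 x var(y) (the boundary is a legitimate optimum for a
    null dominance variance).
    """
    if not 1 <= len(matrices) <= 2:
        raise ValueError("provide one (G) or two (G, D) relationship matrices")
    y, X = design.y, design.X
    n = design.n
    for m in matrices:
        if m.n != n:
            raise ValueError("relationship matrix dimension does not match y")
    kernels = [m.values for m in matrices] + [np.eye(n)]
    k = len(kernels)
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vary
    theta = np.full(k, vary / k)

    P, Py, logL = _reml_pieces(y, X, kernels, theta)
    trace_log = [logL]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        KPy = [K @ Py for K in kernels]
        score = np.array(
            [-0.5 * (np.sum(P * K) - Py @ KPy[i]) for i, K in enumerate(kernels)]
        )
        AI = 0.5 * np.array(
            [[KPy[i] @ P @ KPy[j] for j in range(k)] for i in range(k)]
        )
        def try_ai(active: np.ndarray):
            try:
                delta = np.linalg.solve(AI[np.ix_(active, active)], score[active])
            except np.linalg.LinAlgError:
                return None
            if not np.isfinite(delta).all():
                return None
            cand = theta.copy()
            cand[active] = cand[active] + delta
            cand = np.maximum(cand, floor)
            try:
                P2, Py2, logL2 = _reml_pieces(y, X, kernels, cand)
            except np.linalg.LinAlgError:
                return None
            if logL2 >= logL - 1e-10:
                return cand, P2, Py2, logL2
            return None

        new_theta = None
        res = try_ai(np.arange(k))
        if res is None:
            # boundary-aware retry: freeze clamped components with an inward
            # (negative) score and update the rest
            free = (theta > 2 * floor) | (score > 0)
            if free.any() and not free.all():
                res = try_ai(np.flatnonzero(free))
        if res is not None:
            new_theta, P, Py, new_logL = res
        if new_theta is None:
            # EM step: theta_i' = theta_i + theta_i^2/n (y'P K P y - tr(P K))
            cand = np.maximum(
                theta + theta**2 / n * np.array(
                    [Py @ KPy[i] - np.sum(P * K) for i, K in enumerate(kernels)]
                ),
                floor,
            )
            P, Py, new_logL = _reml_pieces(y, X, kernels, cand)
            new_theta = cand

        d_logL = new_logL - logL
        # components parked at the boundary are excluded from the relative
        # change criterion (they rattle against the clamp)
        free = new_theta > 2 * floor
        rel = (
            np.max(np.abs(new_theta[free] - theta[free]) / np.maximum(theta[free], floor))
            if free.any()
            else 0.0
        )
        theta, logL = new_theta, new_logL
        trace_log.append(logL)
        if abs(d_logL) < tol_logL and rel < tol_theta:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations "
            f"(last dlogL={d_logL:.3g})",
            RuntimeWarning,
        )
    sigma_d2 = float(theta[1]) if k == 3 else None
    return VarianceComponents(
        sigma_a2=float(theta[0]),
        sigma_d2=sigma_d2,
        sigma_e2=float(theta[-1]),
        logL=float(logL),
        converged=converged,
        n_iterations=it,
        trace=trace_log,
    )


def heritabilities(vc: VarianceComponents) -> HeritabilityEstimates:
    """Variance ratios: narrow/dominance/broad h2 and sigma_d2/(sigma_d2+sigma_a2)."""
    sd2 = vc.sigma_d2 or 0.0
    total = vc.sigma_a2 + sd2 + vc.sigma_e2
    if total <= 0:
        raise ValueError("total variance must be positive")
    genetic = vc.sigma_a2 + sd2
    return HeritabilityEstimates(
        h2_narrow=vc.sigma_a2 / total,
        h2_dominance=sd2 / total,
        h2_broad=genetic / total,
        dominance_to_genetic=sd2 / genetic if genetic > 0 else 0.0,
    )


def blup_solve(
    design: TraitDesign,
    matrices: list[RelationshipMatrix],
    vc: VarianceComponents,
) -> BlupSolution:
    """Solve Henderson's mixed-model equations for fixed effects and BLUPs.

    With one record per individual (Z = I) the coefficient matrix is

        [ X'X      X'        (X')      ]
        [ X        I + Ginv*la  I      ]   la = sigma_e2/sigma_a2
        [ X        I        I + Dinv*ld]   ld = sigma_e2/sigma_d2
    """
    y, X = design.y, design.X
    n, p = X.shape
    comps = [vc.sigma_a2] + ([vc.sigma_d2] if vc.sigma_d2 is not None else [])
    if len(comps) != len(matrices):
        raise ValueError("components do not match number of matrices")
    if any(c <= 0 for c in comps) or vc.sigma_e2 <= 0:
        raise ValueError("all included variance components must be positive")
    lambdas = [vc.sigma_e2 / c for c in comps]
    kinvs = []
    for mat, lam in zip(matrices, lambdas):
        try:
            c = cho_factor(mat.values)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"{mat.kind} matrix is singular; stabilize() it with a ridge"
            ) from exc
        kinvs.append(cho_solve(c, np.eye(n)) * lam)

    q = len(matrices)
    dim = p + q * n
    C = np.empty((dim, dim))
    rhs = np.empty(dim)
    C[:p, :p] = X.T @ X
    rhs[:p] = X.T @ y
    eye = np.eye(n)
    for i in range(q):
        r = p + i * n
        C[:p, r : r + n] = X.T
        C[r : r + n, :p] = X
        rhs[r : r + n] = y
        for j in range(q):
            cblock = p + j * n
            C[r : r + n, cblock : cblock + n] = eye + (kinvs[i] if i == j else 0)
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular MME coefficient matrix; try a ridge") from exc
    b_hat = sol[:p]
    a_hat = sol[p : p + n]
    d_hat = sol[p + n : p + 2 * n] if q == 2 else None
    return BlupSolution(b_hat=b_hat, a_hat=a_hat, d_hat=d_hat)


def likelihood_ratio_test(logL_reduced: float, logL_full: float) -> LrtResult:
    """Boundary LRT of the dominance variance (full vs additive-only model)."""
    if not (np.isfinite(logL_reduced) and np.isfinite(logL_full)):
        raise ValueError("log-likelihoods must be finite")
    chi2 = 2.0 * (logL_full - logL_reduced)
    if chi2 < 0:
        warnings.warn(
            f"full-model logL below reduced-model logL by {-chi2/2:.3g}; "
            "clamping the LRT statistic to 0 (optimizer noise)",
            RuntimeWarning,
        )
        chi2 = 0.0
    p_plain = float(stats.chi2.sf(chi2, df=1))
    p_mix = 0.5 * p_plain
    return LrtResult(chi2=chi2, p_value=p_mix, p_value_chi2_1=p_plain)
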