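"""BayesA and BayesAD marker-effect models by Gibbs sampling with an MH step.

Model:  y = Xb + Wa alpha + Wb beta + e.

Per-SNP additive effects alpha_j carry the classic BayesA hierarchy — a
Gaussian effect whose variance sigma_alpha_j^2 has a scaled inverse
chi-square prior (nu_alpha, s_alpha^2), so the marginal effect prior is a
Student-t.  The dominance effect of SNP j (heterozygote coding) has the
conditional Gaussian prior beta_j ~ N(mu_beta, s_D^2 sigma_alpha_j^2),
taking additive and dominance effects as independent given the SNP
variance.  Fixed effects b and the residual variance sigma_e^2 carry flat
priors.

Sampling: fixed effects and per-SNP variances have conjugate conditionals.
For BayesA each alpha_j is drawn from its Gaussian conditional.  For
BayesAD, (alpha_j, beta_j) is updated jointly by a Metropolis–Hastings step
whose independence proposal draws alpha_j* from the BayesA-style Gaussian
conditional (ignoring the dominance column) and beta_j* from its
conditional prior; the prior and proposal terms then cancel so the
acceptance ratio reduces to a ratio of residual likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .greml import TraitDesign
from .io_qc import MISSING, GenotypeMatrix

__all__ = [
    "BayesADHyper",
    "MarkerDesigns",
    "MarkerEffectSamples",
    "build_designs",
    "derive_scale",
    "run_chain",
    "predict_genetic_values",
]


@dataclass(frozen=True)
class BayesADHyper:
    """Hyperparameters and chain settings.

    nu_alpha > 2 keeps the prior marker-effect variance
    var(alpha_j) = s_alpha2 * nu_alpha / (nu_alpha - 2) finite.
    """

    nu_alpha: float = 4.2
    s_alpha2: float = 1e-3
    s_D: float = 0.5
    mu_beta: float = 0.0
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nu_alpha <= 2:
            raise ValueError("nu_alpha must exceed 2 for a finite prior variance")
        if self.s_alpha2 <= 0 or self.s_D <= 0:
            raise ValueError("scale parameters must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class MarkerDesigns:
    """Column-centered additive (0/1/2) and heterozygote (0/1/0) codings."""

    Wa: np.ndarray
    Wb: np.ndarray
    means_a: np.ndarray
    means_b: np.ndarray
    n_missing_filled: int = 0

    def code_new(self, geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Code new individuals with the training centering constants."""
        Wa, Wb, _, _, _ = _raw_codings(geno)
        return Wa - self.means_a, Wb - self.means_b


def _raw_codings(geno: GenotypeMatrix):
    d = geno.dosages.astype(float)
    miss = geno.dosages == MISSING
    n_filled = int(miss.sum())
    if n_filled:
        col_mean = np.where(miss, 0, d).sum(0) / np.maximum((~miss).sum(0), 1)
        d = np.where(miss, col_mean, d)
    het = np.where(miss, 0.0, (geno.dosages == 1).astype(float))
    if n_filled:
        het_mean = het.sum(0) / np.maximum((~miss).sum(0), 1)
        het = np.where(miss, het_mean, het)
    return d, het, miss, n_filled, None


def build_designs(geno: GenotypeMatrix) -> MarkerDesigns:
    """Dosage and heterozygote incidence matrices, column-centered."""
    d, het, _, n_filled, _ = _raw_codings(geno)
    ma, mb = d.mean(axis=0), het.mean(axis=0)
    return MarkerDesigns(Wa=d - ma, Wb=het - mb, means_a=ma, means_b=mb,
                         n_missing_filled=n_filled)


def derive_scale(h2_target: float, geno: GenotypeMatrix, nu_alpha: float,
                 var_y: float = 1.0) -> float:
    """Scale s_alpha2 so the implied total additive variance hits the target.

    Inverts var(alpha_j) * sum_i 2 p_i q_i = h2 * var(y) with
    var(alpha_j) = s_alpha2 * nu / (nu - 2):

        s_alpha2 = h2 * var(y) * (nu - 2) / (nu * sum 2pq)
    """
    if not 0 < h2_target < 1:
        raise ValueError("h2_target must be in (0, 1)")
    if nu_alpha <= 2:
        raise ValueError("nu_alpha must exceed 2")
    from .grm import allele_frequencies

    p = allele_frequencies(geno)
    sum_2pq = float(np.sum(2.0 * p * (1.0 - p)))
    if sum_2pq <= 0:
        raise ValueError("sum 2pq = 0; genotypes are degenerate")
    return h2_target * var_y * (nu_alpha - 2.0) / (nu_alpha * sum_2pq)


@dataclass
class MarkerEffectSamples:
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    b_mean: np.ndarray
    sigma_e2_mean: float
    sigma_e2_draws: np.ndarray
    acceptance_rate: float
    n_draws: int
    model: str
    designs: MarkerDesigns | None = None
    alpha_draws: np.ndarray | None = None
    beta_draws: np.ndarray | None = None


def run_chain(
    design: TraitDesign,
    designs: MarkerDesigns,
    hyper: BayesADHyper,
    model: str = "bayesAD",
    keep_draws: bool = False,
) -> MarkerEffectSamples:
    """Run the Gibbs (BayesA) or Gibbs+MH (BayesAD) chain."""
    if model not in ("bayesA", "bayesAD"):
        raise ValueError("model must be 'bayesA' or 'bayesAD'")
    dominance = model == "bayesAD"
    rng = np.random.default_rng(hyper.seed)
    y, X = design.y, design.X
    Wa, Wb = designs.Wa, designs.Wb
    n, m = Wa.shape
    p = X.shape[1]

    XtX = X.T @ X
    XtX_chol = np.linalg.cholesky(np.linalg.inv(XtX))
    wa_ss = (Wa**2).sum(axis=0)
    wb_ss = (Wb**2).sum(axis=0)
    wab = (Wa * Wb).sum(axis=0)

    b = np.linalg.lstsq(X, y, rcond=None)[0]
    alpha = np.zeros(m)
    beta = np.zeros(m)
    sigma_a2 = np.full(m, hyper.s_alpha2)
    resid = y - X @ b
    sigma_e2 = float(np.var(resid)) or 1.0

    n_kept = (hyper.n_iterations - hyper.burn_in) // hyper.thinning
    alpha_acc = np.zeros(m)
    alpha_sq = np.zeros(m)
    beta_acc = np.zeros(m)
    beta_sq = np.zeros(m)
    b_acc = np.zeros(p)
    se2_draws = np.empty(n_kept)
    a_draws = np.empty((n_kept, m)) if keep_draws else None
    bt_draws = np.empty((n_kept, m)) if keep_draws and dominance else None
    kept = 0
    mh_accept = 0
    mh_total = 0
    nu, s2, sD2, mu_b = hyper.nu_alpha, hyper.s_alpha2, hyper.s_D**2, hyper.mu_beta

    for sweep in range(hyper.n_iterations):
        # --- fixed effects: flat prior => Gaussian around the LS fit of the
        # current partial residual
        resid += X @ b
        b = np.linalg.solve(XtX, X.T @ resid) + np.sqrt(sigma_e2) * (
            XtX_chol @ rng.standard_normal(p)
        )
        resid -= X @ b

        # --- per-SNP variances: scaled inverse chi-square conditional
        if dominance:
            df = nu + 2.0
            ssq = nu * s2 + alpha**2 + (beta - mu_b) ** 2 / sD2
        else:
            df = nu + 1.0
            ssq = nu * s2 + alpha**2
        sigma_a2 = ssq / rng.chisquare(df, size=m)

        # --- marker effects
        if dominance:
            log_u = np.log(rng.random(m))  # MH uniforms
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m) if dominance else None
        for j in range(m):
            wa = Wa[:, j]
            a_cur = alpha[j]
            # wa . r_j where r_j is the residual with SNP j's effects restored
            va = wa @ resid
            if dominance:
                b_cur = beta[j]
                war = va + a_cur * wa_ss[j] + b_cur * wab[j]
            else:
                war = va + a_cur * wa_ss[j]
            prec = wa_ss[j] / sigma_e2 + 1.0 / sigma_a2[j]
            mean = (war / sigma_e2) / prec
            a_new = mean + z1[j] / np.sqrt(prec)
            if dominance:
                wb = Wb[:, j]
                b_new = mu_b + np.sqrt(sD2 * sigma_a2[j]) * z2[j]
                wbr = wb @ resid + a_cur * wab[j] + b_cur * wb_ss[j]
                # ||r_j - wa a - wb b||^2 - ||r_j - wa a||^2 as a scalar form:
                # t(a, b) = -2 b (wb.r_j) + 2 a b (wa.wb) + b^2 (wb.wb)
                t_new = (
                    -2.0 * b_new * wbr
                    + 2.0 * a_new * b_new * wab[j]
                    + b_new**2 * wb_ss[j]
                )
                t_cur = (
                    -2.0 * b_cur * wbr
                    + 2.0 * a_cur * b_cur * wab[j]
                    + b_cur**2 * wb_ss[j]
                )
                mh_total += 1
                # log ratio of residual likelihoods; proposal/prior cancel
                if log_u[j] < (t_cur - t_new) / (2.0 * sigma_e2):
                    mh_accept += 1
                    resid -= wa * (a_new - a_cur) + wb * (b_new - b_cur)
                    alpha[j], beta[j] = a_new, b_new
            else:
                alpha[j] = a_new
                resid -= wa * (a_new - a_cur)
        # --- residual variance: flat prior => SSR / chi2(n-2)
        ssr = resid @ resid
        sigma_e2 = float(ssr / rng.chisquare(n - 2))
        if not np.isfinite(sigma_e2) or sigma_e2 <= 0:
            raise RuntimeError(
                f"residual variance diverged at sweep {sweep}: {sigma_e2}"
            )

        if sweep >= hyper.burn_in and (sweep - hyper.burn_in) % hyper.thinning == 0:
            if kept < n_kept:
                alpha_acc += alpha
                alpha_sq += alpha**2
                beta_acc += beta
                beta_sq += beta**2
                b_acc += b
                se2_draws[kept] = sigma_e2
                if keep_draws:
                    a_draws[kept] = alpha
                    if dominance:
                        bt_draws[kept] = beta
                kept += 1

    alpha_mean = alpha_acc / kept
    beta_mean = beta_acc / kept
    acc_rate = mh_accept / mh_total if mh_total else 1.0
    if dominance and acc_rate < 0.01:
        import warnings

        warnings.warn(f"MH acceptance rate {acc_rate:.3f} below 1%", RuntimeWarning)
    return MarkerEffectSamples(
        alpha_mean=alpha_mean,
        alpha_sd=np.sqrt(np.maximum(alpha_sq / kept - alpha_mean**2, 0.0)),
        beta_mean=beta_mean,
        beta_sd=np.sqrt(np.maximum(beta_sq / kept - beta_mean**2, 0.0)),
        b_mean=b_acc / kept,
        sigma_e2_mean=float(se2_draws.mean()),
        sigma_e2_draws=se2_draws,
        acceptance_rate=float(acc_rate),
        n_draws=kept,
        model=model,
        designs=designs,
        alpha_draws=a_draws,
        beta_draws=bt_draws,
    )


def predict_genetic_values(
    samples: MarkerEffectSamples, Wa: np.ndarray, Wb: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(breeding values, total genetic values) from posterior-mean effects.

    ``Wa``/``Wb`` must be coded and centered with the training constants
    (see :meth:`MarkerDesigns.code_new`).
    """
    if Wa.shape[1] != samples.alpha_mean.shape[0]:
        raise ValueError("Wa columns do not match the number of marker effects")
    bv = Wa @ samples.alpha_mean
    total = bv.copy()
    if samples.model == "bayesAD":
        if Wb is None:
            raise ValueError("Wb required for a bayesAD prediction")
        total = bv + Wb @ samples.beta_mean
    return bv, total
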