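"""Multi-locus mixed-model (MLMM) association scan with dominance effects.

Each SNP is tested in a generalized-least-squares fit under the covariance
sigma_a^2 G (+ sigma_d^2 D) + sigma_e^2 I, entering both its additive
(centered dosage) and dominance (centered heterozygote) codings jointly and
reporting a marginal Wald p-value per coding.  The multi-locus scan adds
the most significant marker as a fixed cofactor, re-estimates variance
components, and repeats until nothing passes the threshold, then
backward-eliminates cofactors that are no longer significant.  Surviving
hits are classified A, D, or A+D by which codings pass, and annotated with
the nearest gene within 100 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, solve_triangular

from .grm import RelationshipMatrix
from .greml import TraitDesign, VarianceComponents, reml_fit
from .io_qc import GenotypeMatrix
from .bayesad import build_designs

__all__ = [
    "ScanConfig",
    "GwasHit",
    "GeneAnnotation",
    "single_marker_test",
    "scan_all_markers",
    "mlmm_scan",
    "annotate_hits",
    "read_gene_table",
]

logger = logging.getLogger(__name__)

#: maximum SNP-to-gene distance for annotation (bp)
ANNOTATION_WINDOW = 100_000


@dataclass(frozen=True)
class ScanConfig:
    """MLMM scan settings.

    The default threshold is Bonferroni over the number of marginal tests
    actually performed — two per SNP (additive and dominance codings) when
    dominance is scanned — i.e. 0.05/(2m); 0.05/m when only the additive
    coding is tested.  A fixed printed cutoff can be supplied instead.
    """

    significance_threshold: float | None = None  # None => 0.05 / n_snps
    max_forward_steps: int = 10
    variance_strategy: str = "refit-per-step"  # or "fixed-after-null"
    include_dominance_kinship: bool = True

    def __post_init__(self) -> None:
        t = self.significance_threshold
        if t is not None and not 0 < t < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.max_forward_steps < 1:
            raise ValueError("max_forward_steps must be >= 1")
        if self.variance_strategy not in ("refit-per-step", "fixed-after-null"):
            raise ValueError(f"unknown variance_strategy {self.variance_strategy!r}")

    def threshold_for(self, n_snps: int, n_codings: int = 2) -> float:
        return self.significance_threshold or 0.05 / (n_snps * n_codings)


@dataclass
class GwasHit:
    snp_id: str
    snp_index: int
    chromosome: str
    position: int
    effect_class: str  # "A" | "D" | "A+D"
    p_additive: float | None
    p_dominance: float | None
    step_found: int


@dataclass
class GeneAnnotation:
    gene_name: str | None
    relation: str  # "within" | "upstream" | "downstream" | "none"
    distance: int


def _whitening(matrices: list[RelationshipMatrix], vc: VarianceComponents, n: int):
    """Lower Cholesky factor of V = sa2 G (+ sd2 D) + se2 I."""
    V = vc.sigma_a2 * matrices[0].values + vc.sigma_e2 * np.eye(n)
    if len(matrices) == 2:
        if vc.sigma_d2 is None:
            raise ValueError("two matrices supplied but sigma_d2 is absent")
        V += vc.sigma_d2 * matrices[1].values
    c, low = cho_factor(V, lower=True)
    return np.tril(c)


def _gls_joint_pvalues(yw, Xw, waw, wbw):
    """Marginal Wald p-values for the two SNP codings in a whitened LS fit."""
    cols = [c for c in (waw, wbw) if c is not None]
    Z = np.column_stack([Xw] + cols)
    q = Xw.shape[1]
    XtX = Z.T @ Z
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None, None
    bhat = XtX_inv @ (Z.T @ yw)
    # after whitening the fit is ordinary LS; t reference with residual df
    # keeps the extreme tail honest at moderate n
    resid = yw - Z @ bhat
    df = max(len(yw) - Z.shape[1], 1)
    s2 = (resid @ resid) / df
    se = np.sqrt(np.diag(XtX_inv) * s2)
    z = bhat / se
    pvals = 2.0 * stats.t.sf(np.abs(z), df)
    p_add = float(pvals[q]) if waw is not None else None
    p_dom = (
        float(pvals[q + 1])
        if wbw is not None and waw is not None
        else (float(pvals[q]) if wbw is not None else None)
    )
    return p_add, p_dom


def single_marker_test(
    design: TraitDesign,
    matrices: list[RelationshipMatrix],
    vc: VarianceComponents,
    snp_additive: np.ndarray,
    snp_dominance: np.ndarray | None,
    cofactors: np.ndarray | None = None,
) -> tuple[float | None, float | None]:
    """Test one SNP (both codings jointly) under the fitted covariance.

    Returns (p_additive, p_dominance); a p-value is ``None`` when the
    corresponding coding is untestable (zero variance / collinear).
    """
    n = design.n
    L = _whitening(matrices, vc, n)
    X = design.X if cofactors is None else np.column_stack([design.X, cofactors])
    yw = solve_triangular(L, design.y, lower=True)
    Xw = solve_triangular(L, X, lower=True)

    def whiten_col(col):
        if col is None:
            return None
        col = col - col.mean()
        if np.allclose(col, 0):
            return None
        w = solve_triangular(L, col, lower=True)
        # residual variance after projecting on Xw: guards collinearity
        resid = w - Xw @ np.linalg.lstsq(Xw, w, rcond=None)[0]
        if resid @ resid < 1e-10 * (w @ w + 1e-30):
            return None
        return w

    waw = whiten_col(np.asarray(snp_additive, float))
    wbw = whiten_col(None if snp_dominance is None else np.asarray(snp_dominance, float))
    if waw is None and wbw is None:
        return None, None
    return _gls_joint_pvalues(yw, Xw, waw, wbw)


def scan_all_markers(
    design: TraitDesign,
    Wa: np.ndarray,
    Wb: np.ndarray,
    matrices: list[RelationshipMatrix],
    vc: VarianceComponents,
    cofactor_idx: list[int],
    exclude: set[int] | None = None,
) -> pd.DataFrame:
    """Vectorized single-pass scan of all markers; returns p-value table."""
    n, m = Wa.shape
    L = _whitening(matrices, vc, n)
    cof = Wa[:, cofactor_idx] if cofactor_idx else None
    X = design.X if cof is None else np.column_stack([design.X, cof])
    yw = solve_triangular(L, design.y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    Waw = solve_triangular(L, Wa, lower=True)
    Wbw = solve_triangular(L, Wb, lower=True)
    # residualize against fixed part (QR projection)
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    Ar = Waw - Q @ (Q.T @ Waw)
    Br = Wbw - Q @ (Q.T @ Wbw)

    aa = (Ar * Ar).sum(0)
    bb = (Br * Br).sum(0)
    ab = (Ar * Br).sum(0)
    ay = Ar.T @ yr
    by = Br.T @ yr
    det = aa * bb - ab * ab
    yy = yr @ yr
    df2 = max(n - X.shape[1] - 2, 1)  # residual df, both codings fitted
    df1 = max(n - X.shape[1] - 1, 1)
    eps_a = 1e-10 * (Waw * Waw).sum(0)
    eps_b = 1e-10 * (Wbw * Wbw).sum(0) + 1e-30

    p_add = np.full(m, np.nan)
    p_dom = np.full(m, np.nan)
    skip = exclude or set()
    ok_a = aa > eps_a
    ok_b = bb > eps_b
    both = ok_a & ok_b & (det > 1e-12 * np.maximum(aa * bb, 1e-30))
    # joint 2x2 solve where both codings are testable
    with np.errstate(divide="ignore", invalid="ignore"):
        ba = (bb * ay - ab * by) / det
        bd = (aa * by - ab * ay) / det
        ssr2 = yy - ba * ay - bd * by  # residual SS of the joint fit
        s2_2 = np.maximum(ssr2, 0.0) / df2
        se_a = np.sqrt(bb / det * s2_2)
        se_d = np.sqrt(aa / det * s2_2)
        p_add_j = 2.0 * stats.t.sf(np.abs(ba / se_a), df2)
        p_dom_j = 2.0 * stats.t.sf(np.abs(bd / se_d), df2)
        # single-coding fallbacks
        s2_a = np.maximum(yy - ay**2 / aa, 0.0) / df1
        s2_b = np.maximum(yy - by**2 / bb, 0.0) / df1
        p_add_s = 2.0 * stats.t.sf(np.abs(ay / np.sqrt(aa * s2_a)), df1)
        p_dom_s = 2.0 * stats.t.sf(np.abs(by / np.sqrt(bb * s2_b)), df1)
    p_add[both] = p_add_j[both]
    p_dom[both] = p_dom_j[both]
    only_a = ok_a & ~both
    only_b = ok_b & ~both
    p_add[only_a] = p_add_s[only_a]
    p_dom[only_b] = p_dom_s[only_b]
    if skip:
        idx = np.fromiter(skip, int)
        p_add[idx] = np.nan
        p_dom[idx] = np.nan
    return pd.DataFrame({"p_additive": p_add, "p_dominance": p_dom})


def mlmm_scan(
    design: TraitDesign,
    geno: GenotypeMatrix,
    matrices: list[RelationshipMatrix],
    config: ScanConfig = ScanConfig(),
) -> list[GwasHit]:
    """Forward-inclusion / backward-elimination multi-locus mixed-model scan."""
    designs = build_designs(geno)
    Wa, Wb = designs.Wa, designs.Wb
    m = Wa.shape[1]
    threshold = config.threshold_for(m)
    mats = matrices if config.include_dominance_kinship else matrices[:1]

    def fit_vc(cofactor_idx):
        X = (
            design.X
            if not cofactor_idx
            else np.column_stack([design.X, Wa[:, cofactor_idx]])
        )
        d = TraitDesign(
            y=design.y, X=X,
            column_names=design.column_names + [f"cof{j}" for j in cofactor_idx],
            ids=design.ids,
        )
        return reml_fit(d, mats)

    cofactors: list[int] = []
    step_found: dict[int, int] = {}
    vc = fit_vc([])
    for step in range(1, config.max_forward_steps + 1):
        table = scan_all_markers(
            design, Wa, Wb, mats, vc, cofactors, exclude=set(cofactors)
        )
        pmin = np.fmin(
            np.nan_to_num(table["p_additive"].to_numpy(), nan=1.0),
            np.nan_to_num(table["p_dominance"].to_numpy(), nan=1.0),
        )
        best = int(np.argmin(pmin))
        if pmin[best] > threshold:
            break
        cofactors.append(best)
        step_found[best] = step
        genetic_total = vc.sigma_a2 + (vc.sigma_d2 or 0.0)
        if config.variance_strategy == "refit-per-step":
            vc = fit_vc(cofactors)
            new_total = vc.sigma_a2 + (vc.sigma_d2 or 0.0)
            if new_total < 1e-6 * (new_total + vc.sigma_e2) and genetic_total > 0:
                logger.warning("genetic variance collapsed to the boundary; stopping")
                break
    else:
        logger.info("max_forward_steps reached")

    # backward elimination: re-test each cofactor in the model holding the others
    final_vc = vc
    surviving = list(cofactors)
    changed = True
    while changed and surviving:
        changed = False
        for j in list(surviving):
            others = [c for c in surviving if c != j]
            pa, pd_ = single_marker_test(
                design, mats, final_vc,
                Wa[:, j], Wb[:, j],
                cofactors=Wa[:, others] if others else None,
            )
            best_p = min(
                [p for p in (pa, pd_) if p is not None], default=1.0
            )
            if best_p > threshold:
                surviving.remove(j)
                changed = True
                if config.variance_strategy == "refit-per-step":
                    final_vc = fit_vc(surviving)

    hits: list[GwasHit] = []
    for j in surviving:
        others = [c for c in surviving if c != j]
        pa, pd_ = single_marker_test(
            design, mats, final_vc,
            Wa[:, j], Wb[:, j],
            cofactors=Wa[:, others] if others else None,
        )
        sig_a = pa is not None and pa <= threshold
        sig_d = pd_ is not None and pd_ <= threshold
        if not (sig_a or sig_d):
            continue
        klass = "A+D" if (sig_a and sig_d) else ("A" if sig_a else "D")
        meta = geno.snp_meta.iloc[j]
        hits.append(
            GwasHit(
                snp_id=str(meta["snp_id"]),
                snp_index=j,
                chromosome=str(meta["chrom"]),
                position=int(meta["pos"]),
                effect_class=klass,
                p_additive=pa if sig_a or pa is not None else None,
                p_dominance=pd_ if sig_d or pd_ is not None else None,
                step_found=step_found.get(j, 0),
            )
        )
    hits.sort(key=lambda h: (h.chromosome, h.position))
    return hits


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_gene_table(path) -> pd.DataFrame:
    """BED-like TSV: chrom, start (0-based half-open), end, name."""
    genes = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str}, comment="#",
    )
    if (genes["end"] < genes["start"]).any():
        bad = genes[genes["end"] < genes["start"]].iloc[0]
        raise ValueError(f"malformed gene interval {bad['name']}: end < start")
    return genes


def annotate_hits(
    hits: list[GwasHit], genes: pd.DataFrame
) -> list[tuple[GwasHit, GeneAnnotation]]:
    """Nearest gene within 100 kb for each hit (within / upstream / downstream).

    Gene intervals are 0-based half-open; SNP positions 1-based, so a SNP at
    position p lies within [start, end) iff start < p <= end.
    """
    if (genes["end"] < genes["start"]).any():
        raise ValueError("malformed gene interval: end < start")
    out = []
    for hit in hits:
        sub = genes[genes["chrom"].astype(str) == hit.chromosome]
        best: GeneAnnotation | None = None
        for _, g in sub.iterrows():
            if g["start"] < hit.position <= g["end"]:
                best = GeneAnnotation(g["name"], "within", 0)
                break
            if hit.position <= g["start"]:
                dist = int(g["start"] - hit.position + 1)
                rel = "upstream"
            else:
                dist = int(hit.position - g["end"])
                rel = "downstream"
            if dist <= ANNOTATION_WINDOW and (best is None or dist < best.distance):
                best = GeneAnnotation(g["name"], rel, dist)
        out.append((hit, best or GeneAnnotation(None, "none", -1)))
    return out


def hits_to_frame(annotated: list[tuple[GwasHit, GeneAnnotation]]) -> pd.DataFrame:
    rows = []
    for hit, ann in annotated:
        rows.append(
            {
                "snp_id": hit.snp_id,
                "chrom": hit.chromosome,
                "pos": hit.position,
                "effect_class": hit.effect_class,
                "p_additive": hit.p_additive,
                "p_dominance": hit.p_dominance,
                "gene": ann.gene_name,
                "relation": ann.relation,
                "distance": ann.distance,
            }
        )
    return pd.DataFrame(rows)
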