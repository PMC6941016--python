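# Methods

This note documents the statistical models implemented in `domgp`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions that were genuinely open.

## 1. Relationship matrices

Allele frequencies are observed sample frequencies of the second (A2)
allele, recorded in every matrix object for reproducibility.  The additive
matrix is the cross-product of centered dosages,

    G = M M' / Σᵢ 2 pᵢ qᵢ,     M[k,i] = dosage(k,i) − 2 pᵢ,

and the dominance matrix uses the heterozygosity coding centered by its
Hardy–Weinberg expectation,

    D = H H' / Σᵢ 2 pᵢ qᵢ (1 − 2 pᵢ qᵢ),
    H[k,i] = 1 − 2 pᵢ qᵢ  (heterozygote),   −2 pᵢ qᵢ  (either homozygote).

Both denominators make the expected diagonal 1 for non-inbred HWE
individuals; the expected off-diagonal is 0 for unrelated pairs.  Missing
dosages contribute 0 after centering (mean imputation); QC caps SNP
missingness at 5% so the effect is bounded.  Both matrices are invariant to
allele-label flips and to duplicating marker columns (asserted by tests).
Computation streams blocks of 2,048 SNPs to bound memory; matrices are
stored dense (the intended scale is n of a few thousand).  `stabilize`
adds a diagonal ridge (default 10⁻⁶ when needed) and verifies a Cholesky
factorization; the ridge shifts every eigenvalue by exactly its value and is
recorded on the object.

## 2. REML and BLUP

`reml_fit` maximizes the restricted likelihood of y over (σ²_a[, σ²_d],
σ²_e) for V = σ²_a G [+ σ²_d D] + σ²_e I by average-information updates.
Each iteration forms P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹ from a Cholesky solve,
the score −½[tr(PKᵢ) − y′PKᵢPy] (the trace as an elementwise sum, so one
O(n³) factorization per iteration dominates), and the AI matrix
½(KᵢPy)′P(KⱼPy).  If the AI step fails or lowers the likelihood, a
boundary-aware retry updates only the components that are off their bound or
have an outward score; if that also fails, an EM step
θᵢ ← θᵢ + θᵢ²/n·(y′PKᵢPy − tr(PKᵢ)) guarantees ascent.  Components are
clamped at 10⁻⁸·var(y) (a legitimate optimum for a null dominance variance).
Convergence requires |ΔlogL| < 10⁻⁶ and relative component change < 10⁻⁴,
with components parked at the clamp excluded from the latter (they rattle
against it); maximum 200 iterations.  Starting values split var(y) equally
across components.

Fixed effects use reference-level dummy coding with an intercept;
continuous covariates are standardized inside `build_trait_design`.
`blup_solve` solves Henderson's mixed-model equations with K⁻¹·(σ²_e/σ²_k)
blocks; tests verify equality with the direct generalized-least-squares form
σ²_k K V⁻¹(y − Xb̂) and with SNP-BLUP ridge regression at the matched
variance ratio.

The GBLUP-D vs GBLUP comparison is a likelihood-ratio test of one variance
component at its boundary, so the null distribution is the mixture
½χ²₀ + ½χ²₁: p = ½·P(χ²₁ ≥ 2ΔlogL), which equals 0.5 at Δ = 0.  The plain
1-df p-value is reported alongside.  A negative Δ (optimizer noise in nested
fits) is clamped to zero with a warning.

## 3. BayesA / BayesAD sampler

The marker model is y = Xb + W_a α + W_β β + e with W_a the 0/1/2 dosage and
W_β the 0/1/0 heterozygote indicator, both column-centered (centering
constants stored so out-of-sample predictions stay intercept-consistent).
Priors: α_j | σ²_{αj} ~ N(0, σ²_{αj}); σ²_{αj} ~ scaled-inv-χ²(ν_α, s²_α);
β_j | σ²_{αj} ~ N(μ_β, s²_D σ²_{αj}) with additive and dominance effects
taken independent given the SNP variance; flat priors on b and σ²_e.

One sweep updates: b from its Gaussian conditional; every σ²_{αj} from its
scaled-inv-χ² conditional (df ν_α+1 for BayesA, ν_α+2 for BayesAD, with the
(β_j−μ_β)²/s²_D term added to the scale); the marker effects; and σ²_e as
SSR/χ²_{n−2}.  For BayesA each α_j has a conjugate Gaussian conditional.
For BayesAD the pair (α_j, β_j) is updated by a Metropolis–Hastings step
with an independence proposal: α*_j from the BayesA-style Gaussian
conditional computed ignoring the dominance column, β*_j from its
conditional prior.  The prior and proposal densities then cancel so the
log acceptance ratio reduces to a difference of residual log-likelihood
terms, which the implementation evaluates in closed scalar form from two
dot products per SNP (the residual vector is touched only when a proposal
is accepted).  Observed acceptance rates on simulated data are ~0.85–0.95;
a rate below 1% triggers a warning.  Chains are fully reproducible from the
seed.

Hyperparameter defaults — ν_α = 4.2 (heavy-tailed convention), μ_β = 0,
s_D = 0.5, and s²_α from `derive_scale`, which inverts
var(α_j)·Σ2pᵢqᵢ = ĥ²·var(y) with var(α_j) = s²_α ν_α/(ν_α−2) — are package
choices (configurable and logged), as is the default chain (20,000 sweeps,
5,000 burn-in, thin 10; the library-level tests and cross-validation use
shorter chains).  With ν_α ~ 10⁶ the prior is effectively Gaussian and
BayesA predictions correlate > 0.99 with GBLUP at the matched variance
ratio, which the acceptance suite checks.

A caveat on calibration: with an informative s²_α, BayesA legitimately pulls
part of the phenotypic variance into the markers even on pure-noise data
(the prior mass does not vanish), so residual-variance calibration checks
use a deliberately weak scale.

## 4. Multi-locus mixed-model GWAS

Each SNP is tested by generalized least squares under V = σ²_a G
[+ σ²_d D] + σ²_e I (Cholesky whitening), entering its centered additive and
dominance codings jointly and reporting marginal Wald p-values per coding
against a t reference with the residual degrees of freedom — at n of a few
hundred the normal far-tail is anti-conservative enough to double the
family-wise error rate.  The residual scale is re-estimated from the
whitened residual sum of squares.  A SNP with no heterozygotes loses its
dominance p-value; a constant or collinear coding is skipped.

The scan iterates: fit REML under the current cofactor set, test all
markers, add the most significant (smallest of the two p-values; ties broken
by |effect| then genomic position) as a fixed cofactor, and repeat until
nothing passes the threshold or `max_forward_steps` is reached; then
backward-eliminate cofactors that are no longer significant, refitting
variance components per step (`refit-per-step`; a faster
`fixed-after-null` strategy is available).  Surviving hits are classified
A, D, or A+D by which codings pass.

The default threshold is Bonferroni over the number of marginal tests
actually performed — 0.05/(2m) when both codings are scanned — because
0.05/m with two tests per SNP yields a measured null family-wise error rate
near 0.12 rather than 0.05; with the corrected default the measured rate is
0.067 over 60 null replicates.  Any fixed cutoff (e.g. a published constant)
can be supplied as an override.  Gene annotation takes BED-like intervals
(0-based half-open starts; SNP positions 1-based): a SNP inside an interval
is `within` at distance 0, otherwise the nearest interval end within 100 kb
gives `upstream`/`downstream`, else the hit is reported unannotated.

## 5. Cross-validation

`make_folds` produces seeded balanced partitions (fold sizes within one of
n/k; 1233 individuals in 5 folds gives 247/247/247/246/246).  Corrected
phenotypes are y minus the full-data OLS fixed-effect fit; correcting on
full data rather than per training set is a deliberate choice (it mildly
favors no model and keeps the target common across folds); a training-only
variant can be obtained by building designs per fold.  G and D are built
once on all individuals (full-data allele frequencies) and sub-matrixed per
fold.  GBLUP/GBLUP-D fit variance components on the training fold and
predict validation genetic values through the validation-by-training blocks,
â_v = σ²_a G_vt V_t⁻¹ (y_t − X_t b̂); Bayes models predict from
posterior-mean marker effects with chain lengths halved inside CV (a
documented fidelity/runtime trade-off).  Predictive ability is the
within-fold correlation with corrected phenotypes; the default prediction
target is breeding values, with total genetic values (â + d̂) as an option.

Two properties of this design matter when reading results.  First, fold
cells from one dataset share genotypes and phenotypes and are strongly
correlated, so inference about model differences should aggregate over
independent datasets (the test suite does).  Second, a dominance model can
only improve prediction when the sample contains dominance relatedness:
for unrelated HWE individuals D is essentially an identity matrix, no
dominance is predictable across individuals, and GBLUP-D buys nothing (and
can pay a small variance-partitioning penalty).  Full-sib families (D = 0.25
within pairs) are the canonical source of such relatedness, and the
dominance-model advantage check in the acceptance suite therefore simulates
full-sib cohorts and compares the models' full genetic-value predictions —
the quantity on which the two models actually differ.  The measured
advantage (~+0.005 in r) matches the magnitude reported for real cattle
cohorts.

## 6. Synthetic data generator

`simulate_genotypes` draws each SNP's allele frequency uniformly on
`maf_range` (default 0.05–0.5) and genotypes from HWE (p², 2pq, q²);
optional full-sib families draw two latent HWE parents per family and
produce offspring by Mendelian transmission.  `simulate_phenotypes` samples
QTL positions without replacement, draws raw effects from a standard normal,
builds breeding values on the centered dosage coding and dominance
deviations on the 2pq-centered heterozygosity coding (the same codings as G
and D, so the variance-component models are correctly specified), then
Gram–Schmidt-orthogonalizes (breeding values, dominance deviations,
residual) and rescales so the realized in-sample variance fractions equal
`h2_additive` and `h2_dominance` exactly — making recovery tolerances tight
and the in-sample correlation between the two genetic parts exactly zero.
The genetic-plus-residual part has unit variance; fixed effects (6 year
levels, 2 sexes, uniform entry weight 150–250, uniform fattening days
120–240, with fixed coefficients) are added on top.  Missing calls are
injected only after the trait is computed, so the recorded truth never
depends on missingness.  A single seeded RNG stream drives each dataset.

What the generator does **not** emulate: linkage disequilibrium beyond
family structure (QTL are independent markers), multi-breed or half-sib
population structure, genotyping error, non-Gaussian traits (trait
distributions beyond summary statistics are not published for the motivating
cohort, so Gaussian is a modeling decision), and MAF-dependent effect-size
architecture.  Passing tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to LD or model
misspecification.

One consequence of the exact-rescaling contract worth knowing: when a single
QTL carries both an additive and a dominance effect at low MAF, the two
codings are strongly correlated and the orthogonalized dominance deviation
absorbs most of the additive coefficient, so the joint test correctly finds
little marginal additive signal.  Tests of A+D classification construct the
intended architecture explicitly at MAF ≈ 0.5 instead.

## 7. Quality control

The QC cascade is (1) individual missingness (> 10% removed), (2) SNP
missingness (≥ 5% removed), (3) MAF (kept only if > 0.05), (4) Hardy–
Weinberg exact test (kept only if p > 10⁻⁶), with per-SNP statistics
computed on non-missing calls after step 1 and each removed SNP attributed
to the first criterion it fails.  The filter order is a fixed convention
(counts depend on it).  The HWE test is the exact conditional test
(enumeration of heterozygote counts given allele counts via the standard
recurrence, no mid-p), matching common GWAS-toolkit behavior on small
counts; a brute-force log-factorial enumeration serves as its test oracle.
Re-applying QC to its own output is a no-op in practice, but is not
mathematically guaranteed: removing SNPs re-normalizes individual
missingness rates, so a borderline individual can cross the threshold on a
second pass.  Strict inequalities follow the usual reporting convention.

## 8. Problem sizes in the test and acceptance suites

The suites run on one CPU in a few minutes by choice of problem size, never
by weakening tolerances: dominance-matrix expectations at n = 2,000 ×
m = 5,000; GREML recovery at n = 800, m = 1,500 over 24 seeds (|mean bias|
< 0.03 asserted; measured ≈ 0.008/0.004); the CV model-ordering check over
20 independent full-sib datasets of n = 600, m = 1,500; GWAS null error rate
over 60 replicates of n = 300, m = 1,000; the BayesA→GBLUP limit at n = 400,
m = 800 with 3,000 sweeps.  `scripts/acceptance.py` recomputes the same
quantities at comparable sizes from a single `--seed`.

## 9. Known limitations

- Dense linear algebra throughout: n beyond ~5,000 individuals will be slow
  and memory-hungry; no sparse or low-rank paths.
- The dominance ratio σ²_d/σ²_P is weakly identified in unrelated samples
  (D ≈ I): single-dataset estimates at n ≲ 1,000 carry sampling SDs of
  0.05–0.1, so conclusions should rest on replicates or larger cohorts.
- Only the classical dominance-deviation parameterization is implemented; no
  genotypic (breeding-value-free) dominance models.
- The |α_j|-dependent form of the dominance prior (location or scale varying
  with the additive effect) is noted in the model family but only the
  independent form μ_β(|α_j|) = μ_β, σ²_β = s²_D σ²_{αj} is implemented.
- No VCF ingestion, imputation, sex chromosomes, or multi-trait REML.
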