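# domgp — genomic prediction and GWAS with dominance effects

`domgp` is a Python toolkit for quantitative geneticists and animal breeders
who want to ask how much **dominance** (within-locus non-additive gene
action) contributes to a complex trait, whether modeling it improves genomic
prediction, and where dominance association signals sit in the genome.  It
was built around the workflow used in dominance studies of beef-cattle
carcass and growth traits (cohorts of ~1,000 genotyped animals), but every
stage works on any biallelic autosomal SNP panel in PLINK bed/bim/fam format
with a phenotype/covariate table.

## The models

For phenotypes **y** with fixed effects **b** (slaughter year, sex, entry
body weight, fattening days), the individual-level mixed model is

    y = Xb + Z_a a + Z_d d + e
    a ~ N(0, G σ²_a),   d ~ N(0, D σ²_d),   e ~ N(0, I σ²_e)

where the **additive genomic relationship matrix** is G = MM′ / Σ 2pᵢqᵢ
(M holds dosages of the second allele centered by 2pᵢ) and the **dominance
relationship matrix** is D = HH′ / Σ 2pᵢqᵢ(1 − 2pᵢqᵢ) with h = 1 − 2pq for
heterozygotes and −2pq for homozygotes.  For an unrelated, non-inbred HWE
sample, E[diag D] = 1 and E[offdiag D] = 0.

- **GBLUP / GBLUP-D** — variance components (σ²_a, σ²_d, σ²_e) by
  average-information REML with EM fallback; BLUPs by Henderson's mixed-model
  equations; narrow (h²_A = σ²_a/σ²_P) and dominance (h²_D = σ²_d/σ²_P)
  heritabilities; model comparison by a boundary likelihood-ratio test with
  the ½χ²₀ + ½χ²₁ null mixture.
- **BayesA / BayesAD** — marker-effect MCMC: per-SNP additive effects with
  scaled-inverse-χ² variances (Student-t marginal prior), dominance effects
  β_j ~ N(μ_β, s²_D σ²_{αj}) on the heterozygote coding, sampled by Gibbs
  with a Metropolis–Hastings step for the (α_j, β_j) pair.  As ν_α → ∞ the
  prior becomes Gaussian and BayesA converges to GBLUP.
- **MLMM GWAS** — multi-locus mixed-model scan testing each SNP's additive
  and dominance codings jointly under the fitted G (+D) covariance, with
  forward inclusion of significant markers as cofactors, backward
  elimination, A / D / A+D classification, and nearest-gene annotation
  within 100 kb.
- **Cross-validated predictive ability** — repeated k-fold CV; predictive
  ability is the correlation between predicted genetic values and
  fixed-effect-corrected phenotypes in the validation fold.
- **Synthetic cohorts** — a seeded generator with known additive/dominance
  architecture (HWE genotypes, optional full-sib families, exact in-sample
  heritability targets) so the whole stack is testable without external
  data.

## Worked example

```python
import numpy as np
from domgp import (SimulationConfig, simulate_dataset, build_trait_design,
                   build_G, build_D, stabilize, reml_fit, heritabilities,
                   likelihood_ratio_test)

cfg = SimulationConfig(n_individuals=800, n_snps=1500,
                       h2_additive=0.42, h2_dominance=0.158, seed=0)
ds = simulate_dataset(cfg)                      # genotypes + trait + truth
design = build_trait_design(ds.phenotypes)      # year/sex/covariate design
G = stabilize(build_G(ds.genotypes), 1e-6)
D = stabilize(build_D(ds.genotypes), 1e-6)

vc_ad = reml_fit(design, [G, D])                # GBLUP-D
vc_a  = reml_fit(design, [G])                   # GBLUP
h = heritabilities(vc_ad)
lrt = likelihood_ratio_test(vc_a.logL, vc_ad.logL)
print(f"hA2 = {h.h2_narrow:.3f}  hD2 = {h.h2_dominance:.3f}  "
      f"LRT chi2 = {lrt.chi2:.2f}  p = {lrt.p_value:.4f}")
```

Output:

```
hA2 = 0.315  hD2 = 0.239  LRT chi2 = 10.99  p = 0.0005
```

The simulated trait carries 42% additive and 15.8% dominance variance.  A
single dataset of this size estimates each ratio with a sampling SD near
0.06 (the two genetic components trade off against each other, so individual
draws can land as far off as this one), but the likelihood-ratio test
correctly rejects the additive-only model, and averaged over 24 seeds the
estimates are unbiased to within 0.01 (see `tests/test_acceptance.py`).

The same pipeline is scriptable from the shell:

```bash
domgp simulate --out demo --seed 1
domgp qc   --bfile demo --out demo_qc
domgp grm  --bfile demo_qc --out demo
domgp reml --bfile demo_qc --pheno demo.pheno.tsv --out demo
domgp gwas --bfile demo_qc --pheno demo.pheno.tsv --out demo
domgp cv   --bfile demo_qc --pheno demo.pheno.tsv --models GBLUP,GBLUP-D --out demo
domgp run  --config pipeline.yaml     # all stages, manifest with hashes
```

## Layout

```
src/domgp/
  simulate.py   synthetic cohorts with known architecture
  io_qc.py      PLINK bed/bim/fam codec, HWE exact test, QC cascade
  grm.py        G and D relationship matrices, GCTA-format output
  greml.py      AI-REML, Henderson MME, heritabilities, boundary LRT
  bayesad.py    BayesA/BayesAD Gibbs + MH sampler
  gwas.py       multi-locus mixed-model scan and gene annotation
  evaluate.py   corrected phenotypes, folds, cross-validation
  pipeline.py   staged pipeline with hashed manifest
  cli.py        `domgp` command-line entry points
```

See `docs/methods.md` for the statistical details and design choices.
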