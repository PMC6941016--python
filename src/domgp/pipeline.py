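"""End-to-end pipeline orchestration with a hashed artifact manifest.

A pipeline run executes simulate -> qc -> grm -> reml -> bayes -> gwas -> cv
in dependency order from a plain-text (YAML) configuration with one block
per stage.  Every file written is recorded in a manifest with its SHA-256
content hash so reruns can be verified bit-for-bit.  Seeds propagate
deterministically: each stage draws its seed from the global seed plus a
fixed stage offset, so changing one stage's seed never perturbs another's
output.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayesad, evaluate, gwas, greml, grm, io_qc, simulate

logger = logging.getLogger("domgp")

STAGES = ("simulate", "qc", "grm", "reml", "bayes", "gwas", "cv")
_STAGE_SEED_OFFSET = {s: 1000 * i for i, s in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    verbosity: str = "progress"  # "progress" | "debug"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        glob = raw.get("global", {})
        stages = {k: v or {} for k, v in raw.items() if k != "global"}
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage blocks: {sorted(unknown)}")
        return cls(
            out_dir=Path(glob.get("out_dir", "domgp_out")),
            seed=int(glob.get("seed", 0)),
            verbosity=str(glob.get("verbosity", "progress")),
            stages=stages,
        )

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED_OFFSET[stage]) % (2**31 - 1)

    def validate(self) -> None:
        for stage, block in self.stages.items():
            for key in ("bfile", "pheno", "genes"):
                if key in block and not str(block[key]).startswith(
                    str(self.out_dir)
                ):
                    p = Path(block[key])
                    probe = p if key != "bfile" else Path(str(p) + ".bed")
                    if not probe.exists():
                        raise FileNotFoundError(
                            f"stage '{stage}': input {key}={block[key]} not found"
                        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute configured stages in order; return the artifact manifest."""
    config.validate()
    level = logging.DEBUG if config.verbosity == "debug" else logging.INFO
    logging.basicConfig(level=level, format="%(name)s %(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    logger.info("pipeline start: seed=%d out=%s", config.seed, out)
    logger.info(
        "QC thresholds in effect: MAF > 0.05, SNP missing < 0.05, HWE p > 1e-6, "
        "individual missing <= 0.10 (overridable per stage)"
    )

    geno = None
    pheno_df = None
    dataset = None
    G = D = None
    vc_full = None

    if "simulate" in config.stages:
        blk = config.stages["simulate"]
        cfg = simulate.SimulationConfig(
            n_individuals=int(blk.get("n_individuals", 500)),
            n_snps=int(blk.get("n_snps", 2000)),
            maf_range=tuple(blk.get("maf_range", (0.05, 0.5))),
            n_families=int(blk.get("n_families", 0)),
            sibs_per_family=int(blk.get("sibs_per_family", 0)),
            n_qtl_additive=int(blk.get("n_qtl_additive", 100)),
            n_qtl_dominance=int(blk.get("n_qtl_dominance", 50)),
            h2_additive=float(blk.get("h2_additive", 0.42)),
            h2_dominance=float(blk.get("h2_dominance", 0.158)),
            missing_rate=float(blk.get("missing_rate", 0.0)),
            seed=int(blk.get("seed", config.stage_seed("simulate"))),
        )
        dataset = simulate.simulate_dataset(cfg)
        paths = dataset.write(out / "sim")
        written += list(paths.values())
        geno, pheno_df = dataset.genotypes, dataset.phenotypes
        logger.info("simulate: n=%d m=%d", geno.n_individuals, geno.n_snps)

    if geno is None and any(s in config.stages for s in STAGES[1:]):
        blk = next(
            (config.stages[s] for s in STAGES[1:] if s in config.stages), {}
        )
        if "bfile" not in blk:
            raise ValueError("no simulate stage and no bfile input configured")
        geno = io_qc.read_plink(blk["bfile"])
        if "pheno" in blk:
            pheno_df = io_qc.read_phenotypes(blk["pheno"])

    if "qc" in config.stages:
        blk = config.stages["qc"]
        thresholds = io_qc.QcThresholds(
            min_maf=float(blk.get("maf", 0.05)),
            max_snp_missing=float(blk.get("geno", 0.05)),
            min_hwe_p=float(blk.get("hwe", 1e-6)),
            max_ind_missing=float(blk.get("mind", 0.10)),
        )
        geno, report = io_qc.apply_qc(geno, thresholds)
        rpt = out / "qc_report.tsv"
        report.to_frame().to_csv(rpt, sep="\t", index=False)
        written.append(rpt)
        io_qc.write_plink(geno, out / "qc")
        written += [out / f"qc{s}" for s in (".bed", ".bim", ".fam")]
        logger.info("qc: %d individuals, %d SNPs survive", geno.n_individuals, geno.n_snps)

    if "grm" in config.stages:
        G = grm.stabilize(grm.build_G(geno), 1e-6)
        D = grm.stabilize(grm.build_D(geno), 1e-6)
        grm.write_grm(G, out / "add")
        grm.write_grm(D, out / "dom")
        written += [out / f"{k}.grm.{s}" for k in ("add", "dom") for s in ("bin", "id")]
        logger.info("grm: built G and D (%d x %d)", G.n, G.n)

    design = None
    if pheno_df is not None:
        design = greml.build_trait_design(pheno_df)

    if "reml" in config.stages:
        if design is None or G is None:
            raise ValueError("reml stage requires phenotypes and grm stage")
        vc_a = greml.reml_fit(design, [G])
        vc_ad = greml.reml_fit(design, [G, D])
        vc_full = vc_ad
        h_a, h_ad = greml.heritabilities(vc_a), greml.heritabilities(vc_ad)
        lrt = greml.likelihood_ratio_test(vc_a.logL, vc_ad.logL)
        tbl = pd.DataFrame(
            {
                "quantity": [
                    "sigma_a2_AD", "sigma_d2_AD", "sigma_e2_AD",
                    "hA2_AD", "hD2_AD", "dom_to_genetic_AD",
                    "sigma_a2_A", "sigma_e2_A", "hA2_A",
                    "logL_A", "logL_AD", "lrt_chi2", "lrt_p_mixture",
                ],
                "value": [
                    vc_ad.sigma_a2, vc_ad.sigma_d2, vc_ad.sigma_e2,
                    h_ad.h2_narrow, h_ad.h2_dominance, h_ad.dominance_to_genetic,
                    vc_a.sigma_a2, vc_a.sigma_e2, h_a.h2_narrow,
                    vc_a.logL, vc_ad.logL, lrt.chi2, lrt.p_value,
                ],
            }
        )
        path = out / "variance_components.tsv"
        tbl.to_csv(path, sep="\t", index=False)
        written.append(path)
        blup = greml.blup_solve(design, [G, D], vc_ad)
        bl = pd.DataFrame(
            {"id": geno.individual_ids, "a_hat": blup.a_hat, "d_hat": blup.d_hat}
        )
        path = out / "blup.tsv"
        bl.to_csv(path, sep="\t", index=False)
        written.append(path)
        logger.info("reml: hA2=%.3f hD2=%.3f", h_ad.h2_narrow, h_ad.h2_dominance)

    if "bayes" in config.stages:
        blk = config.stages["bayes"]
        designs = bayesad.build_designs(geno)
        hyper = bayesad.BayesADHyper(
            nu_alpha=float(blk.get("nu_alpha", 4.2)),
            s_alpha2=bayesad.derive_scale(
                float(blk.get("h2_prior", 0.5)), geno,
                float(blk.get("nu_alpha", 4.2)), var_y=float(np.var(design.y)),
            ),
            s_D=float(blk.get("s_D", 0.5)),
            n_iterations=int(blk.get("iters", 3000)),
            burn_in=int(blk.get("burnin", 1000)),
            thinning=int(blk.get("thin", 5)),
            seed=int(blk.get("seed", config.stage_seed("bayes"))),
        )
        samples = bayesad.run_chain(
            design, designs, hyper, model=str(blk.get("model", "bayesAD"))
        )
        tbl = pd.DataFrame(
            {
                "snp_id": geno.snp_meta["snp_id"],
                "alpha_mean": samples.alpha_mean,
                "alpha_sd": samples.alpha_sd,
                "beta_mean": samples.beta_mean,
                "beta_sd": samples.beta_sd,
            }
        )
        path = out / "bayes_effects.tsv"
        tbl.to_csv(path, sep="\t", index=False)
        written.append(path)
        logger.info(
            "bayes: %d draws, MH acceptance %.2f", samples.n_draws,
            samples.acceptance_rate,
        )

    if "gwas" in config.stages:
        blk = config.stages["gwas"]
        cfg = gwas.ScanConfig(
            significance_threshold=blk.get("threshold"),
            max_forward_steps=int(blk.get("max_forward_steps", 10)),
        )
        hits = gwas.mlmm_scan(design, geno, [G, D], cfg)
        if "genes" in blk:
            genes = gwas.read_gene_table(blk["genes"])
            annotated = gwas.annotate_hits(hits, genes)
        else:
            annotated = [(h, gwas.GeneAnnotation(None, "none", -1)) for h in hits]
        path = out / "gwas_hits.tsv"
        gwas.hits_to_frame(annotated).to_csv(path, sep="\t", index=False)
        written.append(path)
        logger.info("gwas: %d hits", len(hits))

    if "cv" in config.stages:
        blk = config.stages["cv"]
        models = tuple(blk.get("models", ["GBLUP", "GBLUP-D"]))
        plan = evaluate.make_folds(
            geno.n_individuals,
            k=int(blk.get("k", 5)),
            repeats=int(blk.get("repeats", 3)),
            seed=int(blk.get("seed", config.stage_seed("cv"))),
        )
        res = evaluate.cross_validate((geno, design), models=models, plan=plan)
        path = out / "cv_cells.tsv"
        res.cells.to_csv(path, sep="\t", index=False)
        written.append(path)
        path = out / "cv_summary.tsv"
        res.summary().to_csv(path, sep="\t", index=False)
        written.append(path)
        logger.info("cv: %s", res.summary().to_dict("records"))

    manifest = pd.DataFrame(
        {
            "path": [str(p) for p in written],
            "sha256": [_sha256(Path(p)) for p in written],
        }
    )
    manifest_path = out / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    logger.info("pipeline done: %d artifacts", len(written))
    return manifest
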