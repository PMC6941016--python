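import numpy as np
import pandas as pd
import pytest

from domgp import (SimulationConfig, build_D, build_G, build_trait_design,
                   simulate_dataset, stabilize)


@pytest.fixture(scope="session")
def cw_dataset():
    """Mid-sized simulated cohort at the carcass-weight architecture."""
    cfg = SimulationConfig(
        n_individuals=500, n_snps=1200, h2_additive=0.42, h2_dominance=0.158,
        n_qtl_additive=100, n_qtl_dominance=50, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def cw_design(cw_dataset):
    return build_trait_design(cw_dataset.phenotypes)


@pytest.fixture(scope="session")
def cw_matrices(cw_dataset):
    G = stabilize(build_G(cw_dataset.genotypes), 1e-6)
    D = stabilize(build_D(cw_dataset.genotypes), 1e-6)
    return G, D


def make_geno_frame(n_snps, chrom="1"):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n_snps,
            "snp_id": [f"s{j}" for j in range(n_snps)],
            "pos": np.arange(1, n_snps + 1) * 100,
            "a1": ["A"] * n_snps,
            "a2": ["B"] * n_snps,
        }
    )
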