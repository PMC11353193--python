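import numpy as np
import pandas as pd
import pytest

from ilsdeconv import syndata
from ilsdeconv.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_genes_per_genome=60,
        gene_length=400,
        library_size_mean=3000.0,
        de_fraction=0.2,
        de_log2fc=2.0,
    )


@pytest.fixture(scope="session")
def two_group_design():
    """3 control + 3 parasitized samples of one genotype."""
    return [
        syndata.SampleSpec(f"s{i}", "Formula", cond, i % 3 + 1)
        for i, cond in enumerate(["control"] * 3 + ["parasitized"] * 3)
    ]


@pytest.fixture(scope="session")
def genome_pair(small_config):
    return syndata.make_genome_pair(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def nb_matrix(rng, n_genes=200, n_samples=4, mean=100.0, phi=0.1):
    """Random NB count matrix helper for normalization tests."""
    base = rng.lognormal(np.log(mean), 1.0, n_genes)
    r = 1.0 / phi
    y = rng.negative_binomial(
        r, r / (r + base[:, None]), size=(n_genes, n_samples)
    ).astype(float)
    return pd.DataFrame(
        y,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
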