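import numpy as np
import pandas as pd
import pytest

from metapathways import preprocess as pp
from metapathways import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    """Small three-group cohort used across module tests."""
    return sd.SimulationConfig(
        n_genes_expr=40,
        n_genes_meth=32,
        n_shared_genes=20,
        samples_per_group={"normal": 10, "hpv_positive": 10, "hpv_negative": 10},
        n_patterns=3,
        snr=10.0,
        silenced_fraction=0.5,
        n_gene_sets=15,
        set_size=8,
        enriched_sets=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sd.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_combined(small_cohort):
    expr, probes, clinical, gene_sets, truth = small_cohort
    beta = pp.probes_to_gene_beta(probes)[expr.columns]
    return pp.build_combined(np.log(expr), beta, set(expr.index) | set(beta.index))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
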