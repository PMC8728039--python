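import numpy as np
import pandas as pd
import pytest

from tetragp.brr import BRRModelSpec
from tetragp.simulate import SimConfig, simulate_breeding_program


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down breeding program shared by read-only tests."""
    cfg = SimConfig(
        n_markers=300,
        family_sizes=(12, 12, 25, 25, 12),
        generation_sizes=(25, 10),
        seed=123,
    )
    return simulate_breeding_program(cfg)


@pytest.fixture
def short_spec():
    """Reduced Gibbs chain for fast test fits."""
    return BRRModelSpec(n_iter=1500, burn_in=500, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_pheno(records):
    """Long-format phenotype table from (genotype, location, rep, trait, value)."""
    return pd.DataFrame(
        records, columns=["genotype", "location", "rep", "trait", "value"]
    )
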