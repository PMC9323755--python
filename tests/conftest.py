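import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from postgwas.ld import LdPanel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from postgwas.synth import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """One locus of every scenario at modest cohort sizes."""
    return SimulationConfig(
        scenarios=("chain", "direct", "pleiotropy", "linkage", "null"),
        n_gwas=4_000,
        n_eqtl=2_000,
        n_mqtl=2_000,
        n_ref=1_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_panel(small_dataset):
    return LdPanel(small_dataset.cohorts["ref"])


def make_assoc(snp="rs1", a1="A", a2="G", freq=0.3, b=0.1, se=0.02, n=1000):
    from scipy import stats

    z = b / se
    return pd.DataFrame(
        {
            "SNP": [snp], "A1": [a1], "A2": [a2], "freq": [freq],
            "b": [b], "se": [se], "z": [z],
            "p": [2 * stats.norm.sf(abs(z))], "n": [n],
        }
    )
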