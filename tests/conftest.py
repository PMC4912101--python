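import numpy as np
import pandas as pd
import pytest

from alupopdiv import FrequencyMatrix, GenotypeTable, SimulationConfig, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20160617)


@pytest.fixture
def small_table() -> GenotypeTable:
    """Two populations, two loci, hand-countable calls."""
    records = pd.DataFrame(
        [
            ("A", "a1", "ACE", "II"), ("A", "a2", "ACE", "ID"),
            ("A", "a3", "ACE", "DD"), ("A", "a4", "ACE", "ID"),
            ("A", "a1", "TPA25", "II"), ("A", "a2", "TPA25", "II"),
            ("A", "a3", "TPA25", "ID"), ("A", "a4", "TPA25", None),
            ("B", "b1", "ACE", "DD"), ("B", "b2", "ACE", "DD"),
            ("B", "b1", "TPA25", "ID"), ("B", "b2", "TPA25", "II"),
        ],
        columns=["population", "individual", "locus", "genotype"],
    )
    return GenotypeTable(records=records)


@pytest.fixture
def sim_dataset():
    """Small seeded Balding-Nichols dataset shared across tests."""
    return simulate_genotypes(SimulationConfig(K=4, L=5, n=30, F=0.08, seed=11))


@pytest.fixture
def sim_frequencies(sim_dataset) -> FrequencyMatrix:
    return FrequencyMatrix.from_genotype_table(sim_dataset.genotypes)


def random_frequency_matrix(rng, k=12, l=7) -> FrequencyMatrix:
    p = pd.DataFrame(
        rng.uniform(0.02, 0.98, size=(k, l)),
        index=[f"pop{i}" for i in range(k)],
        columns=[f"L{j}" for j in range(l)],
    )
    return FrequencyMatrix(p=p)
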