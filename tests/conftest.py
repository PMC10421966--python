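import numpy as np
import pytest

from mhc2tx import Dataset, PeptideRecord, SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulated corpus shared by fast tests."""
    config = SimConfig(n_alleles=2, n_positives=60, seed=11)
    dataset, truths = simulate(config)
    return config, dataset, truths


@pytest.fixture
def toy_proteome():
    rng = np.random.default_rng(5)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    return {
        f"P{i:02d}": "".join(rng.choice(aa, size=int(rng.integers(40, 200))))
        for i in range(10)
    }


@pytest.fixture
def tiny_dataset():
    records = [
        PeptideRecord("ACDEFGHIKLMNPQR", "EL", 1.0, allele_name=None),
        PeptideRecord("LMNPQRSTVWYACDE", "EL", 0.0),
        PeptideRecord("GHIKLMNPQRSTVWY", "BA", 0.42),
    ]
    return Dataset(records=records)
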