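import numpy as np
import pytest

import stepblup as sb


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fullsib_pedigree():
    """1, 2 founders; 3 and 4 are full sibs from 1 x 2."""
    return sb.PedigreeTable.from_records(
        [("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"), ("4", "1", "2")]
    )


@pytest.fixture
def inbred_pedigree():
    """1, 2 founders; 3 = 1 x 2; 4 = 1 x 3 (sire-daughter mating, F=0.25)."""
    return sb.PedigreeTable.from_records(
        [("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"), ("4", "1", "3")]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated herd shared by read-only tests."""
    cfg = sb.SimConfig(
        n_animals=360,
        n_generations=4,
        n_snps=600,
        n_phenotyped=220,
        genotyped_fraction=0.5,
        seed=11,
    )
    return sb.simulate_dataset(cfg)
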