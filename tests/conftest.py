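import numpy as np
import pytest

import pirnascreen as ps
from pirnascreen.simulate import SyntheticConfig, simulate_database, simulate_references

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def plasma_records():
    return ps.load_plasma_table()


@pytest.fixture(scope="session")
def plasma_queryset(plasma_records):
    return ps.QuerySet("plasma", [r.query for r in plasma_records])


@pytest.fixture(scope="session")
def yrna_refset():
    """A 112-nt synthetic YRNA-like reference with a known 26-mer window at 66."""
    rng = np.random.default_rng(5)
    ref = random_dna(rng, 112)
    return ps.ReferenceSet("YRNA", [ps.SeqRecord("RNAY4", ref)])


@pytest.fixture(scope="session")
def sim_dataset():
    """Seeded 1,000 genuine + 40 exact contaminants with truth."""
    config = SyntheticConfig(seed=7, n_genuine=1000, n_contaminants=40)
    refsets = simulate_references(config)
    database, truth = simulate_database(config, refsets)
    return config, refsets, database, truth
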