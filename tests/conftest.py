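import numpy as np
import pytest

from kincompare.pedigree import Pedigree
from kincompare.simulate import SimScenario, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded study-shaped cohort (99 individuals, 3 subpopulations,
    5000 gene-dropped loci) shared across tests."""
    return simulate_cohort(SimScenario(seed=3))


@pytest.fixture(scope="session")
def looped_pedigree():
    """Six-generation pedigree with a repeated ancestor on both sides
    (cousin-mating loop continued for two more generations)."""
    recs = [
        ("G1", 0, 0), ("G2", 0, 0), ("X1", 0, 0), ("X2", 0, 0),
        ("B1", "G1", "G2"), ("B2", "G1", "G2"),
        ("C1", "B1", "X1"), ("C2", "B2", "X2"),
        ("Z", "C1", "C2"),           # cousin-mating offspring
        ("Y1", 0, 0),
        ("W", "Z", "Y1"),
        ("V", "Z", "Y1"),            # full sibs through an inbred parent
        ("U", "W", "C2"),            # loop back to an ancestor line
    ]
    return Pedigree.from_records(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
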