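import numpy as np
import pytest

from lsubench.refdb import ReferenceDB, ReferenceRecord
from lsubench.simulate import SimConfig, generate_database
from lsubench.taxonomy import Lineage


def lin(*names: str) -> Lineage:
    return Lineage(tuple(names))


@pytest.fixture
def toy_db() -> ReferenceDB:
    """Six records, two phyla / four genera, hand-written lineages."""
    mk = lambda *n: Lineage(tuple(n))
    return ReferenceDB([
        ReferenceRecord("a1", "ACGTACGTACGTACGTACGT",
                        mk("Fungi", "P1", "C1", "O1", "F1", "G1", "G1 s1")),
        ReferenceRecord("a2", "ACGTACGTACGTACGTACGA",
                        mk("Fungi", "P1", "C1", "O1", "F1", "G1", "G1 s2")),
        ReferenceRecord("b1", "ACGTACGTATTTACGTACGT",
                        mk("Fungi", "P1", "C1", "O1", "F1", "G2", "G2 s1")),
        ReferenceRecord("c1", "TTTTGGGGCCCCAAAATTTT",
                        mk("Fungi", "P1", "C1", "O2", "F2", "G3", "G3 s1")),
        ReferenceRecord("d1", "GGGGCCCCTTTTAAAAGGGG",
                        mk("Fungi", "P2", "C2", "O3", "F3", "G4", "G4 s1")),
        ReferenceRecord("d2", "GGGGCCCCTTTTAAAAGGGA",
                        mk("Fungi", "P2", "C2", "O3", "F3", "G4")),
    ])


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """16-species synthetic configuration used by slower module tests."""
    return SimConfig(n_phyla=2, n_classes=1, n_orders=2, n_families=1,
                     n_genera=2, n_species=2, seed=7)


@pytest.fixture(scope="session")
def small_db(small_sim_config) -> ReferenceDB:
    return generate_database(small_sim_config)


@pytest.fixture(scope="session")
def default_db() -> ReferenceDB:
    """The default 64-species study database (one instance per session)."""
    return generate_database(SimConfig(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
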