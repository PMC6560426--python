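import numpy as np
import pytest

from rumenamp.config_and_io import QualityRead
from rumenamp.synthetic_data import (
    SimulationDesign,
    simulate_reference_db,
    simulate_study,
)


@pytest.fixture(scope="session")
def refs6():
    """Six taxa in three genera (two species each), amplicons <= 540 nt so
    every clean read passes the 400-580 length window with primers on."""
    return simulate_reference_db(6, seed=1, seq_len_range=(420, 540))


@pytest.fixture(scope="session")
def refs8():
    """Eight single-species genera, used where many distinct parents help."""
    return simulate_reference_db(8, seed=1, seq_len_range=(420, 540),
                                 species_per_genus=1)


@pytest.fixture(scope="session")
def clean_study(refs6):
    """Error-free artifact-free small study: 3 samples/group, 100 reads each."""
    design = SimulationDesign(
        n_per_group=3, n_taxa=6, reads_per_sample=100,
        error_rate=0.0, lowq_prob_max=0.0,
        enriched_taxa=(("REF_000", "EO", 8.0),),
        seed=11,
    )
    reads, metadata, truth = simulate_study(design, refs6)
    return design, reads, metadata, truth


@pytest.fixture(scope="session")
def artifact_study(refs6):
    """Study with all three artifact classes planted, error-free otherwise."""
    design = SimulationDesign(
        n_per_group=3, n_taxa=6, reads_per_sample=150,
        error_rate=0.0, lowq_prob_max=0.0,
        chimera_frac=0.05, truncated_frac=0.04, offtarget_short_frac=0.04,
        seed=23,
    )
    reads, metadata, truth = simulate_study(design, refs6)
    return design, reads, metadata, truth


def make_read(seq: str, q: int = 40, read_id: str = "r1") -> QualityRead:
    return QualityRead(read_id=read_id, seq=seq, quals=tuple([q] * len(seq)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
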