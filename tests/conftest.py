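import pytest

from barcode_audit import SimulationConfig, simulate_reference_library
from barcode_audit.seq_io_qc import anchor_to_barcode_frame


@pytest.fixture(scope="session")
def default_library():
    """The standard 20-species x 10-specimen library, seed 1."""
    return simulate_reference_library(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_small_library():
    """A small artifact-free library: no fragments, ambiguities or misids."""
    config = SimulationConfig(
        seed=2,
        n_genera=2,
        species_per_genus=3,
        specimens_per_species=4,
        fragment_fraction=0.0,
        ambiguity_rate=0.0,
        misid_count=0,
    )
    return simulate_reference_library(config)


def anchor_all(library, min_len=300):
    return [
        anchor_to_barcode_frame(sid, bases, min_len=min_len)
        for sid, bases in library.sequences
    ]


@pytest.fixture(scope="session")
def default_anchored(default_library):
    return anchor_all(default_library)
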