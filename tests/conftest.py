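import pytest

from its2barcode import AlignmentParams, SeqRecord
from its2barcode.simulate import SimulationConfig, make_worked_alignment, simulate_dataset


@pytest.fixture(scope="session")
def worked_msa():
    return make_worked_alignment()


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated dataset shared across tests (seed 1)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_msa(default_dataset):
    from its2barcode import progressive_msa

    records, _ = default_dataset
    return progressive_msa(records)


@pytest.fixture
def simple_params():
    return AlignmentParams(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)


@pytest.fixture
def two_species_records():
    return [
        SeqRecord("X1", "Left_sp", "ACGTACGTACGTACGTACGT"),
        SeqRecord("X2", "Left_sp", "ACGTACGTACGTACGTACGT"),
        SeqRecord("Y1", "Right_sp", "ACGTACGTACTTACGTACGT"),
        SeqRecord("Y2", "Right_sp", "ACGTACGTACTTACGTACGT"),
    ]
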