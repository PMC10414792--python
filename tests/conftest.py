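import numpy as np
import pytest

from neurostack.io_formats import PeptideRecord, pad_sequence
from neurostack.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def motif_records():
    """Small planted-motif benchmark: 100 + 100 peptides, fully separable."""
    return generate_dataset(SyntheticSpec(n_pos=100, n_neg=100, seed=7))


@pytest.fixture(scope="session")
def motif_arrays(motif_records):
    y = np.array([r.label for r in motif_records])
    padded = [pad_sequence(r.sequence) for r in motif_records]
    return padded, y


@pytest.fixture
def toy_records():
    return [
        PeptideRecord("p1", "ACDEF", 1),
        PeptideRecord("p2", "GHIKLMN", 0),
        PeptideRecord("p3", "WWYYVV", 1),
    ]
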