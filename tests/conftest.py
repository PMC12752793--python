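import numpy as np
import pytest

from affiselect.design import DEFAULT_DESIGN, LibraryDesign


@pytest.fixture
def toy_design() -> LibraryDesign:
    """Small 8-residue design for fast funnel tests."""
    return LibraryDesign(
        name="toy",
        protein_length=8,
        randomized_positions=(2, 3, 5),
        flank5_dna="ATCCGCGACCAAAGTAAAATTC",
        flank3_dna="CTGCTGGAGAAACTGAAGCT",
        scaffold="MKVAGELT",
    )


@pytest.fixture
def sim_design() -> LibraryDesign:
    """The full-length default simulation design."""
    return DEFAULT_DESIGN


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
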