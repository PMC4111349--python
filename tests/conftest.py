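import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from itshybrid import synthetic
from itshybrid.types import AlignedSet, RegionAnnotation, SequenceRecord, StructureTemplate


@pytest.fixture(scope="session")
def study():
    """One paper-like synthetic study shared across tests (fixed seed)."""
    return synthetic.simulate_study(synthetic.paper_like(11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_alignment():
    return AlignedSet.from_records(
        [
            SequenceRecord("m1", "ACGTACGTAC", "mat"),
            SequenceRecord("m2", "ACGTACGTAC", "mat"),
            SequenceRecord("p1", "ACGTACTTAC", "pat"),
            SequenceRecord("h1", "ACGTACKTAC", "hyb"),
        ]
    )


@pytest.fixture()
def hairpin_template():
    # GGGGG AAAA CCCCC : positions 1-5 pair with 14-10
    seq = "GGGGGAAAACCCCC"
    pairs = frozenset((i, 15 - i) for i in range(1, 6))
    return StructureTemplate(seq, pairs)


@pytest.fixture()
def toy_regions():
    return RegionAnnotation({"ITS1": (1, 4), "5.8S": (5, 7), "ITS2": (8, 10)})
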