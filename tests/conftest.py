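import numpy as np
import pytest

from seqpart.io import Alphabet, SequenceRecord
from seqpart.sketch import SketchScheme
from seqpart.synthetic import FamilySpec, generate_families


def nt_record(seq_id: str, residues: str, label=None) -> SequenceRecord:
    return SequenceRecord(id=seq_id, residues=residues,
                          alphabet=Alphabet.NUCLEOTIDE, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)


@pytest.fixture(scope="session")
def small_families():
    """Six well-separated families (independent founders): intra-family
    cosine distances ~0.1-0.2, inter-family ~1.0 at k=16."""
    spec = FamilySpec(n_families=6, members_per_family=10, seq_length=300,
                      intra_identity=0.995, seed=404)
    return generate_families(spec)


@pytest.fixture(scope="session")
def graded_families():
    """Thirty families sharing a common ancestor: intra distances below
    0.3, inter distances inside (0, 0.7) at k=16/cosine, so both the
    normal and the inverted split regimes are non-degenerate."""
    spec = FamilySpec(n_families=30, members_per_family=10, seq_length=600,
                      intra_identity=0.995, ancestor_identity=0.992,
                      seed=1001)
    return generate_families(spec)


@pytest.fixture
def full16():
    return SketchScheme(k=16, mode="full")
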