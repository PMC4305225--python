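import numpy as np
import pytest

from sigbin.io_formats import SequenceRecord, write_fasta
from sigbin.synthetic import generate_community

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_fasta(tmp_path):
    """Write SequenceRecords (or (id, seq) pairs) to a temp FASTA file."""

    def _write(records, name="input.fasta"):
        recs = [
            r if isinstance(r, SequenceRecord) else SequenceRecord(*r) for r in records
        ]
        path = tmp_path / name
        write_fasta(recs, path)
        return path

    return _write


@pytest.fixture(scope="session")
def small_community():
    """3 populations x 60 fragments, shared by pipeline-level tests."""
    return generate_community(
        n_pops=3,
        genome_length=40_000,
        frag_length_dist=(1000, 1200),
        n_frags_per_pop=60,
        divergence=0.8,
        seed=7,
    )
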