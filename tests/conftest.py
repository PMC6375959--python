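import numpy as np
import pytest

from algscreen.io import SequenceRecord, read_fasta, packaged_reference_path
from algscreen.pcr import packaged_primers


@pytest.fixture(scope="session")
def primers():
    return packaged_primers()


@pytest.fixture(scope="session")
def reference_proteins():
    return read_fasta(packaged_reference_path())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_nt(length: int, rng) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture()
def make_records():
    def _make(seqs, sample_ids=None):
        sample_ids = sample_ids or [""] * len(seqs)
        return [
            SequenceRecord(f"s{i}", seq, sid)
            for i, (seq, sid) in enumerate(zip(seqs, sample_ids))
        ]

    return _make
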