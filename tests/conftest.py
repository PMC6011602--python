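import numpy as np
import pytest

from halopop.synthetic_data import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_fasta(tmp_path):
    """Write records (id, seq) pairs to a FASTA file and return its path."""

    def _write(records, name="test.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def random_seq(rng):
    def _make(length, gc=0.5):
        return random_sequence(rng, length, gc)

    return _make
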