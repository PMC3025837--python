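import numpy as np
import pytest

from secpred.sequences import ALPHABET, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def make_random_record(rng):
    """Factory for random valid records (uniform residues, default length 60)."""

    counter = {"n": 0}

    def _make(length: int = 60, rid: str | None = None) -> SequenceRecord:
        counter["n"] += 1
        residues = "".join(rng.choice(list(ALPHABET), size=length))
        return SequenceRecord(id=rid or f"rnd_{counter['n']:03d}", residues=residues)

    return _make


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">p1 first protein\nMKVLAT\nGHWERT\n>p2\nAAAA\n")
    return path
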