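import numpy as np
import pytest

from asmeval.contiguity import Assembly, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_assembly(seqs, name="test"):
    return Assembly(name=name, records=[
        SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs, start=1)
    ])


@pytest.fixture
def random_scaffolds(rng):
    """200 scaffolds with random lengths and occasional planted gap runs."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = []
    for _ in range(200):
        n = int(rng.integers(500, 5000))
        seq = bases[rng.integers(0, 4, size=n)].tobytes().decode()
        if rng.random() < 0.5:
            gap = "N" * int(rng.integers(10, 80))
            cut = int(rng.integers(1, n))
            seq = seq[:cut] + gap + seq[cut:]
        seqs.append(seq)
    return make_assembly(seqs)
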