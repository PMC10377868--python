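import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes bruteforce importable

from hbpred.sequences import ALPHABET, LabeledDataset, ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20230724)


@pytest.fixture
def random_sequences(rng):
    """100 random valid sequences spanning lengths 2-500."""
    lengths = np.concatenate([[2, 3, 5], rng.integers(2, 501, size=97)])
    return [
        "".join(rng.choice(list(ALPHABET), size=n)) for n in lengths
    ]


def make_dataset(n_pos: int, n_neg: int, length: int = 12, seed: int = 0) -> LabeledDataset:
    """Tiny labelled dataset of random valid sequences."""
    r = np.random.default_rng(seed)
    seqs = [
        ProteinSequence(
            id=f"s{i}", residues="".join(r.choice(list(ALPHABET), size=length))
        )
        for i in range(n_pos + n_neg)
    ]
    labels = np.array([1] * n_pos + [0] * n_neg)
    return LabeledDataset(sequences=seqs, labels=labels)


@pytest.fixture
def tiny_dataset():
    return make_dataset(6, 6)
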