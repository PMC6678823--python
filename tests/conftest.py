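import numpy as np
import pytest

import enhsnap as es


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast, deliberately easy generator setting for smoke tests:
    short sequences, few samples, low motif dosage."""
    return es.SyntheticSpec(n_per_class=24, length=60,
                            copies_positive=1, copies_strong=2, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return es.generate(tiny_spec)


@pytest.fixture(scope="session")
def tiny_encoded(tiny_dataset):
    seqs, y = tiny_dataset.layer(1)
    X, y = es.encode_dataset(seqs, y.tolist())
    return X, y.astype(float)


def random_encoded(rng, n=12, length=20):
    """Random valid encoded batch (not real sequences; for shape/grad tests)."""
    seqs = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
    X, _ = es.encode_dataset(seqs)
    y = rng.integers(0, 2, n).astype(float)
    return X, y
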