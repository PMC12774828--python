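import numpy as np
import pandas as pd
import pytest

from popsphere.io import GenotypeMatrix, LabelSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_gm(calls, chromosomes=None, samples=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if chromosomes is None:
        chromosomes = ["1"] * m
    markers = pd.DataFrame({
        "id": [f"m{j}" for j in range(m)],
        "chromosome": [str(c) for c in chromosomes],
        "position": np.arange(1, m + 1, dtype=np.int64) * 100,
    })
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


@pytest.fixture
def tiny_gm():
    """2 samples x 3 markers, one missing call."""
    return make_gm([[0, 1, 2], [2, -1, 0]])


@pytest.fixture
def random_gm(rng):
    calls = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
    return make_gm(calls)


@pytest.fixture
def tiny_labels():
    return LabelSet(table=pd.DataFrame({
        "sample_id": ["s0", "s1"],
        "subpopulation": ["A", "B"],
        "superpopulation": ["N", "S"],
    }))
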