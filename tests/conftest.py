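import warnings

import numpy as np
import pytest

from ddifuse import (
    BinaryDescriptorMatrix,
    DDIEventTable,
    SyntheticConfig,
    build_features,
    generate,
)


@pytest.fixture(autouse=True)
def _silence_empty_row_warnings():
    # all-zero descriptor rows occur by design in low-rate random fixtures
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*all-zero descriptor row.*")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_view(rng):
    bits = rng.integers(0, 2, size=(12, 10))
    return BinaryDescriptorMatrix(
        view_name="substructure",
        values=bits,
        drug_ids=tuple(f"D{i}" for i in range(12)),
    )


@pytest.fixture()
def small_events():
    pairs = np.array(
        [[0, 1, 1], [0, 2, 2], [1, 2, 1], [2, 3, 3], [1, 3, 2], [0, 4, 1]]
    )
    return DDIEventTable(pairs=pairs, n_classes=3)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small fully-signalled synthetic dataset shared across tests."""
    return generate(SyntheticConfig(n_drugs=40, n_classes=4, n_communities=3, seed=7))


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    return build_features(tiny_dataset)
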