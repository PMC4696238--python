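import numpy as np
import pytest

import flgrade as fg


@pytest.fixture(scope="session")
def palette_training_set():
    """Small seeded training set built from simulated annotated images."""
    images, annotations = fg.simulate_training_data(seed=7)
    return fg.build_training_set(images, annotations, seed=7)


@pytest.fixture(scope="session")
def table2():
    return fg.table2_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_histograms(rng, n):
    """Valid random 64-bin histograms (uniform positive weights, normalized)."""
    w = rng.random((n, 64)) + 1e-6
    return w / w.sum(axis=1, keepdims=True)
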