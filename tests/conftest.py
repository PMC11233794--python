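import numpy as np
import pytest

from tumorgrade.phantom import CLASSES, DatasetSpec, generate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(99)


@pytest.fixture(scope="session")
def small_phantom_set():
    """8 phantoms per class with ground-truth masks (session-cached)."""
    dspec = DatasetSpec(counts={c: 8 for c in CLASSES}, seed=17)
    images, masks, labels = generate_arrays(dspec)
    return images, masks, labels
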