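import numpy as np
import pytest

from angiosprout import cpm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_lattice(rng, shape=(30, 30), n_cells=6, blob=5):
    """Random multicell lattice: n_cells square seeds grown a little."""
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    for cid in range(1, n_cells + 1):
        y = int(rng.integers(2, h - blob - 2))
        x = int(rng.integers(2, w - blob - 2))
        labels[y:y + blob, x:x + blob] = cid
    # make sure every cell id is present
    present = np.unique(labels)
    for cid in range(1, n_cells + 1):
        if cid not in present:
            labels[2 * cid:2 * cid + 2, 0:2] = cid
    return labels


@pytest.fixture
def small_lattice(rng):
    labels = random_lattice(rng)
    return cpm.LatticeState(labels, target_area=20.0)
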