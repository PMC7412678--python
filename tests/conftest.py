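import numpy as np
import pytest

from ceseg import synthetic as syn
from ceseg.labels import make_probabilistic_labels


@pytest.fixture(scope="session")
def small_mosaic():
    """128x128 mosaic with ~40 cells; (truth, gold) with known ground truth."""
    truth, gold = syn.generate_mosaic(
        syn.MosaicSpec(height=128, width=128, n_cells=40, seed=11)
    )
    return truth, gold


@pytest.fixture(scope="session")
def small_prob_label(small_mosaic):
    _, gold = small_mosaic
    return make_probabilistic_labels(gold)


@pytest.fixture(scope="session")
def hex_mosaic():
    """Perfectly regular hexagonal mosaic, pitch 26 px."""
    return syn.generate_mosaic(
        syn.MosaicSpec(height=240, width=528, lattice="hex", hex_spacing=26.0, seed=1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
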