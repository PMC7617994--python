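import numpy as np
import pytest

from caenodiverge import pipeline
from caenodiverge import synthetic_world as sw


@pytest.fixture(scope="session")
def small_world():
    """A fast, fully structured world for unit tests."""
    cfg = sw.WorldConfig(
        n_classes=16,
        n_genes_111=80,
        n_genes_none=10,
        n_orthogroups_multi=4,
        cells_per_class=40,
        seed=1,
    )
    return sw.make_world(cfg)


@pytest.fixture(scope="session")
def noiseless_world():
    """Default-scale world with zero noise: the closure reference."""
    cfg = sw.WorldConfig(seed=2, off_mean=0.0, ambient_rate=0.0)
    return sw.make_world(cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_world):
    """Binarization of the noiseless world with full ground truth."""
    return pipeline.binarize_world(
        noiseless_world, seed=5, gt_fraction=1.0, trees=300, folds=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
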