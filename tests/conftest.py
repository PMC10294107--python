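import numpy as np
import pytest

from seedseg import GenConfig, RetinexParams, generate_scene


@pytest.fixture(scope="session")
def small_config():
    """A compact scene: 12 seeds on 512x384 px, one designated touching pair."""
    return GenConfig(width=512, height=384, n_seeds=12, touching_fraction=0.2, rng_seed=7)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def fast_retinex():
    """Surround scales shrunk to the small-scene geometry to keep unit tests quick."""
    return RetinexParams(scales=(8.0, 40.0, 120.0), weights=(1 / 3, 1 / 3, 1 / 3))


@pytest.fixture(scope="session")
def pair_cluster(small_scene):
    """Connected foreground cluster of the designated touching pair (incl. bridge)."""
    import scipy.ndimage as ndi

    _, truth = small_scene
    (i, j) = truth.touching_pairs[0]
    labels, _ = ndi.label(truth.union_mask, structure=np.ones((3, 3), bool))
    cx, cy = truth.seeds[i].center
    lab = labels[int(round(cy)), int(round(cx))]
    assert lab > 0
    return labels == lab, (i, j)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
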