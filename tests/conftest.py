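import numpy as np
import pytest

from phenocloud import LabeledCloud, PlantSpec, make_plant


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_spec():
    """A small, fast, noiseless 5-leaf plant."""
    return PlantSpec(
        stem_height=1.0,
        stem_radius=0.015,
        n_leaves=5,
        points_per_organ=1200,
        noise_sigma=0.0,
        seed=42,
    )


@pytest.fixture
def simple_plant(simple_spec):
    return make_plant(simple_spec)


@pytest.fixture
def random_cloud(rng):
    return LabeledCloud(
        coords=rng.random((200, 3)),
        semantic_labels=rng.integers(0, 2, 200),
    )
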