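import numpy as np
import pytest

from chromacc.catalog import build_synthetic_catalog
from chromacc.colorimetry import ColorContext
from chromacc.scenes import (
    IlluminantSet,
    default_scene_config,
    make_test_illuminants,
    make_training_illuminants,
)


@pytest.fixture(scope="session")
def ctx():
    return ColorContext.default()


@pytest.fixture(scope="session")
def catalog(ctx):
    """The default desk-scale calibrated catalog (~164 classes)."""
    return build_synthetic_catalog(ctx=ctx)


@pytest.fixture(scope="session")
def small_catalog(ctx):
    """A fast 4x2x2 grid (+2 neutrals) for structural tests."""
    return build_synthetic_catalog(
        n_hues=4, n_values=2, n_chromas=2, spacing_target=7.3, ctx=ctx
    )


@pytest.fixture(scope="session")
def test_illums(ctx):
    return make_test_illuminants(10.0, ctx)


@pytest.fixture(scope="session")
def train_illums(ctx):
    """Desk-scale training set: 5 D-series + 35 jittered emulants."""
    return make_training_illuminants(5, 35, 8.55, seed=0, ctx=ctx)


@pytest.fixture(scope="session")
def d65_only(ctx):
    return IlluminantSet(["D65"], {}, {}, {}, ctx)


@pytest.fixture(scope="session")
def scene_cfg(catalog):
    return default_scene_config(catalog)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
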