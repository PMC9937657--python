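"""Shared fixtures.

Heavy artifacts (the trained toy source model and its phantom cohorts)
are session-scoped so the training cost is paid once for the whole
suite, including the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import brainext as bx

TOY_MODEL = dict(depth=4, base_channels=8, in_plane_size=64, dropout_rate=0.2)
N_SOURCE_TRAIN = 30
N_SOURCE_TEST = 5
SOURCE_EPOCHS = 8


@pytest.fixture(scope="session")
def source_spec() -> bx.DomainSpec:
    """Source-domain phantom: T2-like contrast, mild noise, wobbled ellipsoid."""
    return bx.DomainSpec(noise_sd=0.05, surface_wobble=0.05)


@pytest.fixture(scope="session")
def source_train(source_spec):
    return [bx.make_phantom(source_spec, i) for i in range(N_SOURCE_TRAIN)]


@pytest.fixture(scope="session")
def source_test(source_spec):
    return [bx.make_phantom(source_spec, 1000 + i) for i in range(N_SOURCE_TEST)]


@pytest.fixture(scope="session")
def toy_config() -> bx.ModelConfig:
    return bx.ModelConfig(seed=0, **TOY_MODEL)


@pytest.fixture(scope="session")
def source_model(toy_config, source_train):
    """Toy network trained on the source phantom domain (shared)."""
    model = bx.build_model(toy_config)
    tcfg = bx.TrainConfig(epochs=SOURCE_EPOCHS, seed=0)
    model, trace = bx.train_supervised(model, source_train, tcfg, role="source")
    model._training_trace = trace
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
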