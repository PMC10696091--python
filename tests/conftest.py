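import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microseek import simulate as sim

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
from microseek.classifier import train_classifier
from microseek.network import ClassifierConfig
from microseek.segmentation import SegmentationConfig, build_dataset

# Equal strides because the synthetic classes have equal total length; the
# per-class stride defaults (26 / 2 / 130) compensate for the very unequal
# class sizes of real reference collections instead.
FIXTURE_STRIDES = {"human": 10, "viral": 10, "bacterial": 10}


@pytest.fixture(scope="session")
def origin_models():
    return sim.divergent_origin_models(0)


@pytest.fixture(scope="session")
def training_references(origin_models):
    return sim.make_references(origin_models, 30, (800, 1600), rng_seed=1)


@pytest.fixture(scope="session")
def datasets(training_references):
    cfg = SegmentationConfig(stride_by_class=dict(FIXTURE_STRIDES))
    return build_dataset(training_references, cfg, rng_seed=2)


@pytest.fixture(scope="session")
def trained_model(datasets):
    return train_classifier(datasets, ClassifierConfig(epochs=5, rng_seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
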