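import numpy as np
import pytest

from shadea import GeneratorConfig, generate, make_fixture
from shadea.dea import DEAInstance


@pytest.fixture(scope="session")
def tiny3():
    return make_fixture("tiny3")


@pytest.fixture(scope="session")
def frontier4():
    return make_fixture("frontier4")


@pytest.fixture(scope="session")
def andalusia65():
    return make_fixture("andalusia65")


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 12-area dataset with the full variable registry."""
    return generate(GeneratorConfig(n_areas=12, seed=7))


def xy_instance(dataset) -> DEAInstance:
    """DEAInstance from a 1-input/1-output fixture dataset."""
    ids = [rec.area_id for rec in dataset.areas]
    X = np.array([[rec.rates["staff"]] for rec in dataset.areas])
    Y = np.array([[rec.rates["users"]] for rec in dataset.areas])
    return DEAInstance(dmu_ids=ids, X=X, Y=Y)


def random_instance(rng, n_dmu=4, m_in=2, m_out=1) -> DEAInstance:
    X = rng.uniform(0.5, 5.0, size=(n_dmu, m_in))
    Y = rng.uniform(0.5, 5.0, size=(n_dmu, m_out))
    return DEAInstance(dmu_ids=[f"D{i}" for i in range(n_dmu)], X=X, Y=Y)
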