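import numpy as np
import pytest

from idrsig.features import FeatureCatalog
from idrsig.simulate import IndelModel, SubstitutionModel
from idrsig.synth import gen_root_idr, gen_tree


@pytest.fixture(scope="session")
def catalog():
    return FeatureCatalog.default()


@pytest.fixture(scope="session")
def model():
    return SubstitutionModel.default()


@pytest.fixture(scope="session")
def small_tree():
    return gen_tree(8, 1.0, seed=11)


@pytest.fixture(scope="session")
def root60():
    return gen_root_idr(60, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def no_indels():
    return IndelModel.none()
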