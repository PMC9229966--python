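import numpy as np
import pytest

from cefpbpk.compound import (load_compound, load_tissue_composition,
                              predict_kp_set)
from cefpbpk.physiology import PopulationSpec, reference_adult


@pytest.fixture(scope="session")
def composition():
    return load_tissue_composition()


@pytest.fixture(scope="session")
def cefazolin():
    return load_compound("cefazolin")


@pytest.fixture(scope="session")
def cefuroxime():
    return load_compound("cefuroxime")


@pytest.fixture(scope="session")
def ref_subject():
    return reference_adult()


@pytest.fixture(scope="session")
def kps_cefazolin(cefazolin, composition):
    return predict_kp_set(cefazolin, composition)


@pytest.fixture(scope="session")
def lean_spec():
    return PopulationSpec(population_class="lean", n_subjects=4,
                          proportion_female=1.0, target_mean_weight=62.3,
                          seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
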