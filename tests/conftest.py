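import warnings

import numpy as np
import pytest

from ipmncea import base_case_parameters, bundled_us_2017
from ipmncea.lifetables import LifeTable


@pytest.fixture(scope="session")
def base_params():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return base_case_parameters()


@pytest.fixture(scope="session")
def life_table():
    return bundled_us_2017()


@pytest.fixture(scope="session")
def zero_mortality_table():
    ages = np.arange(60, 101)
    return LifeTable(ages=ages, qx=np.zeros(ages.size))
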