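import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from ktcea.life_tables import LifeTable, MortalityModel, make_gompertz_life_table
from ktcea.parameters import load_parameters

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def life_table():
    return make_gompertz_life_table()


@pytest.fixture(scope="session")
def mortality(params, life_table):
    return MortalityModel.from_parameters(params, life_table)


def flat_life_table(q, min_age=0, max_age=110):
    """Life table with the same annual death probability at every age."""
    ages = np.arange(min_age, max_age + 1)
    return LifeTable(ages=ages, qx=np.full(len(ages), q))


@pytest.fixture(scope="session")
def zero_mortality(params):
    return MortalityModel.from_parameters(params, flat_life_table(0.0))


@pytest.fixture(scope="session")
def identity_mortality():
    """SMR 1 everywhere, ratio 1: disease mortality equals the general population."""
    return MortalityModel(
        life_table=make_gompertz_life_table(),
        smr_bands=((0.0, 59.0, 1.0), (60.0, 69.0, 1.0), (70.0, 79.0, 1.0), (80.0, np.inf, 1.0)),
        eskd_vs_kt_ratio=1.0,
    )
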