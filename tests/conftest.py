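import numpy as np
import pytest

from cystotriage.lifetable import GompertzParams, make_life_table
from cystotriage.parameters import build_base_case


@pytest.fixture(scope="session")
def base_params():
    return build_base_case()


@pytest.fixture(scope="session")
def life_table(base_params):
    return make_life_table(start_age=base_params.start_age,
                           male_fraction=base_params.male_fraction)


@pytest.fixture(scope="session")
def zero_mortality_life_table():
    """All-cause mortality switched off (deterministic-dynamics checks)."""
    zero = GompertzParams(level=0.0, slope=0.1)
    return make_life_table(male=zero, female=zero)


@pytest.fixture
def rng():
    return np.random.default_rng(20140823)


def no_death_params(**extra):
    """Parameter set with every mortality/progression source zeroed."""
    overrides = {
        "p_bcdeath_nmibc": 0.0, "p_bcdeath_mibc": 0.0,
        "p_bcdeath_mibc_late": 0.0, "p_bcdeath_met": 0.0,
        "p_turbt_mort": 0.0, "p_cystectomy_mort": 0.0,
        "p_prog_hrbcg_mibc": 0.0, "p_prog_hrbcg_met": 0.0,
        "p_prog_hrcyst_met": 0.0, "p_prog_mibc_met": 0.0,
        "p_prog_mibc_met_late": 0.0,
        "p_rec_lr": 0.0, "p_rec_hr": 0.0,
    }
    overrides.update(extra)
    return build_base_case(overrides)
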