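import numpy as np
import pytest

import robustsem as rs


@pytest.fixture(scope="session")
def gen_params():
    return rs.generating_parameters()


@pytest.fixture(scope="session")
def spec_correct():
    return rs.correct_spec()


@pytest.fixture(scope="session")
def spec_misspecified():
    return rs.misspecified_spec()


@pytest.fixture(scope="session")
def clean_300(gen_params):
    """One clean dataset of 300 rows from the study generating model."""
    return rs.generate_clean(300, gen_params, seed=20240901)


@pytest.fixture(scope="session")
def clean_fit_normal(clean_300, spec_correct):
    return rs.fit_ml_normal(clean_300.data, spec_correct)
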