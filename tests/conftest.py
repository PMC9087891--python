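import pytest

from mscipost import parse_model
from mscipost.model import BDIEvent

from model_specs import (
    FIG1_TEXT,
    FIG5A_TEXT,
    FIG5B_TEXT,
    FIG6A_TEXT,
    FIG11D_TEXT,
    PLAIN_TREE_TEXT,
    S3_TEXT,
)


@pytest.fixture(scope="session")
def fig1_model():
    return parse_model(FIG1_TEXT)


@pytest.fixture(scope="session")
def fig5a_model():
    return parse_model(FIG5A_TEXT)


@pytest.fixture(scope="session")
def fig5b_model():
    return parse_model(FIG5B_TEXT)


@pytest.fixture(scope="session")
def fig6a_model():
    return parse_model(FIG6A_TEXT)


@pytest.fixture(scope="session")
def s3_model():
    return parse_model(S3_TEXT)


@pytest.fixture(scope="session")
def fig11d_model():
    return parse_model(FIG11D_TEXT)


@pytest.fixture(scope="session")
def plain_tree_model():
    return parse_model(PLAIN_TREE_TEXT)


@pytest.fixture(scope="session")
def single_event():
    return BDIEvent(nodes=("X", "Y"), time=0.00125, phi_params=("phi_X", "phi_Y"),
                    theta_params=("theta_X", "theta_Y"), sister=True)
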