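import pytest

from methanoflux import constants
from methanoflux.mechanisms import ReactionIdMap
from methanoflux.synthetic_data import build_core_model


@pytest.fixture(scope="session")
def core_model():
    """The packaged core methanotroph model (session-scoped, treat as read-only)."""
    return build_core_model()


@pytest.fixture(scope="session")
def idmap():
    return ReactionIdMap()


@pytest.fixture
def methane_growth_bounds():
    """Redox-arm reference constraints: uptake 14.9, NGAM 3.5."""
    return {
        "EX_ch4_e0": (-constants.CH4_UPTAKE, -constants.CH4_UPTAKE),
        "ATPM": (constants.NGAM_ATP, constants.NGAM_ATP),
        "pMMO1": (0.0, 0.0),
    }
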