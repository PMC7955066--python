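import numpy as np
import pytest

from aavsim import AssemblyModel, InstrumentModel, VPRatio
from aavsim.synthetic import VP1_MASS, VP2_MASS, VP3_MASS


@pytest.fixture(scope="session")
def aav_model() -> AssemblyModel:
    """AAV-like 3-species, 60-subunit assembly model."""
    return AssemblyModel((VP1_MASS, VP2_MASS, VP3_MASS))


@pytest.fixture(scope="session")
def aav9_ratio() -> VPRatio:
    return VPRatio(0.06, 0.16, 0.78)


@pytest.fixture(scope="session")
def wide_instrument() -> InstrumentModel:
    """m/z window covering the zero-offset AAV envelopes, 1 Th bins."""
    return InstrumentModel(grid_min=20000.0, grid_max=29000.0, grid_step=1.0)


@pytest.fixture(scope="session")
def narrow_instrument() -> InstrumentModel:
    """Small window for cheap single-peak rendering tests."""
    return InstrumentModel(grid_min=20000.0, grid_max=23000.0, grid_step=0.25)
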