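import numpy as np
import pytest

from cdc42polar.geometry import CellGeometry, build_mesh
from cdc42polar.params import ModelParams


@pytest.fixture(scope="session")
def default_mesh():
    """Reference mesh (L=8, R=2, default resolution), shared across tests."""
    return build_mesh(CellGeometry(), seed=0)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small, fast mesh for plumbing tests (outside the default area band)."""
    return build_mesh(CellGeometry(target_cell_area=0.35), seed=0)


@pytest.fixture()
def table1():
    """Reference parameter set."""
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
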