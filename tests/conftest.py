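import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from benthoscape.grids import DepthGrid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def flat_grid() -> DepthGrid:
    """Featureless 30 m deep plain, 40x40 cells of 10 m."""
    return DepthGrid(values=np.full((40, 40), 30.0), x0=0.0, y0=400.0, cell=10.0)


@pytest.fixture
def plane_grid() -> DepthGrid:
    """Inclined plane deepening seaward at 0.1 m/m."""
    rows = np.arange(40)[:, None] + 0.5
    values = np.broadcast_to(1.0 + rows * 0.1 * 10.0, (40, 40)).copy()
    return DepthGrid(values=values, x0=0.0, y0=400.0, cell=10.0)
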