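import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tagburden as tb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: Modelled swim speeds (m/s) and their published Reynolds numbers for the
#: 2.95 m adult, used across test modules.
SPEEDS = (0.5, 1.0, 1.5, 2.0, 3.6, 5.0, 7.8, 9.1)
SIZES = (1.0, 1.5, 2.0, 2.5, 2.95)


@pytest.fixture(scope="session")
def fluid():
    return tb.FluidProperties(density=1025.0, dynamic_viscosity=0.00109)


@pytest.fixture(scope="session")
def adult():
    """Full-size adult geometry with the default frontal area (~0.12 m^2)."""
    return tb.SharkGeometry(fork_length=2.95)


@pytest.fixture(scope="session")
def tables():
    return tb.packaged_drag_tables()


@pytest.fixture()
def constant_ratio_tables():
    """Synthetic pair with a speed-independent drag-coefficient ratio 1.273."""
    speeds = np.array(SPEEDS)
    base = np.full((len(SPEEDS), 1), 0.08)
    untag = tb.DragCoefficientTable(speeds, [2.95], base, config="none")
    tag = tb.DragCoefficientTable(speeds, [2.95], base * 1.273, config="fin_mount")
    return untag, tag
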