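import numpy as np
import pytest

from palasym import default_palate_schema, make_palate_geometry
from palasym.simulate import SimulationSpec, simulate_population


@pytest.fixture(scope="session")
def schema():
    return default_palate_schema()


@pytest.fixture(scope="session")
def palate():
    """(GeometryBundle, template coordinates) for the default dome."""
    return make_palate_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_population():
    """Six small groups with modest asymmetry; rigid motions applied."""
    spec = SimulationSpec(
        n_per_group=(5, 6, 5, 6, 8, 6),
        da_magnitude=(0.1, 0.4, 0.2, 0.2, 0.2, 0.3),
        seed=77,
    )
    return simulate_population(spec)
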