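import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon

from bycatch.geometry import DomainSpec, gen_domain
from bycatch.hurdle import BoundaryWarning
from bycatch.mesh import build_mesh
from bycatch.synth import (TruthParams, gen_climate_series, gen_fleet,
                           gen_observer_data, zero_field_sampler)


@pytest.fixture(scope="session")
def domain():
    return gen_domain(1)


@pytest.fixture(scope="session")
def unit_square():
    """Unit-square domain in planar units (scale 1), no barrier."""
    return DomainSpec(boundary=Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]),
                      planar_scale=(1.0, 1.0))


@pytest.fixture(scope="session")
def slit_domain():
    """10x10 planar square with a thin horizontal slit barrier."""
    return DomainSpec(
        boundary=Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
        barriers=[Polygon([(1, 4.7), (9, 4.7), (9, 5.3), (1, 5.3)])],
        planar_scale=(1.0, 1.0))


@pytest.fixture(scope="session")
def small_mesh(slit_domain):
    return build_mesh(slit_domain, 0.8, 1.6, extension_km=1.6)


@pytest.fixture(scope="session")
def observer_data(domain):
    """Moderate synthetic observer dataset without a spatial field."""
    truth = TruthParams(vessel_sd=0.0, field_amplitude=0.0)
    fleet = gen_fleet(domain, truth, 8000, range(2004, 2012), seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BoundaryWarning)
        obs = gen_observer_data(fleet, truth, zero_field_sampler, 1.0, seed=43)
    return obs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
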