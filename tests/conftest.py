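import pytest

from reefdrift import Domain, HabitatGrid, RunParams, make_analytic_flow


@pytest.fixture
def wide_domain():
    return Domain(180.0, 230.0, 0.0, 40.0)


@pytest.fixture
def still_water(wide_domain):
    return make_analytic_flow("uniform", {"u0": 0.0, "v0": 0.0}, wide_domain)


@pytest.fixture
def eastward_half(wide_domain):
    """Uniform 0.5 m/s eastward current."""
    return make_analytic_flow("uniform", {"u0": 0.5, "v0": 0.0}, wide_domain)


@pytest.fixture
def two_island_grid():
    """Two single-pixel islands 1 degree apart on the 20N parallel."""
    return HabitatGrid.from_arrays([200.0, 201.0], [20.0, 20.0], [0, 1])


@pytest.fixture
def deterministic_params():
    return RunParams(eddy_diffusivity=0.0, replicates=1, particles_per_pixel_per_day=5)
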