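import numpy as np
import pytest

from cvdom import (MediumMap, OpticalProperties, SolverConfig,
                   TransportProblem, build_grid, make_cw_source,
                   make_ordinates, uniform_detectors)


@pytest.fixture(scope="session")
def ords16():
    return make_ordinates(16)


@pytest.fixture(scope="session")
def small_grid():
    return build_grid(1.0, 1.0, 0.05, 0.05)


@pytest.fixture()
def scattering_medium(small_grid):
    """1 cm x 1 cm tissue-like medium: mu_a=1, mu_s=5 (isotropic), n=1.4."""
    return MediumMap.homogeneous(small_grid, OpticalProperties(1.0, 5.0, 0.0),
                                 n_m=1.4)


@pytest.fixture()
def small_problem(scattering_medium):
    grid = scattering_medium.grid
    return TransportProblem(scattering_medium, 16,
                            [make_cw_source("bottom", 0.5)],
                            uniform_detectors("top", grid, 5),
                            SolverConfig())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
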