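import numpy as np
import pytest

from hpmono.cell_models import lr91_noble_form, lr91_standard
from hpmono.drivers import calibrate_beta
from hpmono.meshing import build_square_mesh, build_square_with_holes_mesh


@pytest.fixture(scope="session")
def noble_model():
    return lr91_noble_form()


@pytest.fixture(scope="session")
def standard_model():
    return lr91_standard()


@pytest.fixture(scope="session")
def small_square_mesh():
    """Coarse unit-square mesh reused across structural tests."""
    return build_square_mesh(1.0, 0.15, seed=0)


@pytest.fixture(scope="session")
def holes_mesh():
    return build_square_with_holes_mesh(1.0, target_h=0.05, seed=1)


@pytest.fixture(scope="session")
def calibration():
    """One-scalar calibration of beta: converged 1D CV at sigma = 1 S/m,
    h = 0.01 cm, p = 4 matched to 64.52 cm/s.  Shared by every acceptance
    test that needs absolute conduction velocities."""
    return calibrate_beta(target_cv=64.52, sigma=1.0, h=0.01, p=4, dt=0.01,
                          beta0=1400.0, iterations=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
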