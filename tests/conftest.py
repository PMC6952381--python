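import numpy as np
import pytest

from dynscatter import constants as cst
from dynscatter.atomic_physics import DEFAULT_PARAMS, solve_hfs
from dynscatter.sphere_fit import DetectorGeometry


@pytest.fixture(scope="session")
def oxygen_gs():
    """Ground-state oxygen HFS solution (cached for the whole session)."""
    return solve_hfs("O", None, DEFAULT_PARAMS)


@pytest.fixture(scope="session")
def small_geometry():
    """Downsampled two-panel detector for fast sphere-model fits (1000 eV)."""
    lam = cst.photon_energy_to_wavelength_nm(1000.0)
    return DetectorGeometry(
        wavelength_nm=lam, pixel_pitch_mm=0.6, n_rows_panel=64, n_cols=128
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
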