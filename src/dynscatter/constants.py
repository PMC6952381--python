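"""Physical constants and unit conversions.

Internal atomic-physics work is done in Hartree atomic units; interfaces
use the field's conventional units (eV, fs, nm, barn, uJ/um^2).
"""

import numpy as np
import scipy.constants as _c

# --- fundamental ---
FINE_STRUCTURE = _c.fine_structure          # alpha
HARTREE_EV = _c.value("Hartree energy in eV")           # 27.211386...
BOHR_M = _c.value("Bohr radius")                        # m
BOHR_NM = BOHR_M * 1e9
HBAR_EVS = _c.hbar / _c.e                               # eV s
HBAR_EV_FS = HBAR_EVS * 1e15                            # eV fs (0.6582...)
R_ELECTRON_M = _c.value("classical electron radius")    # m
R_ELECTRON_NM = R_ELECTRON_M * 1e9
THOMSON_CS_BARN = 8.0 * np.pi / 3.0 * (R_ELECTRON_M * 1e14) ** 2  # 0.6652 barn

# --- areas ---
BARN_M2 = 1e-28
BOHR2_BARN = (BOHR_M * 1e14) ** 2           # a0^2 in barn (2.80e7)
MBARN_BARN = 1e6

# --- atomic unit of time ---
ATOMIC_TIME_S = _c.hbar / (_c.value("Hartree energy"))
ATOMIC_TIME_FS = ATOMIC_TIME_S * 1e15       # 0.02418884 fs

# --- fluence conversions ---
EV_J = _c.e


def photon_energy_to_wavelength_nm(energy_ev: float) -> float:
    """lambda [nm] = hc / E."""
    return _c.h * _c.c / (energy_ev * _c.e) * 1e9


def wavelength_nm_to_photon_energy(lam_nm: float) -> float:
    return _c.h * _c.c / (lam_nm * 1e-9 * _c.e)


def fluence_uJ_um2_to_photons_per_nm2(fluence_uJ_um2: float, photon_energy_ev: float) -> float:
    """Convert an energy fluence (uJ/um^2) to a photon-number fluence (photons/nm^2)."""
    joule_per_m2 = fluence_uJ_um2 * 1e-6 / 1e-12
    photons_per_m2 = joule_per_m2 / (photon_energy_ev * _c.e)
    return photons_per_m2 * 1e-18


# 1 uJ/um^2 = 1e-6 J / 1e-12 m^2 = 1e6 J/m^2
J_M2_PER_UJ_UM2 = 1e6


def photons_per_nm2_to_uJ_um2(photons_per_nm2: float, photon_energy_ev: float) -> float:
    photons_per_m2 = photons_per_nm2 * 1e18
    joule_per_m2 = photons_per_m2 * photon_energy_ev * _c.e
    return joule_per_m2 / J_M2_PER_UJ_UM2

# Avogadro
N_AVOGADRO = _c.N_A

# atomic masses (u) for the species handled here
ATOMIC_MASS_U = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Ar": 39.948}
ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "Ar": 18}
U_KG = _c.u

# electron mass in u (for MD where masses are in u)
ELECTRON_MASS_U = _c.m_e / _c.u

# Coulomb constant in (eV nm / e^2): V(r) = KE2 * q1*q2 / r[nm] -> eV
COULOMB_EV_NM = _c.e / (4.0 * np.pi * _c.epsilon_0) * 1e9
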