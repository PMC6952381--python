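"""XFEL pulse description: Gaussian temporal envelope and spectral bandwidth.

The temporal profile ``j_X(t)`` is a photon-flux density (photons/nm^2/fs,
centered on t = 0) whose time integral is the photon fluence; the spectral
profile ``g(w, w_x)`` is a unit-normalized Gaussian with a fractional FWHM
bandwidth (default 1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.constants as _c
from numpy.polynomial.hermite import hermgauss

from . import constants as cst

_G = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma


@dataclass(frozen=True)
class PulseSpec:
    """XFEL pulse parameters.

    fluence is stored as an energy fluence in uJ/um^2; the photon-number
    fluence follows from the photon energy.
    """

    photon_energy_ev: float
    fwhm_fs: float
    fluence_uJ_um2: float
    bandwidth_fwhm_fraction: float = 0.01

    def __post_init__(self):
        if self.photon_energy_ev <= 0 or self.fwhm_fs <= 0:
            raise ValueError("photon energy and duration must be positive")
        if self.fluence_uJ_um2 < 0:
            raise ValueError("fluence must be non-negative")

    # -- fluence -----------------------------------------------------------
    @property
    def photon_fluence_per_nm2(self) -> float:
        return cst.fluence_uJ_um2_to_photons_per_nm2(
            self.fluence_uJ_um2, self.photon_energy_ev
        )

    @property
    def wavelength_nm(self) -> float:
        return cst.photon_energy_to_wavelength_nm(self.photon_energy_ev)

    @property
    def bandwidth_fwhm_ev(self) -> float:
        return self.bandwidth_fwhm_fraction * self.photon_energy_ev

    # -- temporal profile --------------------------------------------------
    @property
    def sigma_t_fs(self) -> float:
        return self.fwhm_fs / _G

    def temporal_profile(self, t_fs):
        """photon flux j_X(t) in photons / nm^2 / fs (Gaussian, center 0)."""
        s = self.sigma_t_fs
        norm = self.photon_fluence_per_nm2 / (s * math.sqrt(2.0 * math.pi))
        t = np.asarray(t_fs, dtype=float)
        return norm * np.exp(-0.5 * (t / s) ** 2)

    def time_window_fs(self, n_sigma: float = 4.0) -> tuple[float, float]:
        """Window containing >= 99.99% of the pulse energy at n_sigma = 4."""
        half = n_sigma * self.sigma_t_fs
        return (-half, half)

    # -- spectral profile --------------------------------------------------
    def spectral_profile(self, omega_ev):
        """g(w, w_x): unit-normalized Gaussian in photon energy (1/eV)."""
        s = self.bandwidth_fwhm_ev / _G
        w = np.asarray(omega_ev, dtype=float)
        return np.exp(-0.5 * ((w - self.photon_energy_ev) / s) ** 2) / (
            s * math.sqrt(2.0 * math.pi)
        )

    def bandwidth_quadrature(self, n_nodes: int = 7):
        """Gauss-Hermite nodes/weights for averaging over g(w, w_x).

        Returns (omega_ev nodes, weights) with weights summing to 1:
        ``int g(w) f(w) dw ~= sum_i w_i f(w_i)``.
        """
        x, w = hermgauss(n_nodes)
        s = self.bandwidth_fwhm_ev / _G
        omega = self.photon_energy_ev + math.sqrt(2.0) * s * x
        return omega, w / math.sqrt(math.pi)

    # -- field quantities (for the two-level estimate) ---------------------
    @property
    def peak_intensity_W_m2(self) -> float:
        """Peak of the Gaussian intensity envelope."""
        fluence_J_m2 = self.fluence_uJ_um2 * cst.J_M2_PER_UJ_UM2
        return fluence_J_m2 / (self.fwhm_fs * 1e-15 * math.sqrt(math.pi / (4 * math.log(2))))

    @property
    def peak_field_V_m(self) -> float:
        return math.sqrt(2.0 * self.peak_intensity_W_m2 / (_c.epsilon_0 * _c.c))

    def field_envelope_V_m(self, t_fs):
        """Field envelope E(t); intensity envelope is its square."""
        t = np.asarray(t_fs, dtype=float)
        return self.peak_field_V_m * np.exp(
            -2.0 * math.log(2.0) * (t / self.fwhm_fs) ** 2
        )
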