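import math

import numpy as np
import pytest

from dynscatter import constants as cst
from dynscatter._radial import bound_state, continuum_wave
from dynscatter.atomic_physics import (
    DEFAULT_PARAMS,
    ExtrapolationError,
    HFSParams,
    kramers_kronig,
    resonant_cs,
    solve_hfs,
)
from dynscatter.configuration import ElectronicConfiguration, InvalidConfigurationError


# ----------------------------------------------------------------------
# radial-solver oracles
# ----------------------------------------------------------------------

class TestHydrogenOracles:
    """Pure-Coulomb problems with known analytic solutions."""

    @pytest.mark.parametrize(
        "n,l,exact",
        [(1, 0, -0.5), (2, 0, -0.125), (2, 1, -0.125), (3, 2, -0.5 / 9.0)],
    )
    def test_eigenvalues(self, n, l, exact):
        r = np.geomspace(1e-5, 40.0, 3200)
        e, u = bound_state(r, -1.0 / r, n, l)
        assert e == pytest.approx(exact, rel=1e-2)
        # normalized
        h = math.log(r[1] / r[0])
        assert np.trapezoid(u * u * r, dx=h) == pytest.approx(1.0, rel=1e-6)

    def test_hydrogen_1s_energy_in_ev(self):
        """The -13.6 eV benchmark for the radial solver (exchange-free)."""
        r = np.geomspace(1e-5, 40.0, 3200)
        e, _ = bound_state(r, -1.0 / r, 1, 0)
        assert e * cst.HARTREE_EV == pytest.approx(-13.605, rel=1e-2)

    @pytest.mark.parametrize("omega_ev", [20.0, 50.0, 150.0])
    def test_photoionization_matches_stobbe(self, omega_ev):
        """Hydrogenic photo cross section against the closed-form result."""
        r = np.geomspace(1e-5, 40.0, 3200)
        e1, u1 = bound_state(r, -1.0 / r, 1, 0)
        dr = 0.004
        r_lin = (np.arange(6250) + 1.0) * dr
        u_b = np.interp(r_lin, r, u1, left=0.0, right=0.0)
        w = omega_ev / cst.HARTREE_EV
        u_c = continuum_wave(r_lin, -1.0 / r_lin, w + e1, 1)
        dip = np.trapezoid(u_c * r_lin * u_b, dx=dr)
        sigma = (4 * math.pi**2 * cst.FINE_STRUCTURE / 3.0) * w * dip**2
        assert sigma == pytest.approx(_stobbe_au(w), rel=0.03)


def _stobbe_au(omega_au, z=1.0):
    """Closed-form nonrelativistic hydrogenic K-shell photo cross section (a.u.)."""
    ip = z * z / 2.0
    nu = math.sqrt(ip / (omega_au - ip))
    pref = 2**9 * math.pi**2 / 3.0 * cst.FINE_STRUCTURE / z**2
    return (
        pref
        * (ip / omega_au) ** 4
        * math.exp(-4.0 * nu * math.atan(1.0 / nu))
        / (1.0 - math.exp(-2.0 * math.pi * nu))
    )


# ----------------------------------------------------------------------
# SCF solutions
# ----------------------------------------------------------------------

class TestSolveHFS:
    def test_density_normalization(self, oxygen_gs):
        assert oxygen_gs.density_norm() == pytest.approx(8.0, rel=1e-4)

    @pytest.mark.parametrize(
        "element,occ,n_el",
        [("C", (2, 2, 2), 6), ("O", (1, 2, 4), 7), ("O", (2, 2, 2), 6), ("Ar", (2, 2, 6, 2, 6), 18)],
    )
    def test_density_normalization_ions(self, element, occ, n_el):
        d = solve_hfs(element, ElectronicConfiguration(element, occ))
        assert d.density_norm() == pytest.approx(n_el, rel=1e-4)

    def test_core_excited_configuration_lists_k_resonance(self):
        """The K-vacancy, open-2p configuration carries a 1s->2p entry."""
        d = solve_hfs("O", ElectronicConfiguration("O", (1, 2, 5)))
        t = d.find_transition("1s", "2p")
        assert t.f_osc > 0
        assert t.gamma_ev > 0

    def test_invalid_occupation_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            solve_hfs("O", ElectronicConfiguration("O", (2, 2, 7)))

    def test_caching_returns_same_object(self, oxygen_gs):
        assert solve_hfs("O", None, DEFAULT_PARAMS) is oxygen_gs


# ----------------------------------------------------------------------
# photoionization
# ----------------------------------------------------------------------

class TestPhotoionization:
    def test_zero_below_threshold(self, oxygen_gs):
        thr = oxygen_gs.ionization_threshold_ev("2p")
        assert oxygen_gs.photoionization_cs("2p", 0.5 * thr) == 0.0
        assert oxygen_gs.photoionization_cs("2p", thr * 1.2) > 0.0

    def test_k_shell_closed_below_edge(self, oxygen_gs):
        """Direct K ionization of ground-state O must be closed at 530 eV."""
        assert oxygen_gs.photoionization_cs("1s", 530.0) == 0.0
        assert oxygen_gs.photoionization_cs("1s", 800.0) > 0.0

    def test_continuous_and_decaying_above_threshold(self, oxygen_gs):
        thr = oxygen_gs.ionization_threshold_ev("2s")
        vals = [oxygen_gs.photoionization_cs("2s", thr * f) for f in (1.05, 1.1, 8.0)]
        assert all(v > 0 for v in vals)
        # no jump just above threshold, and decay far above it
        assert vals[0] == pytest.approx(vals[1], rel=0.5)
        assert vals[2] < vals[1]

    def test_unknown_subshell_rejected(self, oxygen_gs):
        with pytest.raises(InvalidConfigurationError):
            oxygen_gs.photoionization_cs("7k", 530.0)


# ----------------------------------------------------------------------
# resonant cross section
# ----------------------------------------------------------------------

class TestResonantCS:
    def test_large_bandwidth_dilutes_to_zero(self, oxygen_gs):
        t = oxygen_gs.find_transition("1s", "2p")
        narrow = resonant_cs(oxygen_gs, "1s", "2p", t.omega_ev, 5.3)
        wide = resonant_cs(oxygen_gs, "1s", "2p", t.omega_ev, 5000.0)
        assert wide < 1e-2 * narrow

    def test_full_upper_subshell_rejected(self):
        d = solve_hfs("O", ElectronicConfiguration("O", (1, 1, 6)))
        with pytest.raises(InvalidConfigurationError):
            resonant_cs(d, "1s", "2p", 530.0, 5.3)

    def test_detuning_symmetric_gaussian_wings(self, oxygen_gs):
        t = oxygen_gs.find_transition("1s", "2p")
        lo = resonant_cs(oxygen_gs, "1s", "2p", t.omega_ev - 4.0, 5.3)
        hi = resonant_cs(oxygen_gs, "1s", "2p", t.omega_ev + 4.0, 5.3)
        assert lo == pytest.approx(hi, rel=0.05)


# ----------------------------------------------------------------------
# form factors
# ----------------------------------------------------------------------

class TestFormFactor:
    def test_f0_zero_q_equals_electron_count(self, oxygen_gs):
        assert oxygen_gs.f0(0.0) == pytest.approx(8.0, rel=1e-4)

    def test_f0_decays(self, oxygen_gs):
        q = np.array([0.0, 20.0, 60.0, 200.0])  # 1/nm
        f = oxygen_gs.f0(q)
        assert np.all(np.diff(f) < 0)

    def test_forward_factor_far_above_edges(self, oxygen_gs):
        f = oxygen_gs.form_factor(0.0, 8000.0)
        assert f.real == pytest.approx(8.0, abs=0.25)
        assert 0 <= f.imag < 0.2

    def test_bare_ion_scatters_nothing(self):
        d = solve_hfs("O", ElectronicConfiguration("O", ()))
        assert d.form_factor(3.0, 530.0) == 0.0

    def test_f_double_prime_nonnegative(self, oxygen_gs):
        w = np.geomspace(20.0, 3e4, 40)
        assert np.all(oxygen_gs.f_double_prime(w) >= 0.0)

    def test_extrapolation_error_outside_grid(self, oxygen_gs):
        with pytest.raises(ExtrapolationError):
            oxygen_gs.f_double_prime(1e6)
        with pytest.raises(ExtrapolationError):
            oxygen_gs.f_prime(1.0)

    def test_sampled_configs_f0_matches_bound_count(self):
        for occ in [(2, 2, 3), (1, 2, 4), (2, 1, 1)]:
            d = solve_hfs("O", ElectronicConfiguration("O", occ))
            assert d.f0(0.0) == pytest.approx(sum(occ), rel=1e-3)


# ----------------------------------------------------------------------
# Kramers-Kronig
# ----------------------------------------------------------------------

def _oscillator_pair(grid, w0, gamma):
    """Damped-oscillator anomalous factors in the scattering convention.

    f'' = gamma w^3 / D and f' = [w0^2 (w^2 - w0^2) - gamma^2 w^2] / D with
    D = (w^2 - w0^2)^2 + gamma^2 w^2: f' -> -1 at w -> 0 (full screening of
    one electron) and f' -> 0 at w -> infinity.
    """
    den = (grid**2 - w0**2) ** 2 + (gamma * grid) ** 2
    f_im = gamma * grid**3 / den
    f_re = (w0**2 * (grid**2 - w0**2) - gamma**2 * grid**2) / den
    return f_re, f_im


class TestKramersKronig:
    def test_lorentz_oscillator_pair(self):
        """Numeric KK of a damped-oscillator f'' reproduces the analytic f'."""
        w0, gamma = 500.0, 5.0
        grid = np.unique(
            np.concatenate(
                [np.geomspace(5.0, 5e4, 600), w0 + gamma * np.linspace(-40, 40, 401)]
            )
        )
        f_re, f_im = _oscillator_pair(grid, w0, gamma)
        probe = np.array([300.0, 450.0, 490.0, 510.0, 600.0, 1500.0])
        got = kramers_kronig(grid, f_im, probe)
        want = np.interp(probe, grid, f_re)
        assert got == pytest.approx(want, rel=0.02, abs=0.03)

    def test_static_limit_screens_bound_electrons(self):
        """f'(w -> 0) approaches -1 for a one-electron oscillator."""
        w0, gamma = 500.0, 5.0
        grid = np.unique(
            np.concatenate(
                [np.geomspace(0.5, 5e4, 1200), w0 + gamma * np.linspace(-40, 40, 401)]
            )
        )
        _, f_im = _oscillator_pair(grid, w0, gamma)
        got = kramers_kronig(grid, f_im, np.array([1.0]))[0]
        assert got == pytest.approx(-1.0, abs=0.05)

    def test_forward_then_inverse_reproduces_imaginary_part(self):
        """f'' -> (KK) -> f' -> (inverse KK) -> f'' round-trips on the grid."""
        w0, gamma = 500.0, 8.0
        grid = np.unique(
            np.concatenate(
                [np.geomspace(5.0, 5e4, 700), w0 + gamma * np.linspace(-50, 50, 601)]
            )
        )
        _, f_im = _oscillator_pair(grid, w0, gamma)
        f_re = kramers_kronig(grid, f_im, grid)
        probe = np.array([200.0, 460.0, 495.0, 505.0, 560.0, 2000.0])
        back = _kk_inverse(grid, f_re, probe)
        want = np.interp(probe, grid, f_im)
        # limited by the finite-range truncation of the slowly decaying f'
        assert back == pytest.approx(want, rel=0.05, abs=0.08)


def _kk_inverse(grid, f_re, omega):
    """Inverse transform: f''(w) = (2 w / pi) P int f'(w')/(w'^2 - w^2) dw'."""
    out = np.empty_like(np.asarray(omega, dtype=float))
    for i, wi in enumerate(np.atleast_1d(omega)):
        fw = np.interp(wi, grid, f_re)
        denom = grid**2 - wi**2
        num = f_re - fw
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = np.where(np.abs(denom) > 0, num / denom, 0.0)
        a, b = grid[0], grid[-1]
        val = np.trapezoid(integrand, grid)
        val += fw * (1.0 / (2.0 * wi)) * (
            math.log(abs((b - wi) / (b + wi))) - math.log(abs((a - wi) / (a + wi)))
        )
        out[i] = (2.0 * wi / math.pi) * val
    return out
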