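import math

import numpy as np
import pytest
from scipy.optimize import brentq

from dynscatter import constants as cst
from dynscatter.sphere_fit import (
    DetectorGeometry,
    SphereModel,
    dse_experimental,
    fit_sphere,
    radial_profile,
    refractive_decrement,
    sphere_envelope,
    sphere_image,
)


def _dn(geometry):
    omega = cst.wavelength_nm_to_photon_energy(geometry.wavelength_nm)
    return abs(refractive_decrement({"C": 12, "H": 22, "O": 11}, 1581.0, omega))


class TestForwardModel:
    def test_central_intensity_series_limit(self, small_geometry):
        """As s -> 0 the envelope tends to 1/9, fixing the central intensity."""
        dn = 1e-3
        f_ph = 100.0
        model = SphereModel(45.0, dn, small_geometry.wavelength_nm, f_ph)
        img = sphere_image(model, small_geometry)
        q_min_idx = np.unravel_index(np.argmin(small_geometry.q_invnm()), img.shape)
        s_min = math.pi * 45.0 * small_geometry.q_invnm()[q_min_idx]
        amp2 = (6 * math.pi * model.volume_nm3 * dn / model.wavelength_nm**2) ** 2
        want = (
            f_ph * small_geometry.d_qe_geo()[q_min_idx] * amp2 * sphere_envelope(s_min)
        )
        assert img[q_min_idx] == pytest.approx(want, rel=1e-12)
        assert sphere_envelope(0.0) == pytest.approx(1.0 / 9.0, rel=1e-12)
        assert sphere_envelope(1e-5) == pytest.approx(1.0 / 9.0, rel=1e-4)

    def test_envelope_zeros_at_tan_s_equals_s(self):
        """Intensity zeros exactly where tan s = s (root-finding oracle)."""
        for bracket in [(3.5, 4.6), (6.9, 7.8), (10.0, 11.0)]:
            root = brentq(lambda s: math.sin(s) - s * math.cos(s), *bracket)
            assert sphere_envelope(root) < 1e-28
            assert sphere_envelope(root - 0.3) > 1e-12
        root1 = brentq(lambda s: math.sin(s) - s * math.cos(s), 3.5, 4.6)
        assert root1 == pytest.approx(4.4934, abs=1e-4)

    def test_linearity_in_fluence(self, small_geometry):
        dn = _dn(small_geometry)
        a = sphere_image(SphereModel(40.0, dn, small_geometry.wavelength_nm, 10.0), small_geometry)
        b = sphere_image(SphereModel(40.0, dn, small_geometry.wavelength_nm, 20.0), small_geometry)
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_radial_profile_is_azimuthally_flat(self, small_geometry):
        """The model is isotropic: pixel values depend only on |q|."""
        dn = _dn(small_geometry)
        img = sphere_image(SphereModel(45.0, dn, small_geometry.wavelength_nm, 10.0), small_geometry)
        q = small_geometry.q_invnm()
        sel = (q > 0.05) & (q < 0.056)
        ratio = img[sel] / sphere_envelope(math.pi * 45.0 * q[sel])
        # after removing the envelope, only the smooth solid-angle factor
        # remains, which varies weakly within a thin q ring
        assert ratio.std() / ratio.mean() < 0.02

    def test_wavelength_mismatch_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            sphere_image(SphereModel(40.0, 1e-3, 99.0, 1.0), small_geometry)


class TestRefractiveDecrement:
    def test_zero_density(self):
        assert refractive_decrement({"O": 1}, 0.0, 1000.0) == 0

    def test_additive_in_number_density(self):
        """dn of a mixture is the density-weighted sum of components."""
        full = refractive_decrement({"C": 1, "O": 1}, 1000.0, 1483.0)
        # same formula unit split into two half-density single-element parts
        m_c = cst.ATOMIC_MASS_U["C"]
        m_o = cst.ATOMIC_MASS_U["O"]
        rho_c = 1000.0 * m_c / (m_c + m_o)
        rho_o = 1000.0 * m_o / (m_c + m_o)
        parts = refractive_decrement({"C": 1}, rho_c, 1483.0) + refractive_decrement(
            {"O": 1}, rho_o, 1483.0
        )
        assert parts == pytest.approx(full, rel=1e-9)

    def test_sucrose_against_tabulated_value(self):
        """|dn| for sucrose at 1483 eV vs the electron-density dispersion
        value delta = r_e lambda^2 n_e / 2 pi (f ~= Z far from edges)."""
        got = abs(refractive_decrement({"C": 12, "H": 22, "O": 11}, 1581.0, 1483.0))
        lam_nm = cst.photon_energy_to_wavelength_nm(1483.0)
        n_e = 1.581 * cst.N_AVOGADRO * 182.0 / 342.3 * 1e-21  # electrons / nm^3
        delta = cst.R_ELECTRON_NM * lam_nm**2 * n_e / (2 * math.pi)
        assert got == pytest.approx(delta, rel=0.05)


class TestFitting:
    def test_noiseless_roundtrip(self, small_geometry):
        dn = _dn(small_geometry)
        truth = SphereModel(47.3, dn, small_geometry.wavelength_nm, 55.0)
        img = sphere_image(truth, small_geometry)
        fit = fit_sphere(img, small_geometry, dn)
        # recovery is limited only by the radial binning of the estimator
        assert fit.diameter_nm == pytest.approx(47.3, rel=5e-3)
        assert fit.i0_photons_per_nm2 == pytest.approx(55.0, rel=0.02)
        assert not fit.low_confidence

    def test_poisson_recovery_study(self, small_geometry):
        """Median relative fluence error < 10% over many noisy realizations.

        Fluences span experiment-like photon fluences (a few uJ/um^2 at
        1 keV is ~1e4-1e5 photons/nm^2).
        """
        dn = _dn(small_geometry)
        rng = np.random.default_rng(2024)
        errors = []
        for _ in range(100):
            d = rng.uniform(38.0, 52.0)
            i0 = rng.uniform(1e4, 2e5)
            img = rng.poisson(
                sphere_image(SphereModel(d, dn, small_geometry.wavelength_nm, i0), small_geometry)
            ).astype(float)
            fit = fit_sphere(img, small_geometry, dn)
            errors.append(abs(fit.i0_photons_per_nm2 - i0) / i0)
        assert np.median(errors) < 0.10

    def test_fringe_count_grows_with_photon_energy(self):
        """Fixed 45 nm sphere: more visible minima at higher photon energy."""
        def n_minima(energy_ev):
            lam = cst.photon_energy_to_wavelength_nm(energy_ev)
            geo = DetectorGeometry(wavelength_nm=lam, pixel_pitch_mm=0.6,
                                   n_rows_panel=64, n_cols=128)
            s_max = math.pi * 45.0 * geo.q_max_invnm
            # zeros of the envelope: tan s = s, asymptotically at
            # s ~ (k + 1/2) pi
            return int(s_max / math.pi - 0.5)

        counts = [n_minima(e) for e in (530.0, 800.0, 1000.0, 1483.0)]
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]

    def test_small_sphere_flagged_low_confidence(self, small_geometry):
        """No fringe minimum inside the q range -> flagged, not silent."""
        dn = _dn(small_geometry)
        img = sphere_image(SphereModel(6.0, dn, small_geometry.wavelength_nm, 50.0),
                           small_geometry)
        fit = fit_sphere(img, small_geometry, dn, d_range_nm=(3.0, 60.0))
        assert fit.low_confidence

    def test_masked_pixels_ignored(self, small_geometry):
        dn = _dn(small_geometry)
        truth = SphereModel(45.0, dn, small_geometry.wavelength_nm, 40.0)
        img = sphere_image(truth, small_geometry)
        mask = np.ones_like(img, dtype=bool)
        mask[40:50, :] = False
        img_corrupt = img.copy()
        img_corrupt[40:50, :] = 1e6
        fit = fit_sphere(img_corrupt, small_geometry, dn, mask=mask)
        assert fit.diameter_nm == pytest.approx(45.0, rel=5e-3)


class TestExperimentalDSE:
    def test_uniform_samples_give_unity(self):
        assert dse_experimental([3.0] * 40, 3.0) == pytest.approx(1.0)

    def test_size_filter_applied_before_selection(self):
        i0 = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        sizes = np.array([45.0, 46.0, 44.0, 45.0, 80.0])  # outlier carries the 100
        val = dse_experimental(i0, 1.0, sizes_nm=sizes, top_fraction=0.25)
        assert val == pytest.approx(1.0)

    def test_heavy_tail_top_fraction_ordering(self):
        rng = np.random.default_rng(7)
        # 1/F-like distribution on (0.01, 1]
        samples = np.exp(rng.uniform(math.log(0.01), 0.0, 2000))
        top = dse_experimental(samples, 1.0, top_fraction=0.05)
        full = dse_experimental(samples, 1.0, top_fraction=1.0)
        assert top > full

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            dse_experimental([], 1.0)
        with pytest.raises(ValueError):
            dse_experimental([1.0], 0.0)
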