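import math

import numpy as np
import pytest

from dynscatter.atomic_physics import DEFAULT_PARAMS, solve_hfs
from dynscatter.configuration import ElectronicConfiguration, ground_state
from dynscatter.ionization_dynamics import (
    StepSizeError,
    argon_benchmark,
    build_rate_table,
    evolve_configurations,
    lotz_cross_section_nm2,
)
from dynscatter.pulse import PulseSpec

BARN_NM2 = 1e-10


def _pulse(energy=530.0, fwhm=10.0, fluence=1.0):
    return PulseSpec(energy, fwhm, fluence)


class TestRateTable:
    def test_ground_state_dark_atom_has_no_rates(self):
        pulse = _pulse(fluence=1.0)
        # far in the pulse wings, intensity ~ 0
        table = build_rate_table(ground_state("O"), pulse, t_fs=1e4)
        assert table.total_rate_per_fs == pytest.approx(0.0, abs=1e-12)

    def test_core_hole_decays_at_configured_auger_rate(self):
        """A 1s-hole oxygen ion decays at 1/tau with the 4 fs preset."""
        cfg = ElectronicConfiguration("O", (1, 2, 4))
        table = build_rate_table(cfg, _pulse(fluence=0.0), t_fs=0.0)
        auger = [c for c in table.channels if c.channel == "A"]
        assert sum(c.rate_per_fs for c in auger) == pytest.approx(1.0 / 4.0, rel=1e-9)
        # Auger final states: hole filled, one more electron gone
        for c in auger:
            assert c.final.charge == cfg.charge + 1
            assert c.electron_delta == 1
            assert c.electron_energy_ev > 0

    def test_branching_probabilities_sum_to_one(self):
        pulse = _pulse(fluence=5.0)
        for occ in [(2, 2, 4), (1, 2, 4), (2, 2, 2), (2, 1, 3)]:
            table = build_rate_table(
                ElectronicConfiguration("O", occ), pulse, t_fs=0.0
            )
            if table.total_rate_per_fs > 0:
                assert table.branching().sum() == pytest.approx(1.0, rel=1e-12)
                assert all(c.rate_per_fs >= 0 for c in table.channels)

    def test_field_channels_linear_in_intensity(self):
        pulse = _pulse(fluence=2.0)
        t1 = build_rate_table(ground_state("O"), pulse, 0.0)
        pulse2 = _pulse(fluence=4.0)
        t2 = build_rate_table(ground_state("O"), pulse2, 0.0)
        r1 = {c.final: c.rate_per_fs for c in t1.channels if c.channel in "P RE".split()}
        for c in t2.channels:
            if c.channel in ("P", "RE"):
                assert c.rate_per_fs == pytest.approx(2.0 * r1[c.final], rel=1e-9)

    def test_resonant_channel_gated_by_detuning(self):
        """1s->2p excitation is active near the line and off far away."""
        cfg = ground_state("O")
        data = solve_hfs("O", cfg)
        w0 = data.find_transition("1s", "2p").omega_ev
        near = build_rate_table(cfg, _pulse(energy=w0, fluence=1.0), 0.0)
        far = build_rate_table(cfg, _pulse(energy=w0 - 100.0, fluence=1.0), 0.0)
        assert any(c.channel == "RE" for c in near.channels)
        assert not any(c.channel == "RE" for c in far.channels)


class TestEvolveConfigurations:
    def test_zero_fluence_keeps_ground_state(self):
        pulse = _pulse(fluence=0.0)
        finals, events = evolve_configurations(
            [ground_state("O")] * 5, pulse, seed=1, dt_fs=0.05
        )
        assert all(c == ground_state("O") for c in finals)
        assert all(len(e) == 0 for e in events)

    def test_seed_determinism(self):
        pulse = _pulse(fluence=3.0, fwhm=5.0)
        a = evolve_configurations([ground_state("O")] * 20, pulse, seed=7, dt_fs=0.02)
        b = evolve_configurations([ground_state("O")] * 20, pulse, seed=7, dt_fs=0.02)
        assert a[0] == b[0]
        assert [[(e.t_fs, e.channel, e.final) for e in ev] for ev in a[1]] == [
            [(e.t_fs, e.channel, e.final) for e in ev] for ev in b[1]
        ]

    def test_single_photon_poisson_statistics(self):
        """Weak non-resonant pulse: ionized fraction = 1 - exp(-sigma F).

        800 eV photons on oxygen, fluence chosen for sigma*F ~ 0.1; compared
        within 3 binomial standard errors.
        """
        n = 600
        pulse = PulseSpec(800.0, 5.0, 30.0)
        data = solve_hfs("O", ground_state("O"))
        sigma_nm2 = data.total_photoionization_cs(800.0) * BARN_NM2
        expected = 1.0 - math.exp(-sigma_nm2 * pulse.photon_fluence_per_nm2)
        finals, _ = evolve_configurations(
            [ground_state("O")] * n, pulse, seed=11, dt_fs=0.02
        )
        frac = sum(1 for c in finals if c != ground_state("O")) / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3.0 * se + 1e-9

    def test_auger_survival_is_exponential(self):
        """Field-off 1s-hole ensemble decays as exp(-t/tau)."""
        n = 800
        tau = 4.0
        cfg = ElectronicConfiguration("O", (1, 2, 4))
        t_obs = 3.0
        finals, events = evolve_configurations(
            [cfg] * n, _pulse(fluence=0.0), seed=3, dt_fs=0.02,
            window_fs=(0.0, t_obs),
        )
        survived = sum(1 for c in finals if c == cfg) / n
        expected = math.exp(-t_obs / tau)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(survived - expected) < 3.0 * se

    def test_electron_bookkeeping_conserved(self):
        """Every event changes bound+free electron count consistently."""
        pulse = PulseSpec(530.0, 5.0, 10.0)
        finals, events = evolve_configurations(
            [ground_state("O")] * 30, pulse, seed=5, dt_fs=0.01
        )
        for cfg0, cfg_final, evs in zip([ground_state("O")] * 30, finals, events):
            freed = sum(e.electron_delta for e in evs)
            assert cfg0.n_electrons == cfg_final.n_electrons + freed
            for e in evs:
                assert e.initial.n_electrons - e.final.n_electrons == e.electron_delta

    def test_step_too_coarse_raises(self):
        pulse = PulseSpec(530.0, 1.0, 500.0)  # brutal intensity
        with pytest.raises(StepSizeError):
            evolve_configurations([ground_state("O")] * 2, pulse, seed=1, dt_fs=0.5)


class TestLotz:
    def test_zero_below_binding(self):
        assert lotz_cross_section_nm2(10.0, 20.0, 4) == 0.0

    def test_formula_value(self):
        e, p, n = 100.0, 20.0, 4
        want = 4.5 * n * math.log(e / p) / (e * p)
        assert lotz_cross_section_nm2(e, p, n) == pytest.approx(want, rel=1e-12)


class TestArgonBenchmark:
    def test_zero_fluence_all_neutral(self):
        pulse = PulseSpec(530.0, 5.0, 0.0)
        dist = argon_benchmark(pulse, (np.array([0.0]), np.array([1.0])), n_atoms=20, seed=1)
        assert dist == {0: 1.0}

    def test_flat_profile_degenerates_to_single_fluence(self):
        """A delta focal distribution reproduces the single-fluence run."""
        from dynscatter.experiment_tools import BeamlineSpec, focal_fluence_distribution

        pulse = PulseSpec(530.0, 5.0, 2.0)
        beam = BeamlineSpec(0.1, 0.10, 5.0, 530.0)  # F0 = 2 uJ/um^2
        flat = focal_fluence_distribution(beam, profile="flat")
        single = argon_benchmark(pulse, (np.array([2.0]), np.array([1.0])), n_atoms=60, seed=9)
        averaged = argon_benchmark(pulse, flat, n_atoms=60, seed=9)
        assert set(single) == set(averaged)
        for q in single:
            assert single[q] == pytest.approx(averaged[q], abs=1e-12)

    def test_calibration_conditions_ionize_argon(self):
        """At the 530 eV / 25 uJ/um^2 calibration point Ar charges up."""
        pulse = PulseSpec(530.0, 5.0, 25.0)
        dist = argon_benchmark(pulse, (np.array([25.0]), np.array([1.0])), n_atoms=30, seed=2)
        mean_charge = sum(q * p for q, p in dist.items())
        assert mean_charge > 0.5
        assert all(p >= 0 for p in dist.values())
        assert sum(dist.values()) == pytest.approx(1.0, rel=1e-9)
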