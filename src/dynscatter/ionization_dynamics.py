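"""Monte-Carlo sampling of electronic-configuration transitions.

Each atom/ion carries a configuration; six channels connect it to
neighboring configurations: photoionization (P), Auger decay (A),
fluorescence (F), resonant excitation (RE), electron-impact ionization
(EI) and recombination (RC).  Field-driven channels scale linearly with
the instantaneous pulse intensity; per-configuration cross sections are
cached so the time dependence costs nothing.

Event sampling is per-MD-step Bernoulli with p = Gamma * dt, which is
accurate for Gamma * dt << 1 (enforced) and reproduces the exponential
survival and Poisson single-photon statistics oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .atomic_physics import (
    DEFAULT_PARAMS,
    AtomicData,
    HFSParams,
    resonant_cs,
    solve_hfs,
)
from .configuration import (
    SUBSHELLS,
    ElectronicConfiguration,
    InvalidConfigurationError,
    ground_state,
)
from .pulse import PulseSpec

__all__ = [
    "RateChannel",
    "RateTable",
    "LocalEnvironment",
    "ConfigEvent",
    "build_rate_table",
    "evolve_configurations",
    "argon_benchmark",
    "lotz_cross_section_nm2",
    "StepSizeError",
]

BARN_NM2 = 1e-10
# Lotz constant a ~= 4.5e-14 cm^2 eV^2 = 4.5 nm^2 eV^2
LOTZ_A_NM2_EV2 = 4.5
RESONANT_DETUNING_WINDOW = 4.0  # in units of the bandwidth FWHM


class StepSizeError(RuntimeError):
    """Raised when Gamma * dt exceeds the configured bound."""


@dataclass(frozen=True)
class RateChannel:
    channel: str                            # "P", "A", "F", "RE", "EI", "RC"
    final: ElectronicConfiguration
    rate_per_fs: float
    electron_delta: int = 0                 # +1 emitted, -1 captured
    electron_energy_ev: float = 0.0


@dataclass
class RateTable:
    configuration: ElectronicConfiguration
    channels: list

    @property
    def total_rate_per_fs(self) -> float:
        return sum(c.rate_per_fs for c in self.channels)

    def branching(self) -> np.ndarray:
        tot = self.total_rate_per_fs
        if tot <= 0:
            return np.zeros(len(self.channels))
        return np.array([c.rate_per_fs / tot for c in self.channels])


@dataclass(frozen=True)
class LocalEnvironment:
    """Mean-field plasma environment for the EI/RC channels.

    In the coupled cluster simulation impact ionization and recombination
    are resolved per collision in the molecular dynamics instead; this
    mean-field form serves isolated-atom/rate-equation runs.
    """

    electron_flux_per_nm2_fs: float = 0.0
    electron_energy_ev: float = 0.0
    recombination_rate_per_fs: float = 0.0


def lotz_cross_section_nm2(e_ev: float, binding_ev: float, n_electrons: int) -> float:
    """Lotz-type electron-impact ionization cross section (nm^2)."""
    if e_ev <= binding_ev or binding_ev <= 0 or n_electrons <= 0:
        return 0.0
    return LOTZ_A_NM2_EV2 * n_electrons * math.log(e_ev / binding_ev) / (e_ev * binding_ev)


# ----------------------------------------------------------------------
# static (per-configuration) channel templates
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class _Template:
    channel: str
    final: ElectronicConfiguration
    sigma_nm2: float          # for intensity-driven channels (P, RE)
    rate_per_fs: float        # for field-free channels (A, F)
    electron_delta: int
    electron_energy_ev: float


_TEMPLATE_CACHE: dict = {}


def _channel_templates(cfg, pulse_key, params) -> tuple:
    key = (cfg, pulse_key, params)
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    omega_x, bandwidth_ev = pulse_key
    data = solve_hfs(cfg.element, cfg, params)
    out = []
    # photoionization
    for s in cfg.occupied_subshells:
        sigma = data.photoionization_cs(s, omega_x) * BARN_NM2
        if sigma > 0:
            out.append(
                _Template(
                    "P", cfg.remove(s), sigma, 0.0, +1,
                    omega_x - data.ionization_threshold_ev(s),
                )
            )
    # resonant excitation, only near-degenerate with the pulse
    for t in data.transitions:
        if abs(t.omega_ev - omega_x) > RESONANT_DETUNING_WINDOW * bandwidth_ev:
            continue
        sigma = resonant_cs(data, t.lower, t.upper, omega_x, bandwidth_ev) * BARN_NM2
        if sigma > 0:
            out.append(_Template("RE", cfg.excite(t.lower, t.upper), sigma, 0.0, 0, 0.0))
    # core-hole decay: Auger (and a fluorescence fraction, default 0)
    out.extend(_auger_templates(cfg, data, params))
    result = tuple(out)
    _TEMPLATE_CACHE[key] = result
    return result


def _auger_templates(cfg, data: AtomicData, params) -> list:
    out = []
    lifetimes = params.lifetimes()
    for idx, s in enumerate(SUBSHELLS[: len(cfg.occupations)]):
        holes = cfg.holes(s)
        if holes <= 0:
            continue
        tau = lifetimes.get((cfg.element, s))
        if tau is None:
            continue
        b_core = data.orbital_energies.get(s)
        if b_core is None:
            continue
        pairs = []
        for i1 in range(idx + 1, len(cfg.occupations)):
            for i2 in range(i1, len(cfg.occupations)):
                v1, v2 = SUBSHELLS[i1], SUBSHELLS[i2]
                n1 = cfg.occupation(v1)
                n2 = cfg.occupation(v2) - (1 if v1 == v2 else 0)
                w = n1 * n2
                if w <= 0:
                    continue
                if v1 not in data.orbital_energies or v2 not in data.orbital_energies:
                    continue
                e_auger = (
                    -data.orbital_energies[v1]
                    - data.orbital_energies[v2]
                    + data.orbital_energies[s]
                )
                e_auger = -e_auger  # B(core) - B(v1) - B(v2)
                if e_auger <= 0:
                    continue
                try:
                    final = cfg.add(s).remove(v1).remove(v2)
                except InvalidConfigurationError:
                    continue
                pairs.append((final, w, e_auger))
        if not pairs:
            continue
        total_rate = holes / tau
        wsum = sum(w for _, w, _ in pairs)
        for final, w, e_auger in pairs:
            out.append(_Template("A", final, 0.0, total_rate * w / wsum, +1, e_auger))
    return out


# ----------------------------------------------------------------------
# public rate-table construction
# ----------------------------------------------------------------------

def build_rate_table(
    configuration: ElectronicConfiguration,
    pulse: PulseSpec,
    t_fs: float,
    local_environment: LocalEnvironment | None = None,
    params: HFSParams = DEFAULT_PARAMS,
) -> RateTable:
    """Channel-resolved transition rates of one configuration at time t."""
    flux = float(pulse.temporal_profile(t_fs))  # photons / nm^2 / fs
    pulse_key = (pulse.photon_energy_ev, pulse.bandwidth_fwhm_ev)
    channels = []
    for tpl in _channel_templates(configuration, pulse_key, params):
        rate = tpl.rate_per_fs + tpl.sigma_nm2 * flux
        if rate > 0:
            channels.append(
                RateChannel(tpl.channel, tpl.final, rate, tpl.electron_delta,
                            tpl.electron_energy_ev)
            )
    env = local_environment
    if env is not None and env.electron_flux_per_nm2_fs > 0:
        data = solve_hfs(configuration.element, configuration, params)
        for s in configuration.occupied_subshells:
            sigma = lotz_cross_section_nm2(
                env.electron_energy_ev, data.binding_energy_ev(s),
                configuration.occupation(s),
            )
            rate = sigma * env.electron_flux_per_nm2_fs
            if rate > 0:
                channels.append(RateChannel("EI", configuration.remove(s), rate, +1, 0.0))
    if env is not None and env.recombination_rate_per_fs > 0:
        vac = _lowest_vacancy(configuration)
        if vac is not None:
            channels.append(
                RateChannel("RC", configuration.add(vac), env.recombination_rate_per_fs, -1, 0.0)
            )
    return RateTable(configuration, channels)


def _lowest_vacancy(cfg: ElectronicConfiguration):
    gs = ground_state(cfg.element)
    for s in gs.occupied_subshells:
        if cfg.holes(s) > 0:
            return s
    return None


# ----------------------------------------------------------------------
# isolated-atom Monte-Carlo evolution
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ConfigEvent:
    t_fs: float
    channel: str
    initial: ElectronicConfiguration
    final: ElectronicConfiguration
    electron_delta: int
    electron_energy_ev: float


def evolve_configurations(
    atoms,
    pulse: PulseSpec,
    seed: int,
    dt_fs: float = 0.01,
    window_fs: tuple | None = None,
    local_environment: LocalEnvironment | None = None,
    params: HFSParams = DEFAULT_PARAMS,
    max_rate_dt: float = 0.2,
):
    """Evolve an ensemble of isolated atoms through the pulse.

    Parameters
    ----------
    atoms:
        Sequence of initial :class:`ElectronicConfiguration`.
    seed:
        Fixed seed -> bit-for-bit reproducible event lists.

    Returns
    -------
    (final_configurations, events): per-atom final states and the list of
    time-stamped :class:`ConfigEvent` per atom.
    """
    rng = np.random.default_rng(seed)
    if window_fs is None:
        window_fs = pulse.time_window_fs()
    t0, t1 = window_fs
    n_steps = int(math.ceil((t1 - t0) / dt_fs))
    configs = list(atoms)
    events = [[] for _ in configs]

    # group atoms by configuration for vectorized sampling
    for step in range(n_steps):
        t = t0 + (step + 0.5) * dt_fs
        groups: dict = {}
        for i, c in enumerate(configs):
            groups.setdefault(c, []).append(i)
        for cfg, idxs in groups.items():
            table = build_rate_table(cfg, pulse, t, local_environment, params)
            tot = table.total_rate_per_fs
            if tot <= 0:
                continue
            p = tot * dt_fs
            if p > max_rate_dt:
                raise StepSizeError(
                    f"total rate {tot:.3g}/fs * dt {dt_fs} fs = {p:.3g} exceeds "
                    f"{max_rate_dt}; use a smaller time step"
                )
            hits = rng.random(len(idxs)) < p
            if not np.any(hits):
                continue
            branching = table.branching()
            for j in np.nonzero(hits)[0]:
                k = rng.choice(len(table.channels), p=branching)
                ch = table.channels[k]
                i = idxs[j]
                events[i].append(
                    ConfigEvent(t, ch.channel, cfg, ch.final, ch.electron_delta,
                                ch.electron_energy_ev)
                )
                configs[i] = ch.final
    return configs, events


# ----------------------------------------------------------------------
# argon fluence benchmark
# ----------------------------------------------------------------------

def argon_benchmark(
    pulse: PulseSpec,
    focal_distribution,
    n_atoms: int = 200,
    seed: int = 0,
    dt_fs: float = 0.01,
    params: HFSParams = DEFAULT_PARAMS,
):
    """Focal-volume-averaged Ar charge-state distribution.

    ``focal_distribution`` is (fluences_uJ_um2, weights) as produced by
    :func:`dynscatter.experiment_tools.focal_fluence_distribution`; the
    charge-state distribution of each single-fluence run is averaged with
    the corresponding weights.

    Returns a dict charge -> probability.
    """
    fluences, weights = focal_distribution
    result: dict = {}
    gs = ground_state("Ar")
    for m, (f, w) in enumerate(zip(fluences, weights)):
        sub = PulseSpec(
            pulse.photon_energy_ev, pulse.fwhm_fs, float(f),
            pulse.bandwidth_fwhm_fraction,
        )
        dist = _charge_distribution_counts(sub, gs, n_atoms, seed + 7919 * m, dt_fs, params)
        for q, p in dist.items():
            result[q] = result.get(q, 0.0) + w * p
    norm = sum(result.values())
    return {q: p / norm for q, p in sorted(result.items())}


def _charge_distribution_counts(pulse, cfg0, n_atoms, seed, dt_fs, params):
    """Fast occupation-number Monte Carlo over configuration counts."""
    rng = np.random.default_rng(seed)
    t0, t1 = pulse.time_window_fs()
    n_steps = int(math.ceil((t1 - t0) / dt_fs))
    counts = {cfg0: n_atoms}
    for step in range(n_steps):
        t = t0 + (step + 0.5) * dt_fs
        new_counts: dict = {}
        for cfg, n in counts.items():
            if n == 0:
                continue
            table = build_rate_table(cfg, pulse, t, None, params)
            tot = table.total_rate_per_fs
            if tot <= 0:
                new_counts[cfg] = new_counts.get(cfg, 0) + n
                continue
            p = min(tot * dt_fs, 1.0)
            k = rng.binomial(n, p)
            new_counts[cfg] = new_counts.get(cfg, 0) + (n - k)
            if k > 0:
                split = rng.multinomial(k, table.branching())
                for ch, kc in zip(table.channels, split):
                    if kc > 0:
                        new_counts[ch.final] = new_counts.get(ch.final, 0) + kc
        counts = new_counts
    dist: dict = {}
    for cfg, n in counts.items():
        dist[cfg.charge] = dist.get(cfg.charge, 0) + n
    return {q: n / n_atoms for q, n in dist.items()}
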