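"""Time- and bandwidth-resolved coherent scattering of (damaged) clusters.

The observed pattern is the pulse-weighted sum of instantaneous patterns:
the cluster form factor F_c(q, t) = sum_j f_j(q, C_j(t)) exp(i q.R_j(t))
over atoms/ions plus an incoherent N_e(t) term for the delocalized
electrons, multiplied by the Thomson cross section and averaged over the
Gaussian bandwidth.  Total cross sections follow by solid-angle
integration; the Dynamic Scattering Efficiency (DSE) is the ratio of the
damaged to the undamaged cross section.

Momentum transfer convention: q = k_out - k_in with |k| = 2 pi / lambda,
so |q| = (4 pi / lambda) sin(theta/2) in nm^-1 (physical convention; the
sphere-model fit uses its own s = pi d q dialect, documented there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as cst
from .atomic_physics import DEFAULT_PARAMS, HFSParams, solve_hfs
from .configuration import ground_state
from .pulse import PulseSpec

__all__ = [
    "Snapshot",
    "AngularGrid",
    "ScatteringPattern",
    "CrossSectionResult",
    "instantaneous_form_factor",
    "dynamic_cross_section",
    "undamaged_cross_section",
    "dse_theory",
]

_RE_NM = cst.R_ELECTRON_NM          # classical electron radius, nm
_NM2_BARN = 1e10


@dataclass(frozen=True)
class Snapshot:
    """Lightweight cluster snapshot entering the scattering integral."""

    t_fs: float
    elements: tuple
    configurations: tuple
    pos_nm: np.ndarray
    n_delocalized: int

    @classmethod
    def from_state(cls, state, n_delocalized=None) -> "Snapshot":
        if n_delocalized is None:
            n_delocalized = state.n_free_electrons
        return cls(
            t_fs=state.t_fs,
            elements=tuple(state.elements),
            configurations=tuple(state.configurations),
            pos_nm=state.ion_pos.copy(),
            n_delocalized=int(n_delocalized),
        )


class AngularGrid:
    """Gauss-Legendre x uniform-azimuth quadrature over the aperture.

    The aperture is the full sphere by default, or the cone up to the
    scattering angle reaching ``q_max``.
    """

    def __init__(self, wavelength_nm, n_theta=24, n_phi=12, q_max_invnm=None):
        k = 2.0 * math.pi / wavelength_nm
        if q_max_invnm is None:
            theta_max = math.pi
        else:
            s = q_max_invnm / (2.0 * k)
            if s > 1.0 + 1e-12:
                raise ValueError(
                    f"q_max {q_max_invnm} nm^-1 beyond the backscattering limit "
                    f"{2 * k:.3f} nm^-1 at this wavelength"
                )
            theta_max = 2.0 * math.asin(min(s, 1.0))
        x, w = np.polynomial.legendre.leggauss(n_theta)
        # map x in [-1,1] to cos(theta) in [cos(theta_max), 1]
        c0 = math.cos(theta_max)
        cos_t = 0.5 * (x + 1.0) * (1.0 - c0) + c0
        w_theta = w * 0.5 * (1.0 - c0)
        phi = (np.arange(n_phi) + 0.5) * 2.0 * math.pi / n_phi
        w_phi = 2.0 * math.pi / n_phi

        self.wavelength_nm = wavelength_nm
        self.cos_theta = cos_t
        self.theta = np.arccos(np.clip(cos_t, -1, 1))
        self.phi = phi
        self.domega = np.outer(w_theta, np.full(n_phi, w_phi))  # (n_theta, n_phi)
        sin_t = np.sqrt(1.0 - cos_t**2)
        kout = np.empty((n_theta, n_phi, 3))
        kout[..., 0] = sin_t[:, None] * np.cos(phi)[None, :]
        kout[..., 1] = sin_t[:, None] * np.sin(phi)[None, :]
        kout[..., 2] = cos_t[:, None]
        kin = np.array([0.0, 0.0, 1.0])
        self.q_vec = k * (kout - kin)                      # (n_theta, n_phi, 3)
        self.q_norm = k * np.sqrt(2.0 * (1.0 - cos_t))     # (n_theta,)

    def polarization_factor(self, mode="unpolarized"):
        if mode == "unpolarized":
            return 0.5 * (1.0 + self.cos_theta**2)
        if mode == "linear":
            # phi-averaged linear polarization equals the unpolarized average
            return 0.5 * (1.0 + self.cos_theta**2)
        if mode == "none":
            return np.ones_like(self.cos_theta)
        raise ValueError(f"unknown polarization mode {mode!r}")


@dataclass
class ScatteringPattern:
    grid: AngularGrid
    dsigma_domega_nm2: np.ndarray          # (n_theta, n_phi)
    pulse: PulseSpec | None = None
    damaged: bool = True
    meta: dict = field(default_factory=dict)

    def expected_photons(self, fluence_per_nm2=None):
        """Expected photon count per grid cell for a given photon fluence."""
        if fluence_per_nm2 is None:
            fluence_per_nm2 = self.pulse.photon_fluence_per_nm2
        return fluence_per_nm2 * self.dsigma_domega_nm2 * self.grid.domega


@dataclass
class CrossSectionResult:
    sigma_dam_barn: float
    sigma_nodam_barn: float | None = None
    per_time_barn: list = field(default_factory=list)

    @property
    def dse(self) -> float:
        if self.sigma_nodam_barn is None:
            raise ValueError("no undamaged reference attached")
        return dse_theory(self.sigma_dam_barn, self.sigma_nodam_barn)


def instantaneous_form_factor(
    snapshot: Snapshot,
    q_vec,
    omega_ev: float,
    params: HFSParams = DEFAULT_PARAMS,
):
    """Exact coherent sum F_c(q, t) over all atoms/ions of a snapshot.

    ``q_vec`` is (..., 3) in nm^-1; free electrons are excluded (they enter
    the cross section incoherently).  Raises with the configuration named
    if atomic data cannot be built for it.
    """
    q = np.asarray(q_vec, dtype=float)
    qflat = q.reshape(-1, 3)
    qnorm = np.linalg.norm(qflat, axis=1)
    out = np.zeros(len(qflat), dtype=complex)
    groups: dict = {}
    for i, cfg in enumerate(snapshot.configurations):
        groups.setdefault(cfg, []).append(i)
    phases = np.exp(1j * (snapshot.pos_nm @ qflat.T))       # (N_a, M)
    for cfg, idx in groups.items():
        try:
            data = solve_hfs(cfg.element, cfg, params)
            fvals = data.f0(qnorm) + data.f_prime(omega_ev) + 1j * data.f_double_prime(omega_ev)
        except Exception as exc:
            raise RuntimeError(f"form factor unavailable for {cfg}: {exc}") from exc
        out += fvals * phases[idx].sum(axis=0)
    return out.reshape(q.shape[:-1])


def _config_ff_table(configs, q_norm, omega_nodes, params):
    """f(q, w) per configuration on the |q| grid and bandwidth nodes."""
    table = {}
    for cfg in configs:
        data = solve_hfs(cfg.element, cfg, params)
        f0 = data.f0(q_norm)
        fw = np.array(
            [data.f_prime(w) + 1j * data.f_double_prime(w) for w in omega_nodes]
        )
        table[cfg] = f0[None, :] + fw[:, None]              # (n_omega, n_theta)
    return table


def dynamic_cross_section(
    snapshots,
    pulse: PulseSpec,
    n_theta: int = 24,
    n_phi: int = 12,
    q_max_invnm: float | None = None,
    n_omega: int = 7,
    polarization: str = "unpolarized",
    params: HFSParams = DEFAULT_PARAMS,
) -> tuple[CrossSectionResult, ScatteringPattern]:
    """Pulse- and bandwidth-weighted scattering cross section of a trajectory.

    ``snapshots`` is a sequence of :class:`Snapshot` at (roughly uniform)
    cadence; their pulse-intensity weights implement the time integral and
    the Gauss-Hermite nodes the bandwidth integral.  Returns the total
    cross section (barn, via solid-angle integration over the aperture) and
    the differential pattern.
    """
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    grid = AngularGrid(pulse.wavelength_nm, n_theta, n_phi, q_max_invnm)
    omega_nodes, omega_w = pulse.bandwidth_quadrature(n_omega)

    if len(snapshots) == 1:
        t_weights = np.array([1.0])
    else:
        t_weights = pulse.temporal_profile(np.array([s.t_fs for s in snapshots]))
        if t_weights.sum() <= 0:
            t_weights = np.full(len(snapshots), 1.0 / len(snapshots))
        else:
            t_weights = t_weights / t_weights.sum()

    all_configs = {c for s in snapshots for c in s.configurations}
    ff = _config_ff_table(all_configs, grid.q_norm, omega_nodes, params)

    nt, npd = grid.domega.shape
    qflat = grid.q_vec.reshape(-1, 3)
    intensity = np.zeros((nt, npd))
    per_time = []
    pol = grid.polarization_factor(polarization)
    thomson = _RE_NM**2 * pol[:, None]                      # (n_theta, 1)

    for s, wt in zip(snapshots, t_weights):
        if wt <= 0 and len(snapshots) > 1:
            per_time.append(0.0)
            continue
        phases = np.exp(1j * (s.pos_nm @ qflat.T))          # (N_a, M)
        groups: dict = {}
        for i, cfg in enumerate(s.configurations):
            groups.setdefault(cfg, []).append(i)
        snap_i = np.zeros((nt, npd))
        for k_w, (w_ev, w_w) in enumerate(zip(omega_nodes, omega_w)):
            F = np.zeros((nt, npd), dtype=complex)
            for cfg, idx in groups.items():
                S = phases[idx].sum(axis=0).reshape(nt, npd)
                F += ff[cfg][k_w][:, None] * S
            snap_i += w_w * (np.abs(F) ** 2 + s.n_delocalized)
        intensity += wt * snap_i
        per_time.append(float(np.sum(thomson * snap_i * grid.domega)) * _NM2_BARN)

    dsdo = thomson * intensity                              # nm^2 / sr
    sigma = float(np.sum(dsdo * grid.domega)) * _NM2_BARN
    pattern = ScatteringPattern(grid, dsdo, pulse, damaged=True)
    return CrossSectionResult(sigma, per_time_barn=per_time), pattern


def undamaged_cross_section(
    state_or_snapshot,
    pulse: PulseSpec,
    **kwargs,
) -> tuple[float, ScatteringPattern]:
    """Static ground-state cross section sigma_nodam (barn).

    All atoms are put in their neutral ground configurations and a single
    static snapshot is evaluated (no time integral; same bandwidth
    quadrature as the damaged case so that the frozen limit is exact).
    """
    snap = state_or_snapshot
    if not isinstance(snap, Snapshot):
        snap = Snapshot.from_state(snap, n_delocalized=0)
    gs = Snapshot(
        t_fs=0.0,
        elements=snap.elements,
        configurations=tuple(ground_state(e) for e in snap.elements),
        pos_nm=snap.pos_nm,
        n_delocalized=0,
    )
    res, pattern = dynamic_cross_section([gs], pulse, **kwargs)
    pattern.damaged = False
    return res.sigma_dam_barn, pattern


def dse_theory(sigma_dam_barn: float, sigma_nodam_barn: float) -> float:
    """DSE = sigma_dam / sigma_nodam."""
    if sigma_nodam_barn <= 0:
        raise ValueError("undamaged cross section must be positive")
    if sigma_dam_barn < 0:
        raise ValueError("damaged cross section must be non-negative")
    return sigma_dam_barn / sigma_nodam_barn
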