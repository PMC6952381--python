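"""Classical propagation of nuclei/ions and delocalized electrons.

Units: length nm, time fs, energy eV; masses in eV fs^2/nm^2.  Forces are
softened Coulomb pair interactions evaluated with a direct O(N^2) sum
(numba-compiled); integration is velocity Verlet at a default step of
10 attoseconds.

Electrons that leave the interaction sphere with positive total energy are
removed from the force loop and counted as escaped; the remaining free
electrons are the delocalized population N_e(t) that scatters incoherently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants as cst
from .atomic_physics import DEFAULT_PARAMS, HFSParams, solve_hfs
from .configuration import ElectronicConfiguration, ground_state
from .ionization_dynamics import lotz_cross_section_nm2

__all__ = ["ClusterState", "step", "apply_continuum_processes", "delocalization_census", "MDEvent"]

# mass conversion: 1 u in eV fs^2/nm^2
_U_MASS = cst.U_KG / 1.602176634e-31
_ELECTRON_MASS = cst.ELECTRON_MASS_U * _U_MASS   # ~5.686 eV fs^2/nm^2
_K = cst.COULOMB_EV_NM                           # 1.44 eV nm


@njit(cache=True)
def _acc_pot(pos, q, minv, soft2):
    """Accelerations and per-particle pair potential energies (softened Coulomb)."""
    n = q.shape[0]
    acc = np.zeros((n, 3))
    pot = np.zeros(n)
    for i in range(n - 1):
        for j in range(i + 1, n):
            qq = q[i] * q[j]
            if qq == 0.0:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz + soft2
            inv_r = 1.0 / math.sqrt(r2)
            e = _K * qq * inv_r
            pot[i] += e
            pot[j] += e
            f = e * inv_r * inv_r  # K qq / (r^2+a^2)^(3/2)
            acc[i, 0] -= f * dx * minv[i]
            acc[i, 1] -= f * dy * minv[i]
            acc[i, 2] -= f * dz * minv[i]
            acc[j, 0] += f * dx * minv[j]
            acc[j, 1] += f * dy * minv[j]
            acc[j, 2] += f * dz * minv[j]
    return acc, pot


@njit(cache=True)
def _close_pairs(epos, ipos, r_cut):
    """Indices of (electron, ion) pairs closer than r_cut."""
    ne = epos.shape[0]
    ni = ipos.shape[0]
    cap = 4 * (ne + 1)
    out_e = np.empty(cap, dtype=np.int64)
    out_i = np.empty(cap, dtype=np.int64)
    out_r2 = np.empty(cap)
    m = 0
    r2cut = r_cut * r_cut
    for a in range(ne):
        for b in range(ni):
            dx = epos[a, 0] - ipos[b, 0]
            dy = epos[a, 1] - ipos[b, 1]
            dz = epos[a, 2] - ipos[b, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < r2cut and m < cap:
                out_e[m] = a
                out_i[m] = b
                out_r2[m] = r2
                m += 1
    return out_e[:m], out_i[:m], out_r2[:m]


@dataclass(frozen=True)
class MDEvent:
    t_fs: float
    kind: str            # "EI", "RC", "escape"
    atom_index: int      # -1 for escapes
    detail: str = ""


@dataclass
class ClusterState:
    """Positions/velocities/configurations of all particles at time t."""

    elements: list
    configurations: list
    ion_pos: np.ndarray      # (N_a, 3) nm
    ion_vel: np.ndarray      # (N_a, 3) nm/fs
    t_fs: float = 0.0
    el_pos: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    el_vel: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    n_escaped: int = 0
    interaction_radius_nm: float = 0.0
    softening_nm: float = 0.01
    params: HFSParams = DEFAULT_PARAMS
    events: list = field(default_factory=list)
    absorbed_energy_ev: float = 0.0
    escaped_energy_ev: float = 0.0
    _acc_cache: tuple | None = field(default=None, repr=False)

    def __post_init__(self):
        self.ion_pos = np.asarray(self.ion_pos, dtype=float)
        self.ion_vel = np.asarray(self.ion_vel, dtype=float)
        if self.interaction_radius_nm <= 0:
            self.interaction_radius_nm = max(2.0, 3.0 * self.initial_radius_nm())
        masses = np.array(
            [cst.ATOMIC_MASS_U[e] * _U_MASS for e in self.elements], dtype=float
        )
        self._ion_mass = masses

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_free_electrons(self) -> int:
        return len(self.el_pos)

    def ion_charges(self) -> np.ndarray:
        return np.array([c.charge for c in self.configurations], dtype=float)

    def total_bound_electrons(self) -> int:
        return sum(c.n_electrons for c in self.configurations)

    def initial_radius_nm(self) -> float:
        center = self.ion_pos.mean(axis=0)
        return float(np.max(np.linalg.norm(self.ion_pos - center, axis=1))) if self.n_atoms else 0.0

    def center_of_mass(self) -> np.ndarray:
        return self.ion_pos.mean(axis=0)

    def gyration_radius_nm(self) -> float:
        c = self.center_of_mass()
        return float(np.sqrt(np.mean(np.sum((self.ion_pos - c) ** 2, axis=1))))

    def sphere_diameter_nm(self) -> float:
        """Sphere-equivalent diameter 2 sqrt(5/3) R_gyr of the nuclei."""
        return 2.0 * math.sqrt(5.0 / 3.0) * self.gyration_radius_nm()

    # -- assembled particle arrays -------------------------------------
    def _assemble(self):
        nq = self.ion_charges()
        pos = np.vstack([self.ion_pos, self.el_pos]) if self.n_free_electrons else self.ion_pos
        vel = np.vstack([self.ion_vel, self.el_vel]) if self.n_free_electrons else self.ion_vel
        q = np.concatenate([nq, -np.ones(self.n_free_electrons)])
        minv = np.concatenate(
            [1.0 / self._ion_mass, np.full(self.n_free_electrons, 1.0 / _ELECTRON_MASS)]
        )
        return pos.copy(), vel.copy(), q, minv

    def kinetic_energy_ev(self) -> float:
        ke = 0.5 * np.sum(self._ion_mass * np.sum(self.ion_vel**2, axis=1))
        if self.n_free_electrons:
            ke += 0.5 * _ELECTRON_MASS * float(np.sum(self.el_vel**2))
        return float(ke)

    def potential_energy_ev(self) -> float:
        pos, _, q, minv = self._assemble()
        _, pot = _acc_pot(pos, q, 1.0 / np.concatenate(
            [self._ion_mass, np.full(self.n_free_electrons, _ELECTRON_MASS)]
        ), self.softening_nm**2)
        return float(0.5 * pot.sum())

    def total_energy_ev(self) -> float:
        return self.kinetic_energy_ev() + self.potential_energy_ev()

    def total_momentum(self) -> np.ndarray:
        p = np.sum(self._ion_mass[:, None] * self.ion_vel, axis=0)
        if self.n_free_electrons:
            p = p + _ELECTRON_MASS * np.sum(self.el_vel, axis=0)
        return p

    # -- electron creation/removal -------------------------------------
    def emit_electron(self, atom_index: int, kinetic_energy_ev: float, rng) -> None:
        """Birth of a photo/Auger/secondary electron at an atom, isotropic."""
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        speed = math.sqrt(max(2.0 * kinetic_energy_ev / _ELECTRON_MASS, 0.0))
        origin = self.ion_pos[atom_index] + 1.5 * self.softening_nm * u
        self.el_pos = np.vstack([self.el_pos, origin])
        self.el_vel = np.vstack([self.el_vel, self.ion_vel[atom_index] + speed * u])
        self._acc_cache = None

    def remove_electrons(self, indices) -> None:
        keep = np.ones(self.n_free_electrons, dtype=bool)
        keep[list(indices)] = False
        self.el_pos = self.el_pos[keep]
        self.el_vel = self.el_vel[keep]
        self._acc_cache = None


def step(state: ClusterState, dt_fs: float = 0.01) -> ClusterState:
    """One velocity-Verlet step under softened pairwise Coulomb forces."""
    pos, vel, q, minv = state._assemble()
    soft2 = state.softening_nm**2
    n = len(q)
    if state._acc_cache is not None and state._acc_cache[1] == n:
        acc = state._acc_cache[0]
    else:
        acc, _ = _acc_pot(pos, q, minv, soft2)
    pos_new = pos + vel * dt_fs + 0.5 * acc * dt_fs**2
    acc_new, pot = _acc_pot(pos_new, q, minv, soft2)
    vel_new = vel + 0.5 * (acc + acc_new) * dt_fs

    if not np.all(np.isfinite(pos_new)):
        bad = np.nonzero(~np.isfinite(pos_new).all(axis=1))[0]
        raise RuntimeError(
            f"non-finite positions after step at t={state.t_fs:.3f} fs "
            f"(particles {bad[:10].tolist()}); diagnostic: n={n}, "
            f"max|v|={np.nanmax(np.abs(vel_new)):.3g} nm/fs"
        )

    na = state.n_atoms
    state.ion_pos = pos_new[:na]
    state.ion_vel = vel_new[:na]
    state.el_pos = pos_new[na:]
    state.el_vel = vel_new[na:]
    state.t_fs += dt_fs
    state._acc_cache = (acc_new, n)

    _remove_escaped(state, pot[na:])
    return state


def _remove_escaped(state: ClusterState, el_pot):
    """Drop electrons beyond the interaction radius with positive total energy."""
    if state.n_free_electrons == 0:
        return
    center = state.center_of_mass()
    r = np.linalg.norm(state.el_pos - center, axis=1)
    ke = 0.5 * _ELECTRON_MASS * np.sum(state.el_vel**2, axis=1)
    etot = ke + el_pot
    out = np.nonzero((r > state.interaction_radius_nm) & (etot > 0))[0]
    if len(out):
        state.n_escaped += len(out)
        state.escaped_energy_ev += float(np.sum(etot[out]))
        state.events.append(MDEvent(state.t_fs, "escape", -1, f"{len(out)} electrons"))
        state.remove_electrons(out)


# ----------------------------------------------------------------------
# collisional processes
# ----------------------------------------------------------------------

_BINDING_CACHE: dict = {}


def _outer_shell_info(cfg: ElectronicConfiguration, params) -> tuple:
    """(outermost occupied subshell, its binding eV, occupation, lowest vacancy binding)."""
    key = (cfg, params)
    if key in _BINDING_CACHE:
        return _BINDING_CACHE[key]
    if cfg.n_electrons == 0:
        info = (None, 0.0, 0, _vacancy_binding(cfg, params))
        _BINDING_CACHE[key] = info
        return info
    data = solve_hfs(cfg.element, cfg, params)
    outer = cfg.occupied_subshells[-1]
    info = (outer, data.binding_energy_ev(outer), cfg.occupation(outer),
            _vacancy_binding(cfg, params))
    _BINDING_CACHE[key] = info
    return info


def _vacancy_binding(cfg: ElectronicConfiguration, params) -> float:
    """Binding energy an electron gains by filling the lowest vacancy."""
    gs = ground_state(cfg.element)
    for s in gs.occupied_subshells:
        if cfg.holes(s) > 0:
            try:
                filled = cfg.add(s)
                data = solve_hfs(cfg.element, filled, params)
                return data.binding_energy_ev(s)
            except Exception:
                return 10.0
    return 0.0


def apply_continuum_processes(
    state: ClusterState,
    dt_fs: float,
    rng,
    r_impact_nm: float = 0.3,
    r_capture_nm: float = 0.1,
    secondary_fraction: float = 0.25,
) -> ClusterState:
    """Electron-impact ionization and classical recombination.

    Impact ionization: for each electron-ion encounter within
    ``r_impact_nm`` the event probability is the Lotz cross section times
    the local one-ion flux density sigma * v * dt / V_sphere.  Recombination:
    an electron within ``r_capture_nm`` of an ion that is bound more deeply
    than the lowest available vacancy is captured into that vacancy.
    """
    if state.n_free_electrons == 0 or state.n_atoms == 0:
        return state
    idx_e, idx_i, r2 = _close_pairs(state.el_pos, state.ion_pos, r_impact_nm)
    if len(idx_e) == 0:
        return state
    v_sphere = 4.0 / 3.0 * math.pi * r_impact_nm**3
    consumed: set = set()
    to_remove: list = []
    for a, b, rr2 in zip(idx_e, idx_i, r2):
        if a in consumed:
            continue
        cfg = state.configurations[b]
        outer, binding, n_occ, vac_binding = _outer_shell_info(cfg, state.params)
        vrel = state.el_vel[a] - state.ion_vel[b]
        e_kin = 0.5 * _ELECTRON_MASS * float(vrel @ vrel)
        # --- recombination: classical capture into the lowest vacancy ----
        if rr2 < r_capture_nm**2 and vac_binding > 0:
            q_ion = cfg.charge
            pair_pot = -_K * q_ion / math.sqrt(rr2 + state.softening_nm**2)
            if e_kin + pair_pot < -0.5 * vac_binding:
                gs = ground_state(cfg.element)
                vac = next(s for s in gs.occupied_subshells if cfg.holes(s) > 0)
                state.configurations[b] = cfg.add(vac)
                to_remove.append(a)
                consumed.add(a)
                state.events.append(MDEvent(state.t_fs, "RC", int(b), vac))
                continue
        # --- impact ionization ------------------------------------------
        if outer is None or e_kin <= binding:
            continue
        sigma = lotz_cross_section_nm2(e_kin, binding, n_occ)
        speed = math.sqrt(float(vrel @ vrel))
        p = sigma * speed * dt_fs / v_sphere
        if rng.random() < p:
            state.configurations[b] = cfg.remove(outer)
            residual = e_kin - binding
            e_secondary = secondary_fraction * rng.random() * residual
            # slow down the projectile to conserve the energy budget
            scale = math.sqrt(max(residual - e_secondary, 0.0) / e_kin)
            state.el_vel[a] = state.ion_vel[b] + vrel * scale
            state.emit_electron(int(b), e_secondary, rng)
            consumed.add(a)
            state.events.append(MDEvent(state.t_fs, "EI", int(b), outer))
    if to_remove:
        state.remove_electrons(to_remove)
    state._acc_cache = None
    return state


def delocalization_census(state: ClusterState) -> tuple[int, int, float]:
    """(delocalized electrons inside the interaction sphere, escaped, diameter nm)."""
    if state.n_free_electrons:
        center = state.center_of_mass()
        r = np.linalg.norm(state.el_pos - center, axis=1)
        inside = int(np.sum(r <= state.interaction_radius_nm))
    else:
        inside = 0
    return inside, state.n_escaped, state.sphere_diameter_nm()
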