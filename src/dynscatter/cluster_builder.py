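"""Stoichiometric sucrose clusters and synthetic fixtures.

A cluster of n C12H22O11 molecules is packed, with random orientations and
a hard minimum intermolecular distance, into a sphere whose radius follows
from n, the molar mass and the bulk sucrose density (1581 kg/m^3).  The
single-molecule template is an idealized 3-D geometry generated once from
the sucrose connectivity (ETKDG embedding with a fixed seed); only ~0.1 nm
positional fidelity matters at the momentum transfers exercised here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import constants as cst
from .configuration import ground_state
from .plasma_md import ClusterState

__all__ = [
    "MoleculeTemplate",
    "sucrose_template",
    "build_cluster",
    "cluster_plan",
    "synthetic_shot_ensemble",
    "write_xyz",
    "write_pdb",
    "PackingError",
    "SUCROSE_MOLAR_MASS",
    "SUCROSE_DENSITY_KG_M3",
]

SUCROSE_SMILES = "OC[C@H]1O[C@@](CO)(O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O"
SUCROSE_DENSITY_KG_M3 = 1581.0
SUCROSE_MOLAR_MASS = 12 * cst.ATOMIC_MASS_U["C"] + 22 * cst.ATOMIC_MASS_U["H"] + 11 * cst.ATOMIC_MASS_U["O"]

# minimum center-center distance between packed molecules (nm); at the bulk
# density this is a ~24% packing fraction of the bounding spheres, well
# inside what random sequential addition reaches
_MIN_MOLECULE_DIST_NM = 0.55


class PackingError(RuntimeError):
    pass


def _template_rg2(tmpl) -> float:
    """Mean-square atomic distance from the molecular center (nm^2)."""
    return float(np.mean(np.sum(tmpl.coords_nm**2, axis=1)))


@dataclass(frozen=True)
class MoleculeTemplate:
    """One molecule: element symbols and internal coordinates (nm, centered)."""

    elements: tuple
    coords_nm: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        return sum(cst.ATOMIC_NUMBER[e] for e in self.elements)

    @property
    def bounding_radius_nm(self) -> float:
        return float(np.max(np.linalg.norm(self.coords_nm, axis=1)))


@lru_cache(maxsize=1)
def sucrose_template() -> MoleculeTemplate:
    """45-atom sucrose geometry (C12 H22 O11), deterministic embedding."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(SUCROSE_SMILES)
    mol = Chem.AddHs(mol)
    ps = AllChem.ETKDGv3()
    ps.randomSeed = 20200109
    if AllChem.EmbedMolecule(mol, ps) != 0:
        raise RuntimeError("sucrose embedding failed")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    xyz = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    ) * 0.1  # Angstrom -> nm
    xyz -= xyz.mean(axis=0)
    return MoleculeTemplate(elements, xyz)


def cluster_plan(n_molecules: int, density_kg_m3: float = SUCROSE_DENSITY_KG_M3) -> dict:
    """Bookkeeping for an n-molecule cluster without building it.

    Returns the sphere diameter set by the bulk density, and the particle
    counts (nuclei, bound electrons, total tracked particles).
    """
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    mass_kg = n_molecules * SUCROSE_MOLAR_MASS / (cst.N_AVOGADRO * 1e3)
    volume_m3 = mass_kg / density_kg_m3
    diameter_nm = (6.0 * volume_m3 / math.pi) ** (1.0 / 3.0) * 1e9
    n_nuclei = 45 * n_molecules
    n_electrons = 182 * n_molecules
    return {
        "n_molecules": n_molecules,
        "diameter_nm": diameter_nm,
        "n_nuclei": n_nuclei,
        "n_electrons": n_electrons,
        "n_particles": n_nuclei + n_electrons,
    }


def build_cluster(
    n_molecules: int,
    seed: int = 0,
    density_kg_m3: float = SUCROSE_DENSITY_KG_M3,
    relaxation: float = 1.0,
    max_attempts_per_molecule: int = 2000,
) -> ClusterState:
    """Pack n sucrose molecules into a density-consistent sphere.

    ``relaxation`` > 1 inflates the sphere radius if packing fails.
    All atoms start in their neutral ground-state configurations with zero
    velocity at t = 0.
    """
    from scipy.spatial.transform import Rotation

    plan = cluster_plan(n_molecules, density_kg_m3)
    tmpl = sucrose_template()
    rng = np.random.default_rng(seed)
    # molecule centers fill the nominal sphere; peripheral molecules may
    # protrude by a fraction of their size, which washes out for n >~ 100
    r_place = 0.5 * plan["diameter_nm"] * relaxation

    centers = np.empty((n_molecules, 3))
    d2_min = _MIN_MOLECULE_DIST_NM**2
    for m in range(n_molecules):
        for attempt in range(max_attempts_per_molecule):
            p = rng.uniform(-1.0, 1.0, 3) * r_place
            if p @ p > r_place * r_place:
                continue
            if m and np.min(np.sum((centers[:m] - p) ** 2, axis=1)) < d2_min:
                continue
            centers[m] = p
            break
        else:
            raise PackingError(
                f"could not place molecule {m + 1}/{n_molecules}; retry with "
                f"relaxation > {relaxation}"
            )

    if n_molecules > 1:
        # hard-core rejection biases centers outward; rescale them so the
        # nuclear radius of gyration equals that of a uniform sphere at the
        # nominal bulk density
        centers -= centers.mean(axis=0)
        rg2 = float(np.mean(np.sum(centers**2, axis=1))) + _template_rg2(tmpl)
        rg2_target = 0.6 * (0.5 * plan["diameter_nm"]) ** 2
        if rg2 > rg2_target > _template_rg2(tmpl):
            scale = math.sqrt(
                (rg2_target - _template_rg2(tmpl))
                / (rg2 - _template_rg2(tmpl))
            )
            centers *= scale

    elements: list = []
    coords: list = []
    for m in range(n_molecules):
        rot = Rotation.random(rng=rng).as_matrix()
        coords.append(tmpl.coords_nm @ rot.T + centers[m])
        elements.extend(tmpl.elements)
    pos = np.vstack(coords)
    configs = [ground_state(e) for e in elements]
    return ClusterState(
        elements=elements,
        configurations=configs,
        ion_pos=pos,
        ion_vel=np.zeros_like(pos),
    )


# ----------------------------------------------------------------------
# structure export
# ----------------------------------------------------------------------

def write_xyz(state: ClusterState, path) -> None:
    """Write the nuclei as an XYZ file (Angstrom)."""
    with open(path, "w") as fh:
        fh.write(f"{state.n_atoms}\n")
        fh.write(f"sucrose cluster t={state.t_fs:.3f} fs\n")
        for e, p in zip(state.elements, state.ion_pos):
            x, y, z = p * 10.0
            fh.write(f"{e} {x:.4f} {y:.4f} {z:.4f}\n")


def write_pdb(state: ClusterState, path) -> None:
    """Write the nuclei as a minimal PDB file (HETATM records, Angstrom)."""
    with open(path, "w") as fh:
        for i, (e, p) in enumerate(zip(state.elements, state.ion_pos), start=1):
            x, y, z = p * 10.0
            fh.write(
                f"HETATM{i % 100000:5d} {e:<3s} MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {e:>2s}\n"
            )
        fh.write("END\n")


# ----------------------------------------------------------------------
# synthetic single-shot ensembles
# ----------------------------------------------------------------------

def synthetic_shot_ensemble(
    geometry,
    size_mean_nm: float,
    size_sd_nm: float,
    focal_distribution,
    damage_factor: float,
    seed: int,
    n_shots: int = 100,
    delta_n: float | None = None,
):
    """Noisy sphere-diffraction images with known ground truth.

    Emulates the experimental hit ensemble: particle diameters are drawn
    from a normal size distribution, incident fluences from the focal
    fluence distribution, and the expected image is the sphere model at an
    effective fluence ``damage_factor * F`` with Poisson counting noise.

    Returns (list of images, pandas DataFrame with d_true / fluence_true).
    """
    import pandas as pd

    from .sphere_fit import SphereModel, refractive_decrement, sphere_image

    rng = np.random.default_rng(seed)
    fluences, weights = focal_distribution
    if delta_n is None:
        omega = cst.wavelength_nm_to_photon_energy(geometry.wavelength_nm)
        delta_n = abs(
            refractive_decrement({"C": 12, "H": 22, "O": 11}, SUCROSE_DENSITY_KG_M3, omega)
        )
    images = []
    rows = []
    for _ in range(n_shots):
        d = max(rng.normal(size_mean_nm, size_sd_nm), 2.0)
        f_uJ = float(rng.choice(fluences, p=weights)) if len(fluences) > 1 else float(fluences[0])
        omega = cst.wavelength_nm_to_photon_energy(geometry.wavelength_nm)
        f_ph = cst.fluence_uJ_um2_to_photons_per_nm2(f_uJ, omega)
        model = SphereModel(d, delta_n, geometry.wavelength_nm, damage_factor * f_ph)
        expected = sphere_image(model, geometry)
        images.append(rng.poisson(expected).astype(float))
        rows.append({"d_true_nm": d, "fluence_true_uJ_um2": f_uJ})
    return images, pd.DataFrame(rows)
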