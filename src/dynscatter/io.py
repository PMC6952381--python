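"""HDF5 I/O: CXI-style image containers and atomic-data archives.

Diffraction images follow the CXI convention (``entry_1/data_1/data`` plus
detector/source metadata); a ground-truth sidecar table for synthetic
ensembles is written as TSV next to the container.  Atomic data export uses
one HDF5 group per configuration with the energies, radial grids and cross
section tables documented below.
"""

from __future__ import annotations

import numpy as np

from .atomic_physics import AtomicData
from .configuration import ElectronicConfiguration


# ----------------------------------------------------------------------
# CXI-style images
# ----------------------------------------------------------------------

def write_cxi_images(path, images, geometry, truth=None, photon_energy_ev=None):
    """Write a stack of diffraction images in a CXI-style layout.

    Layout: entry_1/data_1/data (n, ny, nx), entry_1/instrument_1/
    detector_1/{distance, x_pixel_size, y_pixel_size}, source_1/energy.
    A pandas ``truth`` table, if given, is stored at <path>.truth.tsv.
    """
    import h5py

    arr = np.asarray(images)
    with h5py.File(path, "w") as fh:
        entry = fh.create_group("entry_1")
        data = entry.create_group("data_1")
        data.create_dataset("data", data=arr)
        det = entry.create_group("instrument_1/detector_1")
        det.create_dataset("distance", data=geometry.distance_mm * 1e-3)       # m
        det.create_dataset("x_pixel_size", data=geometry.pixel_pitch_mm * 1e-3)
        det.create_dataset("y_pixel_size", data=geometry.pixel_pitch_mm * 1e-3)
        det.attrs["gap_m"] = geometry.gap_mm * 1e-3
        det.attrs["n_rows_panel"] = geometry.n_rows_panel
        src = entry.create_group("instrument_1/source_1")
        if photon_energy_ev is None:
            from . import constants as cst

            photon_energy_ev = cst.wavelength_nm_to_photon_energy(geometry.wavelength_nm)
        src.create_dataset("energy", data=photon_energy_ev * 1.602176634e-19)  # J
    if truth is not None:
        truth.to_csv(str(path) + ".truth.tsv", sep="\t", index=False)


def read_cxi_images(path):
    """Read images + (distance_mm, pixel_mm, photon_energy_ev) from a CXI file."""
    import h5py

    with h5py.File(path, "r") as fh:
        data = fh["entry_1/data_1/data"][...]
        det = fh["entry_1/instrument_1/detector_1"]
        distance_mm = float(det["distance"][()]) * 1e3
        pixel_mm = float(det["x_pixel_size"][()]) * 1e3
        energy_ev = float(fh["entry_1/instrument_1/source_1/energy"][()]) / 1.602176634e-19
    return data, distance_mm, pixel_mm, energy_ev


# ----------------------------------------------------------------------
# atomic data archives
# ----------------------------------------------------------------------

def write_atomic_data(path, datasets):
    """Export AtomicData records to an HDF5 archive.

    One group per configuration (named like ``O_1s2_2s2_2p4``) holding:
    ``r`` (log grid, a0), ``potential`` (Hartree), ``rho4pir2``, per-subshell
    ``orbitals/<subshell>`` and ``energies/<subshell>`` (eV), transition
    table ``transitions`` (omega_ev, f_osc, gamma_ev with subshell labels in
    attrs), and scalars ``total_energy_ev``, ``auger_rate_per_fs``.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        for data in datasets:
            g = fh.create_group(_group_name(data.configuration))
            g.attrs["element"] = data.configuration.element
            g.attrs["occupations"] = list(data.configuration.occupations)
            g.create_dataset("r", data=data.r)
            g.create_dataset("potential", data=data.potential)
            g.create_dataset("rho4pir2", data=data.rho4pir2)
            g.create_dataset("total_energy_ev", data=data.total_energy_ev)
            g.create_dataset("auger_rate_per_fs", data=data.auger_rate_per_fs)
            ge = g.create_group("energies")
            go = g.create_group("orbitals")
            for s, e in data.orbital_energies.items():
                ge.create_dataset(s, data=e)
                go.create_dataset(s, data=data.orbitals[s])
            if data.transitions:
                tarr = np.array(
                    [[t.omega_ev, t.f_osc, t.gamma_ev] for t in data.transitions]
                )
                td = g.create_dataset("transitions", data=tarr)
                td.attrs["lower"] = [t.lower for t in data.transitions]
                td.attrs["upper"] = [t.upper for t in data.transitions]


def read_atomic_data_summary(path):
    """Read back configuration labels and orbital energies from an archive."""
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for name, g in fh.items():
            cfg = ElectronicConfiguration(
                g.attrs["element"], tuple(int(o) for o in g.attrs["occupations"])
            )
            energies = {s: float(d[()]) for s, d in g["energies"].items()}
            out[cfg] = energies
    return out


def _group_name(cfg: ElectronicConfiguration) -> str:
    from .configuration import SUBSHELLS

    body = "_".join(
        f"{s}{o}" for s, o in zip(SUBSHELLS, cfg.occupations)
    )
    return f"{cfg.element}_{body}" if body else f"{cfg.element}_bare"
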