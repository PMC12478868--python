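"""Shared fixtures: small quantum centers, redox couples and file builders."""

import numpy as np
import pytest

from pmmredox import (ElectronicState, Geometry, QuantumCenter, RedoxSpecies)


def make_geometry(seed: int = 0, n_atoms: int = 4,
                  tags: dict | None = None) -> Geometry:
    """Random non-collinear geometry, a few angstrom across."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-1.5, 1.5, size=(n_atoms, 3))
    elements = tuple("CNOH"[i % 4] for i in range(n_atoms))
    return Geometry(elements=elements, coords=coords, tags=tags or {})


def make_qc(name: str, redox: str, total_charge: float,
            energies, geometry: Geometry, seed: int = 1,
            dipole_scale: float = 0.4) -> QuantumCenter:
    """Quantum center with reproducible dipoles and valid ESP charges."""
    rng = np.random.default_rng(seed)
    n = len(energies)
    n_atoms = geometry.n_atoms
    states = []
    for l, e in enumerate(energies):
        q = rng.normal(0.0, 0.2, size=n_atoms)
        q += (total_charge - q.sum()) / n_atoms     # exact charge sum
        states.append(ElectronicState(
            index=l, energy=float(e),
            permanent_dipole=rng.normal(0.0, dipole_scale, size=3),
            esp_charges=q))
    td = {(i, j): rng.normal(0.0, dipole_scale, size=3)
          for i in range(n) for j in range(i + 1, n)}
    return QuantumCenter(name=name, redox=redox, total_charge=total_charge,
                         geometry=geometry, states=tuple(states),
                         transition_dipoles=td)


@pytest.fixture
def toy_geometry() -> Geometry:
    return make_geometry(seed=0, n_atoms=4)


@pytest.fixture
def toy_species(toy_geometry) -> RedoxSpecies:
    """Two-state redox couple with gas-phase AEA = 0.18 eV.

    The reduced ground state sits 0.18 eV below the oxidized one, so the
    zero-perturbation reduction gap is -0.18 eV.
    """
    ox = make_qc("toy", "oxidized", 0.0, [0.0, 2.0], toy_geometry, seed=1)
    red = make_qc("toy", "reduced", -1.0, [-0.18, 1.5], toy_geometry, seed=2)
    return RedoxSpecies(oxidized=ox, reduced=red,
                        gas_reference={"oxidized": 0.0, "reduced": -0.18})


@pytest.fixture
def five_state_species() -> RedoxSpecies:
    """A 5-state couple (the default state count for the target systems)."""
    geom = make_geometry(seed=3, n_atoms=6,
                         tags={"base": (0, 1, 2, 3), "sugar": (4, 5)})
    ox = make_qc("penta", "oxidized", 0.0,
                 [0.0, 1.1, 2.3, 3.0, 4.2], geom, seed=4)
    red = make_qc("penta", "reduced", -1.0,
                  [-0.25, 0.9, 1.8, 2.6, 3.9], geom, seed=5)
    return RedoxSpecies(oxidized=ox, reduced=red)


def write_gro(path, frames, names=None, residues=None):
    """Write a multi-frame GRO file (coordinates in nm)."""
    with open(path, "w") as fh:
        for f_idx, (coords_nm, box_nm, time_ps) in enumerate(frames):
            n = len(coords_nm)
            fh.write(f"synthetic frame t= {time_ps:.3f}\n{n}\n")
            for k, xyz in enumerate(coords_nm):
                name = (names[k] if names else f"A{k % 10}")
                res = (residues[k] if residues else "SOL")
                fh.write(f"{(k // 3 + 1) % 100000:5d}{res:<5s}{name:>5s}"
                         f"{(k + 1) % 100000:5d}"
                         f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n")
            fh.write(f"  {box_nm[0]:.5f}  {box_nm[1]:.5f}  {box_nm[2]:.5f}\n")
    return path


def write_pdb(path, frames, names=None):
    """Write a multi-model PDB (coordinates in angstrom, CRYST1 box)."""
    with open(path, "w") as fh:
        for f_idx, (coords, box) in enumerate(frames):
            fh.write(f"MODEL     {f_idx + 1:4d}\n")
            fh.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                     "  90.00  90.00  90.00 P 1\n")
            for k, xyz in enumerate(coords):
                name = (names[k] if names else f"A{k % 10}")
                fh.write(f"ATOM  {k + 1:5d} {name:<4s}SOL A{k + 1:4d}    "
                         f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                         "  1.00  0.00           C\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


MINIMAL_QC_JSON = {
    "schema_version": 1,
    "name": "minimal",
    "redox": "oxidized",
    "total_charge": 0.0,
    "geometry": {"elements": ["H"], "coords_angstrom": [[0.0, 0.0, 0.0]]},
    "states": [{"index": 0, "energy": 0.0,
                "permanent_dipole": [0.0, 0.0, 0.0],
                "esp_charges": [0.0]}],
    "transition_dipoles": [],
    "units": {"energy": "eV", "dipole": "e*angstrom", "length": "angstrom"},
}
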