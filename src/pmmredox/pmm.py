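"""Perturbed matrix method core: field evaluation, Hamiltonian assembly,
diagonalization, and perturbed-energy trajectories.

At each environment frame the classical point charges generate an
electrostatic potential and field at the quantum center.  That perturbation
enters the QC's electronic Hamiltonian (expressed in the basis of the
unperturbed vacuum eigenstates) either through

* ``dipole`` mode — a multipole expansion around the expansion center r0:
  diagonal  eps_l + q_T * Phi(r0),  off-diagonal  -E(r0) . mu_ll'; or
* ``esp_diagonal`` mode — the diagonal replaced by the per-state ESP
  charges contracted against per-atom potentials,
  eps_l + sum_k q_k^(l) * Phi(r_k), with the same dipole off-diagonals.

Diagonalizing the resulting symmetric matrix frame by frame yields the
perturbed ground-state energy of each redox form; their difference is the
reduction energy gap that drives the free-energy estimators in
:mod:`pmmredox.thermo`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import COULOMB_EV_ANG
from .errors import ClashError, FrameError, PmmRedoxError
from .frames import EnvironmentFrame, FrameStream
from .qc import Geometry, QuantumCenter, RedoxSpecies

__all__ = [
    "PerturbationField",
    "PerturbedState",
    "compute_field",
    "build_perturbed_hamiltonian",
    "diagonalize",
    "perturbed_energy_trajectory",
]

SYMMETRY_TOL = 1e-10     # eV, max allowed |H - H.T|
DEGENERACY_TOL = 1e-9    # eV, eigenvalue tie window for state tracking
DEFAULT_CLASH_RADIUS = 0.5  # angstrom


@dataclass(frozen=True)
class PerturbationField:
    """Electrostatic perturbation at the quantum center for one frame.

    ``potential`` in volts (eV/e) at r0; ``field`` in V/angstrom at r0;
    ``atom_potentials`` (optional) one potential per QC atom, needed by the
    esp_diagonal expansion mode.
    """

    potential: float
    field: np.ndarray               # (3,)
    atom_potentials: Optional[np.ndarray] = None  # (n_qc_atoms,)
    frame_index: int = 0

    def __post_init__(self):
        f = np.asarray(self.field, dtype=float).reshape(3)
        if not (np.isfinite(self.potential) and np.all(np.isfinite(f))):
            raise FrameError(
                f"frame {self.frame_index}: non-finite perturbation")
        object.__setattr__(self, "field", f)
        if self.atom_potentials is not None:
            ap = np.asarray(self.atom_potentials, dtype=float).ravel()
            if not np.all(np.isfinite(ap)):
                raise FrameError(
                    f"frame {self.frame_index}: non-finite atom potentials")
            object.__setattr__(self, "atom_potentials", ap)


@dataclass(frozen=True)
class PerturbedState:
    """Result of diagonalizing one perturbed Hamiltonian.

    ``eigenvalues`` ascending (eV); ``ground_energy`` is the lowest;
    ``ground_vector`` is the ground-state eigenvector in the unperturbed
    basis, normalized to 1.
    """

    eigenvalues: np.ndarray
    ground_energy: float
    ground_vector: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float).ravel()
        vec = np.asarray(self.ground_vector, dtype=float).ravel()
        if np.any(np.diff(ev) < 0):
            raise PmmRedoxError("eigenvalues must be sorted ascending")
        if abs(np.linalg.norm(vec) - 1.0) > 1e-10:
            raise PmmRedoxError("ground eigenvector must be normalized")
        object.__setattr__(self, "eigenvalues", ev)
        object.__setattr__(self, "ground_vector", vec)


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

def _displacements(points: np.ndarray, sources: np.ndarray,
                   box: Optional[np.ndarray], pbc_mode: str) -> np.ndarray:
    """Displacement vectors point - source, shape (n_points, n_src, 3)."""
    d = points[:, None, :] - sources[None, :, :]
    if pbc_mode == "minimum_image":
        d -= box * np.round(d / box)
    elif pbc_mode != "none":
        raise FrameError(f"unknown pbc_mode {pbc_mode!r}; "
                         "choose 'none' or 'minimum_image'")
    return d


def compute_field(frame: EnvironmentFrame, qc_geometry: Geometry,
                  r0: np.ndarray, pbc_mode: str = "minimum_image",
                  per_atom_potentials: bool = True,
                  clash_radius: float = DEFAULT_CLASH_RADIUS
                  ) -> PerturbationField:
    """Potential and field of a frame's point charges at the quantum center.

    Phi(r) = k_e * sum_j q_j / |r - r_j| and
    E(r)  = k_e * sum_j q_j (r - r_j) / |r - r_j|^3 with
    k_e = 14.399645 eV*angstrom/e^2.  All charges in the frame contribute
    (no cutoff); under ``minimum_image`` each source is folded to its
    nearest periodic image of the evaluation point.

    A source charge closer than ``clash_radius`` to r0 or to any QC atom
    raises :class:`ClashError` naming the frame — the usual cause is QC
    atoms left in the perturbing set.
    """
    r0 = np.asarray(r0, dtype=float).reshape(3)
    points = np.vstack([r0[None, :], qc_geometry.coords])
    d = _displacements(points, frame.positions, frame.box, pbc_mode)
    dist = np.linalg.norm(d, axis=2)                     # (1+n_qc, n_src)
    too_close = dist < clash_radius
    if np.any(too_close):
        j = int(np.argwhere(too_close)[0][1])
        raise ClashError(
            f"frame {frame.index}: source charge {j} within "
            f"{clash_radius} angstrom of the quantum center "
            f"(min distance {dist.min():.3f} angstrom) — check the QC mask")
    inv = 1.0 / dist
    pots = COULOMB_EV_ANG * (frame.charges[None, :] * inv).sum(axis=1)
    field = COULOMB_EV_ANG * (
        frame.charges[:, None] * d[0] * inv[0][:, None] ** 3
    ).sum(axis=0)
    return PerturbationField(
        potential=float(pots[0]), field=field,
        atom_potentials=pots[1:] if per_atom_potentials else None,
        frame_index=frame.index)


# ---------------------------------------------------------------------------
# Hamiltonian assembly and diagonalization
# ---------------------------------------------------------------------------

def build_perturbed_hamiltonian(qc: QuantumCenter, field: PerturbationField,
                                mode: str = "esp_diagonal") -> np.ndarray:
    """Assemble the perturbed electronic Hamiltonian (N x N, eV, symmetric).

    ``dipole`` mode: H_ll' = eps_l d_ll' + q_T Phi(r0) d_ll' - E . mu_ll'.
    ``esp_diagonal`` mode: diagonal eps_l + sum_k q_k^(l) Phi(r_k) (per-state
    ESP charges against per-atom potentials); off-diagonals as in dipole
    mode.  Note -E.mu also contributes to the diagonal in dipole mode via
    the permanent dipoles, matching a first-order multipole expansion.
    """
    if mode not in ("dipole", "esp_diagonal"):
        raise PmmRedoxError(
            f"unknown expansion mode {mode!r}; choose 'dipole' or "
            "'esp_diagonal'")
    mu = qc.dipole_matrix()                    # (N, N, 3)
    h = -np.einsum("ijk,k->ij", mu, field.field)
    if mode == "dipole":
        diag = qc.energies + qc.total_charge * field.potential \
            + np.diag(h)
        np.fill_diagonal(h, diag)
    else:
        if field.atom_potentials is None:
            raise PmmRedoxError(
                "esp_diagonal mode needs per-atom potentials; recompute the "
                "field with per_atom_potentials=True")
        if field.atom_potentials.size != qc.geometry.n_atoms:
            raise PmmRedoxError(
                f"{field.atom_potentials.size} atom potentials for "
                f"{qc.geometry.n_atoms} QC atoms")
        esp = np.array([s.esp_charges @ field.atom_potentials
                        for s in qc.states])
        np.fill_diagonal(h, qc.energies + esp)
    return h


def diagonalize(hamiltonian: np.ndarray, frame_index: int = 0,
                previous_ground: Optional[np.ndarray] = None
                ) -> PerturbedState:
    """Full eigendecomposition of a symmetric perturbed Hamiltonian.

    Eigenvalues are returned ascending and the ground state is the lowest.
    If the two lowest eigenvalues are degenerate (within 1e-9 eV) and a
    previous frame's ground eigenvector is supplied, the tie is broken by
    maximal overlap with it to avoid state-swapping artifacts along a
    trajectory; otherwise index order decides.
    """
    h = np.asarray(hamiltonian, dtype=float)
    asym = np.abs(h - h.T).max() if h.size else 0.0
    if asym > SYMMETRY_TOL:
        raise PmmRedoxError(
            f"Hamiltonian asymmetric by {asym:.2e} eV (tolerance "
            f"{SYMMETRY_TOL:.0e})")
    vals, vecs = np.linalg.eigh(0.5 * (h + h.T))
    ground = 0
    if (vals.size > 1 and vals[1] - vals[0] < DEGENERACY_TOL
            and previous_ground is not None):
        overlaps = np.abs(vecs[:, :2].T @ previous_ground)
        ground = int(np.argmax(overlaps))
    gvec = vecs[:, ground]
    # fix an overall sign for reproducibility
    k = int(np.argmax(np.abs(gvec)))
    if gvec[k] < 0:
        gvec = -gvec
    return PerturbedState(
        eigenvalues=vals, ground_energy=float(vals[ground]),
        ground_vector=gvec / np.linalg.norm(gvec), frame_index=frame_index)


# ---------------------------------------------------------------------------
# trajectory driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyTrajectory:
    """Aligned per-frame perturbed ground-state energies of a redox couple.

    ``gap`` is the reduction energy gap Delta U_e = U_red - U_ox, the
    package-wide sign convention (energy change on adding the electron).
    """

    times_ps: np.ndarray
    u_ox: np.ndarray
    u_red: np.ndarray
    mode: str
    pbc_mode: str

    @property
    def gap(self) -> np.ndarray:
        return self.u_red - self.u_ox


def perturbed_energy_trajectory(species: RedoxSpecies, frames: FrameStream,
                                mode: str = "esp_diagonal",
                                pbc_mode: str = "minimum_image",
                                clash_radius: float = DEFAULT_CLASH_RADIUS
                                ) -> EnergyTrajectory:
    """Perturb and diagonalize both redox forms over every frame.

    Both forms see the SAME field in each frame (the reduction is vertical
    within a frame: one electron arrives, nuclei do not move), so the per
    frame gap isolates the electronic response plus the electrostatic
    coupling difference of the two charge states.
    """
    ox, red = species.oxidized, species.reduced
    r0 = ox.expansion_center()
    n = len(frames)
    u_ox = np.empty(n)
    u_red = np.empty(n)
    times = np.empty(n)
    prev_ox = prev_red = None
    for i, fr in enumerate(frames):
        try:
            field = compute_field(fr, ox.geometry, r0, pbc_mode=pbc_mode,
                                  per_atom_potentials=(mode == "esp_diagonal"),
                                  clash_radius=clash_radius)
            s_ox = diagonalize(build_perturbed_hamiltonian(ox, field, mode),
                               frame_index=fr.index, previous_ground=prev_ox)
            s_red = diagonalize(build_perturbed_hamiltonian(red, field, mode),
                                frame_index=fr.index, previous_ground=prev_red)
        except PmmRedoxError as exc:
            raise type(exc)(f"frame {fr.index} (t={fr.time_ps} ps): {exc}") \
                from exc
        prev_ox, prev_red = s_ox.ground_vector, s_red.ground_vector
        u_ox[i], u_red[i] = s_ox.ground_energy, s_red.ground_energy
        times[i] = fr.time_ps
    return EnergyTrajectory(times_ps=times, u_ox=u_ox, u_red=u_red,
                            mode=mode, pbc_mode=pbc_mode)
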