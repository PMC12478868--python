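"""Quantum-center model and gas-phase redox observables.

A quantum center (QC) is the molecule treated quantum mechanically — here a
nucleobase in one redox form.  Its unperturbed electronic structure (state
energies, permanent and transition dipoles, per-state ESP atomic charges,
geometry) is computed once in vacuum by an external electronic-structure
code and consumed from a versioned JSON schema; this module never runs
quantum chemistry itself.

Gas-phase observables implemented here:

* vertical electron affinity   VEA = E_neutral - E_anion, both at the frozen
  neutral geometry (positive => the anion is vertically bound);
* adiabatic electron affinity  AEA = E_neutral(min) - E_anion(min), with
  optional zero-point corrections;
* Kabsch minimal RMSD between two geometries (unweighted, proper rotations
  only) — the structural-reorganization measure for anion vs neutral;
* the fraction of the total charge an atom subset carries, from per-state
  ESP charges (charge-localization diagnostics at a QM/MM boundary).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from .constants import DIPOLE_FACTORS, ENERGY_FACTORS, LENGTH_FACTORS
from .errors import ChargeSumError, GeometryError, SchemaError

CHARGE_SUM_TOL = 1e-6  # e, per-state ESP sum vs total charge

__all__ = [
    "Geometry",
    "ElectronicState",
    "QuantumCenter",
    "RedoxSpecies",
    "load_quantum_center",
    "save_quantum_center",
    "vertical_electron_affinity",
    "adiabatic_electron_affinity",
    "kabsch_rmsd",
    "charge_localization_fraction",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Atomic geometry in angstrom with optional moiety tags.

    ``tags`` maps a moiety name (e.g. ``"base"``, ``"sugar"``) to a tuple of
    atom indices; tags cover a subset of atoms without duplicates within a
    tag.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), angstrom
    tags: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise GeometryError(
                f"{len(self.elements)} element labels but {coords.shape[0]} "
                "coordinate triples")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        n = coords.shape[0]
        for name, idx in dict(self.tags).items():
            idx = tuple(int(i) for i in idx)
            if len(set(idx)) != len(idx):
                raise GeometryError(f"tag {name!r} has duplicate indices")
            if idx and (min(idx) < 0 or max(idx) >= n):
                raise GeometryError(f"tag {name!r} indexes outside 0..{n - 1}")
        object.__setattr__(
            self, "tags",
            {k: tuple(int(i) for i in v) for k, v in dict(self.tags).items()})

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def geometric_center(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class ElectronicState:
    """One unperturbed electronic state of a quantum center.

    ``energy`` is in eV relative to the species' declared reference;
    ``permanent_dipole`` in e*angstrom; ``esp_charges`` one per atom, in e.
    The ESP charges of every state must sum to the species' total charge.
    """

    index: int
    energy: float
    permanent_dipole: np.ndarray  # (3,), e*angstrom
    esp_charges: np.ndarray       # (n_atoms,), e

    def __post_init__(self):
        mu = np.asarray(self.permanent_dipole, dtype=float).reshape(3)
        q = np.asarray(self.esp_charges, dtype=float).ravel()
        if not (np.isfinite(self.energy) and np.all(np.isfinite(mu))
                and np.all(np.isfinite(q))):
            raise SchemaError(f"state {self.index}: non-finite entries")
        object.__setattr__(self, "permanent_dipole", mu)
        object.__setattr__(self, "esp_charges", q)


@dataclass(frozen=True)
class QuantumCenter:
    """A redox species' complete unperturbed electronic structure.

    ``transition_dipoles`` stores one vector per unordered state pair
    (i < j); :meth:`dipole_matrix` symmetrizes into the full (N, N, 3)
    array with permanent dipoles on the diagonal.  ``r0`` is the expansion
    center for the perturbation (defaults to the geometric center of the
    atoms, overridable in the schema).
    """

    name: str
    redox: str                      # "oxidized" | "reduced"
    total_charge: float             # e
    geometry: Geometry
    states: tuple[ElectronicState, ...]
    transition_dipoles: Mapping[tuple[int, int], np.ndarray]
    r0: Optional[np.ndarray] = None  # angstrom; None -> geometric center

    def __post_init__(self):
        if self.redox not in ("oxidized", "reduced"):
            raise SchemaError(
                f"redox must be 'oxidized' or 'reduced', got {self.redox!r}")
        if len(self.states) < 1:
            raise SchemaError("at least one electronic state required")
        idx = [s.index for s in self.states]
        if len(set(idx)) != len(idx):
            raise SchemaError(f"duplicate state indices: {sorted(idx)}")
        states = tuple(sorted(self.states, key=lambda s: s.index))
        if [s.index for s in states] != list(range(len(states))):
            raise SchemaError("state indices must be 0..N-1")
        n_atoms = self.geometry.n_atoms
        for s in states:
            if s.esp_charges.size != n_atoms:
                raise SchemaError(
                    f"state {s.index}: {s.esp_charges.size} ESP charges for "
                    f"{n_atoms} atoms")
            if abs(s.esp_charges.sum() - self.total_charge) > CHARGE_SUM_TOL:
                raise ChargeSumError(
                    f"state {s.index}: ESP charges sum to "
                    f"{s.esp_charges.sum():.6f} e but total charge is "
                    f"{self.total_charge:g} e")
        # symmetrize transition dipoles onto canonical i < j keys
        td: dict[tuple[int, int], np.ndarray] = {}
        for (i, j), v in dict(self.transition_dipoles).items():
            i, j = int(i), int(j)
            if i == j:
                raise SchemaError("transition dipole with equal indices; "
                                  "permanent dipoles live on the states")
            key = (min(i, j), max(i, j))
            v = np.asarray(v, dtype=float).reshape(3)
            if key in td and not np.allclose(td[key], v):
                raise SchemaError(
                    f"conflicting transition dipoles for pair {key}")
            td[key] = v
        n = len(states)
        missing = [(i, j) for i in range(n) for j in range(i + 1, n)
                   if (i, j) not in td]
        if missing:
            raise SchemaError(f"missing transition dipoles for pairs {missing}")
        r0 = self.r0
        if r0 is not None:
            r0 = np.asarray(r0, dtype=float).reshape(3)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "transition_dipoles", td)
        object.__setattr__(self, "r0", r0)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states])

    def expansion_center(self) -> np.ndarray:
        if self.r0 is not None:
            return self.r0
        return self.geometry.geometric_center()

    def dipole_matrix(self) -> np.ndarray:
        """Full symmetric dipole matrix, shape (N, N, 3), e*angstrom."""
        n = self.n_states
        mu = np.zeros((n, n, 3))
        for s in self.states:
            mu[s.index, s.index] = s.permanent_dipole
        for (i, j), v in self.transition_dipoles.items():
            mu[i, j] = v
            mu[j, i] = v
        return mu


@dataclass(frozen=True)
class RedoxSpecies:
    """A redox couple: the oxidized (neutral) and reduced (radical anion)
    quantum centers sharing one atom list, plus optional gas-phase reference
    energies for environment-shift analysis.

    ``gas_reference`` maps a redox label to that form's gas-phase electronic
    energy (eV) on the same reference as the state energies.
    """

    oxidized: QuantumCenter
    reduced: QuantumCenter
    gas_reference: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.oxidized.geometry.elements != self.reduced.geometry.elements:
            raise SchemaError(
                "oxidized and reduced quantum centers must share identical "
                "atom labels and ordering")
        dq = self.oxidized.total_charge - self.reduced.total_charge
        if abs(dq - 1.0) > CHARGE_SUM_TOL:
            raise SchemaError(
                f"reduced total charge must be oxidized - 1 e (one-electron "
                f"reduction); got difference {dq:g} e")
        for key in self.gas_reference:
            if key not in ("oxidized", "reduced"):
                raise SchemaError(f"gas_reference key {key!r} invalid")

    @property
    def n_atoms(self) -> int:
        return self.oxidized.geometry.n_atoms


# ---------------------------------------------------------------------------
# JSON schema (pydantic models mirror the on-disk layout)
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


class _GeometryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    elements: list[str]
    coords_angstrom: list[list[float]]
    tags: dict[str, list[int]] = {}


class _StateModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    index: int
    energy: float
    permanent_dipole: list[float]
    esp_charges: list[float]


class _TransitionDipoleModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    i: int
    j: int
    vector: list[float]


class _UnitsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    energy: str = "eV"
    dipole: str = "e*angstrom"
    length: str = "angstrom"


class _QCFileModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int = SCHEMA_VERSION
    name: str
    redox: str
    total_charge: float
    geometry: _GeometryModel
    states: list[_StateModel]
    transition_dipoles: list[_TransitionDipoleModel] = []
    units: _UnitsModel = _UnitsModel()
    expansion_center: Optional[list[float]] = None


def _unit_factor(table: Mapping[str, float], unit: str, kind: str) -> float:
    key = unit.strip().lower().replace("·", "*").replace(" ", "")
    if key not in table:
        raise SchemaError(
            f"unknown {kind} unit {unit!r}; accepted: {sorted(table)}")
    return table[key]


def load_quantum_center(path) -> QuantumCenter:
    """Read and validate a quantum-center JSON file.

    Units declared in the file's ``units`` block (Hartree, Debye, nm/bohr
    accepted) are converted to the package's internal eV / e*angstrom /
    angstrom on load.  Raises :class:`SchemaError` naming the offending
    field on any schema violation and :class:`ChargeSumError` when a
    state's ESP charges do not sum to the total charge.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    try:
        model = _QCFileModel.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"{path}: field {loc!r}: {first['msg']}") from exc
    if model.schema_version != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema_version {model.schema_version} unsupported "
            f"(this reader understands {SCHEMA_VERSION})")

    f_e = _unit_factor(ENERGY_FACTORS, model.units.energy, "energy")
    f_d = _unit_factor(DIPOLE_FACTORS, model.units.dipole, "dipole")
    f_l = _unit_factor(LENGTH_FACTORS, model.units.length, "length")

    geom = Geometry(
        elements=tuple(model.geometry.elements),
        coords=np.asarray(model.geometry.coords_angstrom, dtype=float),
        tags={k: tuple(v) for k, v in model.geometry.tags.items()},
    )
    states = tuple(
        ElectronicState(
            index=s.index,
            energy=s.energy * f_e,
            permanent_dipole=np.asarray(s.permanent_dipole) * f_d,
            esp_charges=np.asarray(s.esp_charges, dtype=float),
        )
        for s in model.states
    )
    td = {(t.i, t.j): np.asarray(t.vector, dtype=float) * f_d
          for t in model.transition_dipoles}
    r0 = None
    if model.expansion_center is not None:
        r0 = np.asarray(model.expansion_center, dtype=float) * f_l
    return QuantumCenter(
        name=model.name, redox=model.redox,
        total_charge=model.total_charge, geometry=geom,
        states=states, transition_dipoles=td, r0=r0)


def save_quantum_center(qc: QuantumCenter, path) -> None:
    """Write a quantum center back to the JSON schema in internal units."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": qc.name,
        "redox": qc.redox,
        "total_charge": qc.total_charge,
        "geometry": {
            "elements": list(qc.geometry.elements),
            "coords_angstrom": qc.geometry.coords.tolist(),
            "tags": {k: list(v) for k, v in qc.geometry.tags.items()},
        },
        "states": [
            {"index": s.index, "energy": s.energy,
             "permanent_dipole": s.permanent_dipole.tolist(),
             "esp_charges": s.esp_charges.tolist()}
            for s in qc.states
        ],
        "transition_dipoles": [
            {"i": i, "j": j, "vector": v.tolist()}
            for (i, j), v in sorted(qc.transition_dipoles.items())
        ],
        "units": {"energy": "eV", "dipole": "e*angstrom",
                  "length": "angstrom"},
    }
    if qc.r0 is not None:
        doc["expansion_center"] = qc.r0.tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# gas-phase observables
# ---------------------------------------------------------------------------

def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def vertical_electron_affinity(e_neutral_at_neutral: float,
                               e_anion_at_neutral: float) -> float:
    """VEA = E(neutral) - E(anion), both at the frozen neutral geometry.

    Positive means the anion is vertically bound.  Energies in eV on a
    common reference.
    """
    _require_finite(e_neutral_at_neutral=e_neutral_at_neutral,
                    e_anion_at_neutral=e_anion_at_neutral)
    return e_neutral_at_neutral - e_anion_at_neutral


def adiabatic_electron_affinity(e_neutral_min: float, e_anion_min: float,
                                zpe_neutral: float = 0.0,
                                zpe_anion: float = 0.0) -> float:
    """AEA = (E + ZPE)(neutral minimum) - (E + ZPE)(anion minimum), eV.

    Positive means the relaxed anion is thermodynamically bound.
    """
    _require_finite(e_neutral_min=e_neutral_min, e_anion_min=e_anion_min,
                    zpe_neutral=zpe_neutral, zpe_anion=zpe_anion)
    return (e_neutral_min + zpe_neutral) - (e_anion_min + zpe_anion)


def kabsch_rmsd(a: Geometry, b: Geometry,
                atom_subset: Optional[Sequence[int]] = None) -> float:
    """Minimal unweighted RMSD (angstrom) after optimal superposition.

    Translations are removed by centering; the optimal proper rotation is
    the Kabsch solution (SVD with determinant correction, so reflections
    are excluded).  Symmetric in its arguments.  Requires at least three
    non-collinear atoms on the compared subset.
    """
    if a.elements != b.elements:
        raise GeometryError("geometries have different atom labels/order: "
                            f"{a.elements[:5]}... vs {b.elements[:5]}...")
    idx = (np.arange(a.n_atoms) if atom_subset is None
           else np.asarray(list(atom_subset), dtype=int))
    if idx.size and (idx.min() < 0 or idx.max() >= a.n_atoms):
        raise GeometryError("atom_subset indexes outside the geometry")
    pa = a.coords[idx] - a.coords[idx].mean(axis=0)
    pb = b.coords[idx] - b.coords[idx].mean(axis=0)
    if idx.size < 3:
        raise GeometryError(
            f"superposition needs >= 3 atoms, got {idx.size}")
    # collinearity check: rank of centered coordinates < 2 on either side
    if (np.linalg.matrix_rank(pa, tol=1e-8) < 2
            or np.linalg.matrix_rank(pb, tol=1e-8) < 2):
        raise GeometryError(
            "degenerate (collinear) atom set: the optimal rotation is not "
            "unique")
    h = pb.T @ pa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = pa - pb @ rot
    return float(np.sqrt((diff ** 2).sum() / idx.size))


def charge_localization_fraction(state: ElectronicState,
                                 subset: Sequence[int],
                                 total_charge: float) -> float:
    """Fraction of the species' total charge carried by an atom subset.

    Returns sum(q_k, k in subset) / q_T.  Undefined for a neutral species
    (q_T = 0): raises with instructions to report the raw subset charge.
    """
    if total_charge == 0:
        raise ValueError(
            "charge-localization fraction undefined for total charge 0; "
            "report the raw subset charge sum(state.esp_charges[subset]) "
            "instead")
    idx = np.asarray(list(subset), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= state.esp_charges.size):
        raise ValueError("subset indexes outside the charge array")
    return float(state.esp_charges[idx].sum() / total_charge)
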