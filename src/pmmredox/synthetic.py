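"""Seeded synthetic environment frames.

Real applications of the perturbed matrix method post-process MD
trajectories of an explicit solvent box (for the systems this package
targets: ~900 TIP3P waters or ~500 DMF molecules in a 3.0-4.5 nm cubic box,
optionally with one counterion, sampled every 2 ps over 100 ns).  The
generators here replace that machinery with independent, identically
distributed point-charge configurations that preserve exactly the features
the estimators rely on:

* neutral polar molecules (3-site water-like template by default) whose
  orientations are isotropic or biased toward the quantum center, mimicking
  dielectric alignment around a charged solute;
* an optional monatomic counterion;
* a tunable, seeded Gaussian structure of the reduction energy gap via a
  single calibrated probe charge.

Frames are i.i.d. — there is no molecular dynamics and hence no
autocorrelation.  That is sufficient (and documented) for estimator
validation; block-error scans must degrade gracefully to the plain
standard error on such data.  All randomness flows through one
``numpy.random.default_rng(seed)`` (PCG64), so a seed fixes every stream
bit-for-bit across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import FrameError
from .frames import EnvironmentFrame, FrameStream
from .pmm import build_perturbed_hamiltonian, compute_field, diagonalize
from .qc import Geometry, RedoxSpecies

__all__ = [
    "SolventSpec",
    "EnsembleTarget",
    "water_like_template",
    "generate_frames",
    "generate_gaussian_gap_frames",
    "orientation_bias",
]

FRAME_SPACING_PS = 2.0  # synthetic frames mimic the 2 ps sampling stride


def water_like_template() -> tuple[np.ndarray, np.ndarray]:
    """3-site rigid water-like molecule (TIP3P charges and geometry).

    Site offsets are in the molecular frame with the oxygen at the origin
    and the dipole along +z (toward the hydrogens).  Returns (offsets,
    charges) with charges O = -0.834 e, H = +0.417 e each.
    """
    r_oh = 0.9572
    half = math.radians(104.52 / 2.0)
    offsets = np.array([
        [0.0, 0.0, 0.0],
        [r_oh * math.sin(half), 0.0, r_oh * math.cos(half)],
        [-r_oh * math.sin(half), 0.0, r_oh * math.cos(half)],
    ])
    charges = np.array([-0.834, 0.417, 0.417])
    return offsets, charges


@dataclass(frozen=True)
class SolventSpec:
    """A synthetic solvent box specification.

    ``site_offsets``/``site_charges`` define one rigid molecule in its own
    frame (charges must sum to 0 — solvent molecules are neutral);
    ``bias`` in [0, 1] preferentially points the molecular dipole (+z in
    the template frame) at the quantum center: 0 = isotropic, 1 = fully
    aligned.  ``counterion_charge`` must be an integer; counterions are
    placed like molecules.
    """

    site_offsets: np.ndarray = field(
        default_factory=lambda: water_like_template()[0])
    site_charges: np.ndarray = field(
        default_factory=lambda: water_like_template()[1])
    n_molecules: int = 64
    box_edge: float = 30.0          # angstrom
    counterion_charge: float = 0.0  # e
    n_counterions: int = 0
    bias: float = 0.0
    clash_shell: float = 2.5        # angstrom, exclusion around QC atoms
    min_spacing: float = 2.0        # angstrom, feasibility check only

    def __post_init__(self):
        off = np.asarray(self.site_offsets, dtype=float).reshape(-1, 3)
        q = np.asarray(self.site_charges, dtype=float).ravel()
        if off.shape[0] != q.size:
            raise FrameError("site offsets and charges differ in length")
        if abs(q.sum()) > 1e-12:
            raise FrameError(
                f"solvent molecule must be neutral; site charges sum to "
                f"{q.sum():g} e")
        if self.n_counterions and abs(
                self.counterion_charge - round(self.counterion_charge)) > 1e-9:
            raise FrameError("counterion charge must be an integer")
        if not 0.0 <= self.bias <= 1.0:
            raise FrameError(f"bias must be in [0, 1], got {self.bias}")
        n_part = self.n_molecules + self.n_counterions
        if n_part * self.min_spacing ** 3 > self.box_edge ** 3:
            raise FrameError(
                f"box edge {self.box_edge} angstrom too small for "
                f"{n_part} particles at {self.min_spacing} angstrom "
                "spacing; enlarge the box or reduce the count")
        object.__setattr__(self, "site_offsets", off)
        object.__setattr__(self, "site_charges", q)


@dataclass(frozen=True)
class EnsembleTarget:
    """Requested Gaussian structure of the reduction gap in one ensemble."""

    mean: float   # eV
    sd: float     # eV
    label: str = "oxidized"

    def __post_init__(self):
        if self.sd < 0:
            raise FrameError(f"target sd must be >= 0, got {self.sd}")
        if not (np.isfinite(self.mean) and np.isfinite(self.sd)):
            raise FrameError("target mean/sd must be finite")


def orientation_bias(spec: SolventSpec, bias: float) -> SolventSpec:
    """A copy of ``spec`` with the dipole-orientation bias set.

    Bias > 0 points solvent dipoles preferentially at the quantum center,
    the qualitative mechanism by which a polar solvent stabilizes the more
    negative redox form.
    """
    return replace(spec, bias=bias)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _uniform_rotation_about(direction: np.ndarray, phi: float) -> np.ndarray:
    """Rotation matrix mapping +z to ``direction`` after an azimuth phi
    about +z.  With ``direction`` uniform on the sphere and phi uniform on
    [0, 2pi) the composite is Haar-uniform on SO(3)."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        align = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        align = np.eye(3) + vx + vx @ vx / (1.0 + c)
    cp, sp = math.cos(phi), math.sin(phi)
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return align @ rz


def _place_centers(rng: np.random.Generator, n: int, box: float,
                   qc_coords: np.ndarray, clash: float) -> np.ndarray:
    """Uniform positions in the box outside a clash shell around QC atoms."""
    centers = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 1000 * max(n, 1)
    while placed < n:
        if attempts >= max_attempts:
            raise FrameError(
                f"could not place {n} particles outside a {clash} angstrom "
                f"shell in a {box} angstrom box; reduce the count or "
                "enlarge the box")
        c = rng.uniform(0.0, box, size=3)
        attempts += 1
        if qc_coords.size and np.min(
                np.linalg.norm(qc_coords - c, axis=1)) < clash:
            continue
        centers[placed] = c
        placed += 1
    return centers


def generate_frames(spec: SolventSpec, qc_geometry: Geometry,
                    n_frames: int, seed: int) -> FrameStream:
    """I.i.d. solvent configurations around a fixed quantum center.

    Each frame places ``spec.n_molecules`` rigid molecules uniformly in the
    box outside the clash shell around the QC atoms, with orientations
    Haar-uniform (bias 0) or dipole-biased toward the QC center; counterions
    are placed the same way.  Deterministic for a given seed.
    """
    if n_frames < 1:
        raise FrameError(f"n_frames must be >= 1, got {n_frames}")
    rng = np.random.default_rng(seed)
    qc_center = qc_geometry.geometric_center()
    frames = []
    box = np.full(3, spec.box_edge)
    for i in range(n_frames):
        centers = _place_centers(rng, spec.n_molecules, spec.box_edge,
                                 qc_geometry.coords, spec.clash_shell)
        pos_blocks = []
        q_blocks = []
        for c in centers:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if spec.bias > 0.0:
                toward = qc_center - c
                nrm = np.linalg.norm(toward)
                if nrm > 1e-12:
                    d = (1.0 - spec.bias) * v + spec.bias * toward / nrm
                    nd = np.linalg.norm(d)
                    v = d / nd if nd > 1e-12 else v
            rot = _uniform_rotation_about(v, rng.uniform(0.0, 2.0 * math.pi))
            pos_blocks.append(c + spec.site_offsets @ rot.T)
            q_blocks.append(spec.site_charges)
        if spec.n_counterions:
            ions = _place_centers(rng, spec.n_counterions, spec.box_edge,
                                  qc_geometry.coords, spec.clash_shell)
            pos_blocks.append(ions)
            q_blocks.append(np.full(spec.n_counterions,
                                    spec.counterion_charge))
        positions = (np.vstack(pos_blocks) if pos_blocks
                     else np.empty((0, 3)))
        charges = np.concatenate(q_blocks) if q_blocks else np.empty(0)
        frames.append(EnvironmentFrame(
            positions=positions, charges=charges, box=box,
            time_ps=FRAME_SPACING_PS * i, index=i))
    return FrameStream(frames=tuple(frames), metadata={
        "source": f"synthetic(seed={seed})",
        "qc_mask_indices": (),
        "link_atom_policy": "none",
        "generator": {
            "n_molecules": spec.n_molecules,
            "box_edge": spec.box_edge,
            "bias": spec.bias,
            "counterion_charge": spec.counterion_charge,
            "n_counterions": spec.n_counterions,
            "seed": int(seed),
        },
    })


# ---------------------------------------------------------------------------
# calibrated Gaussian-gap streams
# ---------------------------------------------------------------------------

_PROBE_DISTANCE = 150.0   # angstrom from the expansion center
_PROBE_BOX = 2000.0       # angstrom; large enough that images never matter


def _gap_for_probe_charge(species: RedoxSpecies, q: float,
                          probe_pos: np.ndarray, box: float) -> float:
    frame = EnvironmentFrame(positions=probe_pos[None, :],
                             charges=np.array([q]),
                             box=np.full(3, box), time_ps=0.0, index=0)
    field = compute_field(frame, species.oxidized.geometry,
                          species.oxidized.expansion_center(),
                          pbc_mode="none", per_atom_potentials=False)
    u = {}
    for label, qc in (("ox", species.oxidized), ("red", species.reduced)):
        h = build_perturbed_hamiltonian(qc, field, mode="dipole")
        u[label] = diagonalize(h).ground_energy
    return u["red"] - u["ox"]


def generate_gaussian_gap_frames(species: RedoxSpecies,
                                 target_ox: EnsembleTarget,
                                 target_red: EnsembleTarget,
                                 n_frames: int, seed: int
                                 ) -> tuple[FrameStream, FrameStream]:
    """Two frame streams whose reduction-gap series (through the PMM core
    in dipole mode) have the requested Gaussian mean/sd per ensemble.

    Each frame holds a single probe charge at a fixed distant position; the
    map from probe charge to gap is measured on a 3-point stencil, checked
    for linearity, and inverted, so Gaussian charges give a Gaussian gap.
    Calibration metadata (intercept, slope, drawn-charge moments) is
    recorded in each stream.  Raises when the redox couple offers no
    electrostatic handle (identical charge and dipoles => zero slope).
    """
    if n_frames < 1:
        raise FrameError(f"n_frames must be >= 1, got {n_frames}")
    r0 = species.oxidized.expansion_center()
    probe_pos = r0 + np.array([_PROBE_DISTANCE, 0.0, 0.0])
    g = {q: _gap_for_probe_charge(species, q, probe_pos, _PROBE_BOX)
         for q in (-1.0, 0.0, 1.0)}
    intercept = g[0.0]
    slope = 0.5 * (g[1.0] - g[-1.0])
    curvature = g[1.0] + g[-1.0] - 2.0 * g[0.0]
    if abs(slope) < 1e-9:
        raise FrameError(
            "gap target unreachable: the redox couple has no net charge or "
            "dipole difference for a probe charge to couple to")
    if abs(curvature) > 0.02 * abs(slope):
        raise FrameError(
            "probe response is not linear enough for Gaussian calibration; "
            "check the quantum-center state energies for near-degeneracies")

    rng = np.random.default_rng(seed)
    streams = []
    for target in (target_ox, target_red):
        q_mean = (target.mean - intercept) / slope
        q_sd = target.sd / abs(slope)
        charges = (np.full(n_frames, q_mean) if target.sd == 0.0
                   else rng.normal(q_mean, q_sd, size=n_frames))
        frames = tuple(
            EnvironmentFrame(positions=probe_pos[None, :],
                             charges=np.array([qi]),
                             box=np.full(3, _PROBE_BOX),
                             time_ps=FRAME_SPACING_PS * i, index=i)
            for i, qi in enumerate(charges))
        streams.append(FrameStream(frames=frames, metadata={
            "source": f"synthetic-gaussian-gap(seed={seed})",
            "qc_mask_indices": (),
            "link_atom_policy": "none",
            "calibration": {
                "ensemble": target.label,
                "intercept_ev": float(intercept),
                "slope_ev_per_e": float(slope),
                "curvature_ev": float(curvature),
                "probe_distance_angstrom": _PROBE_DISTANCE,
                "charge_mean_e": float(q_mean),
                "charge_sd_e": float(q_sd),
                "target_mean_ev": target.mean,
                "target_sd_ev": target.sd,
            },
        }))
    return streams[0], streams[1]
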