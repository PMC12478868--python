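"""Environment frames: perturbing point charges around the quantum center.

The perturbation source in the PMM scheme is the instantaneous configuration
of the classical environment — every atom outside the quantum center,
represented as a fixed point charge at its frame coordinates.  Coordinate
trajectory formats carry no charges, so charges are supplied as a sidecar
(per-atom list, name->charge mapping, or a JSON/CSV file); parsing
force-field topologies is deliberately out of scope.

Supported trajectory formats: multi-frame GRO (hand parser, nm -> angstrom),
multi-model PDB (MDAnalysis), and XTC through MDAnalysis when a topology
file is given.  Only orthorhombic boxes are accepted.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import FrameError, UnsupportedFormatError

__all__ = [
    "EnvironmentFrame",
    "FrameStream",
    "LinkAtomPolicy",
    "read_frames",
    "apply_link_atom_mask",
    "frames_to_csv",
    "frames_from_csv",
    "frames_to_pdb",
]


@dataclass(frozen=True)
class EnvironmentFrame:
    """One configuration of perturbing point charges.

    positions in angstrom, charges in e, orthorhombic box edge lengths in
    angstrom, time in ps.
    """

    positions: np.ndarray   # (n, 3)
    charges: np.ndarray     # (n,)
    box: np.ndarray         # (3,) edge lengths
    time_ps: float
    index: int

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        q = np.asarray(self.charges, dtype=float).ravel()
        box = np.asarray(self.box, dtype=float).reshape(3)
        if pos.shape[0] != q.size:
            raise FrameError(
                f"frame {self.index}: {pos.shape[0]} positions but "
                f"{q.size} charges")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(q))
                and np.all(np.isfinite(box))):
            raise FrameError(f"frame {self.index}: non-finite values")
        if np.any(box <= 0):
            raise FrameError(f"frame {self.index}: box edges must be > 0, "
                             f"got {box}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "box", box)

    @property
    def n_atoms(self) -> int:
        return self.charges.size

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass(frozen=True)
class FrameStream:
    """Ordered sequence of environment frames plus provenance metadata.

    Metadata always records the source (path or generator seed), the QC
    atom indices that were masked out, and the link-atom policy applied
    (empty entries are recorded explicitly, never omitted).
    """

    frames: tuple[EnvironmentFrame, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        frames = tuple(self.frames)
        times = [f.time_ps for f in frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise FrameError("frame times must be strictly increasing")
        meta = dict(self.metadata)
        meta.setdefault("source", None)
        meta.setdefault("qc_mask_indices", ())
        meta.setdefault("link_atom_policy", "none")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "metadata", meta)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> EnvironmentFrame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# charge sidecar
# ---------------------------------------------------------------------------

ChargeSource = Union[str, Path, Sequence[float], Mapping[str, float]]


def _load_charge_source(source: ChargeSource):
    """Normalize a charge sidecar into (per_atom_list | None, name_map | None)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() == ".json":
            doc = json.loads(path.read_text())
            if "charges" in doc:
                return [float(x) for x in doc["charges"]], None
            if "name_to_charge" in doc:
                return None, {str(k): float(v)
                              for k, v in doc["name_to_charge"].items()}
            raise FrameError(
                f"{path}: charge JSON needs a 'charges' list or a "
                "'name_to_charge' mapping")
        if path.suffix.lower() in (".csv", ".tsv"):
            delim = "\t" if path.suffix.lower() == ".tsv" else ","
            with open(path, newline="") as fh:
                rows = list(csv.DictReader(fh, delimiter=delim))
            if rows and "name" in rows[0] and "charge" in rows[0]:
                return None, {r["name"].strip(): float(r["charge"])
                              for r in rows}
            if rows and "charge" in rows[0]:
                return [float(r["charge"]) for r in rows], None
            raise FrameError(
                f"{path}: charge CSV needs columns (name, charge) or (charge)")
        raise FrameError(f"unsupported charge sidecar format: {path.suffix}")
    if isinstance(source, Mapping):
        return None, {str(k): float(v) for k, v in source.items()}
    return [float(x) for x in source], None


def _resolve_charges(source: ChargeSource, atom_names: Sequence[str],
                     n_atoms: int) -> np.ndarray:
    per_atom, name_map = _load_charge_source(source)
    if per_atom is not None:
        if len(per_atom) != n_atoms:
            raise FrameError(
                f"charge list has {len(per_atom)} entries but the "
                f"trajectory has {n_atoms} atoms")
        return np.asarray(per_atom, dtype=float)
    missing = sorted({n for n in atom_names if n not in name_map})
    if missing:
        raise FrameError(
            f"no charge for atom names {missing[:8]} in the name->charge "
            "mapping")
    return np.array([name_map[n] for n in atom_names], dtype=float)


# ---------------------------------------------------------------------------
# trajectory readers
# ---------------------------------------------------------------------------

_GRO_TIME_RE = re.compile(r"t\s*=\s*([0-9.eE+-]+)")


def _read_gro_frames(path: Path):
    """Parse a (possibly multi-frame) GRO file.

    Fixed-column format; coordinates in nm are converted to angstrom.
    Yields (atom_names, positions_angstrom, box_angstrom, time_ps_or_None).
    """
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        m = _GRO_TIME_RE.search(title)
        time_ps = float(m.group(1)) if m else None
        natoms = int(lines[i + 1].strip())
        names, pos = [], np.empty((natoms, 3))
        for k in range(natoms):
            ln = lines[i + 2 + k]
            names.append(ln[10:15].strip())
            pos[k] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        box_fields = [float(x) for x in lines[i + 2 + natoms].split()]
        if len(box_fields) >= 9 and any(abs(v) > 1e-12 for v in box_fields[3:]):
            raise FrameError(
                "triclinic box in GRO file; only orthorhombic boxes are "
                "supported")
        box = np.array(box_fields[:3])
        yield names, pos * 10.0, box * 10.0, time_ps
        i += 3 + natoms


def _read_mdanalysis_frames(trajectory: Path, topology: Optional[Path]):
    """PDB multi-model / XTC via MDAnalysis. Positions already in angstrom."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        # PDB models carry no time step; we fall back to frame indices
        warnings.filterwarnings("ignore", message=".*no dt information.*")
        if topology is not None:
            u = mda.Universe(str(topology), str(trajectory))
        else:
            u = mda.Universe(str(trajectory))
        names = [a.name for a in u.atoms]
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or np.all(dims[:3] == 0):
                raise FrameError(
                    f"frame {ts.frame}: no box information in trajectory")
            if not np.allclose(dims[3:6], 90.0, atol=1e-3):
                raise FrameError(
                    f"frame {ts.frame}: non-orthorhombic box (angles "
                    f"{dims[3:6]}); only orthorhombic boxes are supported")
            t = float(ts.time) if np.isfinite(ts.time) else None
            yield (names, ts.positions.astype(float).copy(),
                   dims[:3].astype(float), t)


def read_frames(trajectory, topology_charges: ChargeSource,
                qc_selection: Sequence[int],
                stride_ps: Optional[float] = None,
                topology=None,
                exclude_indices: Sequence[int] = ()) -> FrameStream:
    """Read environment frames from a trajectory file.

    Parameters
    ----------
    trajectory
        Multi-frame GRO, multi-model PDB, or XTC (the latter requires
        ``topology``, any MDAnalysis-readable structure file).
    topology_charges
        Per-atom charge sidecar covering every atom in the trajectory
        (QC atoms included): an explicit list, a name->charge mapping, or
        a JSON/CSV file in the documented layouts.
    qc_selection
        Indices (into the full trajectory atom list) of quantum-center
        atoms; these are removed from every frame — the QC must never
        perturb itself.
    stride_ps
        Keep frames evenly spaced at (at least) this interval; ``None``
        keeps every frame.
    exclude_indices
        Additional full-trajectory atom indices to drop from the
        perturbing set (e.g. a counterion, which is included by default).
    """
    path = Path(trajectory)
    suffix = path.suffix.lower()
    if suffix == ".gro":
        raw_iter = _read_gro_frames(path)
    elif suffix in (".pdb", ".xtc", ".trr"):
        if suffix in (".xtc", ".trr") and topology is None:
            raise FrameError(
                f"{suffix} trajectories carry no atom records; pass "
                "topology=<structure file>")
        raw_iter = _read_mdanalysis_frames(path, topology)
    else:
        raise UnsupportedFormatError(
            f"unsupported trajectory format {suffix!r}; supported: "
            ".gro (multi-frame), .pdb (multi-model), .xtc/.trr (with "
            "topology)")

    qc_idx = np.asarray(sorted(set(int(i) for i in qc_selection)), dtype=int)
    drop = set(qc_idx.tolist()) | {int(i) for i in exclude_indices}

    frames: list[EnvironmentFrame] = []
    charges_full: Optional[np.ndarray] = None
    keep: Optional[np.ndarray] = None
    next_keep_time = None
    out_index = 0
    for raw_i, (names, pos, box, t) in enumerate(raw_iter):
        if charges_full is None:
            charges_full = _resolve_charges(topology_charges, names, len(names))
            bad = [i for i in drop if i < 0 or i >= len(names)]
            if bad:
                raise FrameError(f"QC/exclude indices {bad} outside the "
                                 f"{len(names)}-atom trajectory")
            keep = np.array([i for i in range(len(names)) if i not in drop],
                            dtype=int)
        elif len(names) != charges_full.size:
            raise FrameError(
                f"frame {raw_i}: atom count changed from "
                f"{charges_full.size} to {len(names)}")
        time_ps = float(t) if t is not None else float(raw_i)
        if stride_ps is not None:
            if next_keep_time is None:
                next_keep_time = time_ps
            if time_ps + 1e-9 < next_keep_time:
                continue
            next_keep_time += stride_ps
        frames.append(EnvironmentFrame(
            positions=pos[keep], charges=charges_full[keep], box=box,
            time_ps=time_ps, index=out_index))
        out_index += 1
    if not frames:
        raise FrameError(f"{path}: no frames read")
    return FrameStream(frames=tuple(frames), metadata={
        "source": str(path),
        "qc_mask_indices": tuple(qc_idx.tolist()),
        "excluded_indices": tuple(sorted(int(i) for i in exclude_indices)),
        "stride_ps": stride_ps,
        "link_atom_policy": "none",
    })


# ---------------------------------------------------------------------------
# link-atom boundary policies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkAtomPolicy:
    """Treatment of environment atoms at a covalent QC boundary.

    When the quantum center is capped by a link hydrogen (present in the QM
    calculation, absent from the environment), the environment atom the cap
    replaces sits unphysically close to the QC.  ``mode='exclude'`` (the
    default treatment) removes the listed atoms' charges from the
    perturbing set; ``mode='redistribute'`` zeroes each listed atom and
    spreads its charge equally over its ``n_neighbors`` nearest surviving
    environment atoms (total environment charge is conserved exactly);
    ``mode='none'`` leaves the stream unchanged.

    ``atoms`` are indices into the environment-atom ordering of the stream
    (i.e. after QC masking).
    """

    mode: str = "exclude"
    atoms: tuple[int, ...] = ()
    n_neighbors: int = 3

    def __post_init__(self):
        if self.mode not in ("none", "exclude", "redistribute"):
            raise FrameError(f"unknown link-atom policy mode {self.mode!r}")
        object.__setattr__(self, "atoms",
                           tuple(int(i) for i in self.atoms))


def apply_link_atom_mask(stream: FrameStream,
                         policy: LinkAtomPolicy) -> FrameStream:
    """Apply a link-atom boundary policy to every frame of a stream."""
    if policy.mode == "none" or not policy.atoms:
        meta = dict(stream.metadata)
        meta["link_atom_policy"] = "none"
        return FrameStream(frames=stream.frames, metadata=meta)

    n = stream.frames[0].n_atoms if stream.frames else 0
    bad = [i for i in policy.atoms if i < 0 or i >= n]
    if bad:
        raise FrameError(
            f"link-atom policy references absent environment atoms {bad} "
            f"(stream has {n})")

    new_frames = []
    for fr in stream.frames:
        if policy.mode == "exclude":
            keep = np.setdiff1d(np.arange(fr.n_atoms),
                                np.asarray(policy.atoms))
            new_frames.append(replace(
                fr, positions=fr.positions[keep], charges=fr.charges[keep]))
        else:  # redistribute
            q = fr.charges.copy()
            others = np.setdiff1d(np.arange(fr.n_atoms),
                                  np.asarray(policy.atoms))
            if others.size < policy.n_neighbors:
                raise FrameError(
                    "not enough environment atoms to redistribute onto")
            for i in policy.atoms:
                d = np.linalg.norm(fr.positions[others] - fr.positions[i],
                                   axis=1)
                nearest = others[np.argsort(d)[:policy.n_neighbors]]
                q[nearest] += q[i] / policy.n_neighbors
                q[i] = 0.0
            new_frames.append(replace(fr, charges=q))
    meta = dict(stream.metadata)
    meta["link_atom_policy"] = (
        f"{policy.mode}(atoms={policy.atoms}, "
        f"n_neighbors={policy.n_neighbors})")
    return FrameStream(frames=tuple(new_frames), metadata=meta)


# ---------------------------------------------------------------------------
# internal serialization (compact CSV) and PDB export
# ---------------------------------------------------------------------------

def frames_to_csv(stream: FrameStream, path) -> None:
    """Write a stream to a flat CSV (one row per atom per frame)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time_ps", "box_x", "box_y", "box_z",
                    "x", "y", "z", "charge"])
        for fr in stream:
            for p, q in zip(fr.positions, fr.charges):
                w.writerow([fr.index, repr(fr.time_ps),
                            repr(float(fr.box[0])), repr(float(fr.box[1])),
                            repr(float(fr.box[2])),
                            repr(float(p[0])), repr(float(p[1])),
                            repr(float(p[2])), repr(float(q))])


def frames_from_csv(path) -> FrameStream:
    """Read a stream written by :func:`frames_to_csv`."""
    by_frame: dict[int, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = by_frame.setdefault(int(row["frame"]), {
                "time": float(row["time_ps"]),
                "box": (float(row["box_x"]), float(row["box_y"]),
                        float(row["box_z"])),
                "pos": [], "q": []})
            rec["pos"].append((float(row["x"]), float(row["y"]),
                               float(row["z"])))
            rec["q"].append(float(row["charge"]))
    frames = tuple(
        EnvironmentFrame(positions=np.array(rec["pos"]),
                         charges=np.array(rec["q"]),
                         box=np.array(rec["box"]),
                         time_ps=rec["time"], index=i)
        for i, rec in sorted(by_frame.items()))
    return FrameStream(frames=frames, metadata={"source": str(path)})


def frames_to_pdb(stream: FrameStream, path,
                  element: str = "X") -> None:
    """Write a stream as a multi-model PDB for visual inspection only.

    Charges are stored in the B-factor column (lossy: 2 decimals).
    """
    with open(path, "w") as fh:
        for fr in stream:
            fh.write(f"MODEL     {fr.index + 1:4d}\n")
            fh.write(f"CRYST1{fr.box[0]:9.3f}{fr.box[1]:9.3f}"
                     f"{fr.box[2]:9.3f}  90.00  90.00  90.00 P 1\n")
            for k, (p, q) in enumerate(zip(fr.positions, fr.charges), 1):
                fh.write(
                    f"ATOM  {k % 100000:5d} {element:<4s}ENV A{k % 10000:4d}"
                    f"    {p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}"
                    f"{q:6.2f}          {element:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
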