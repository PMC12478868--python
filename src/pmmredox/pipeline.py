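"""Configuration-driven workflows tying the pipeline together.

Two entry points mirror how the package is used:

* :func:`run_redox_pipeline` — frames -> fields -> perturbed energies ->
  gaps -> free energy / condensed-phase AEA / reduction potential, from a
  validated :class:`RunConfig`.  Writes a results JSON, per-ensemble gap
  CSVs, a convergence CSV, and a manifest recording every default that was
  applied (enough to reproduce the run bit-for-bit).
* :func:`gas_phase_report` — the vacuum observables (VEA, AEA with optional
  zero-point correction, anion-vs-neutral RMSD, charge localization) as a
  pandas DataFrame.

These functions are the package's "front end": there is no command-line
interface, scripts in ``examples/`` show the same flows narratively.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .constants import SHE_VOLTS
from .errors import SchemaError
from .frames import FrameStream, read_frames
from .pmm import perturbed_energy_trajectory
from .qc import (RedoxSpecies, QuantumCenter, charge_localization_fraction,
                 kabsch_rmsd, load_quantum_center,
                 adiabatic_electron_affinity, vertical_electron_affinity)
from .synthetic import SolventSpec, generate_frames, water_like_template
from .thermo import (GapSamples, ThermoConstants, convergence_curve,
                     free_energy_eq1, free_energy_linear_response,
                     solution_aea)

__all__ = ["RunConfig", "SyntheticConfig", "TrajectoryConfig",
           "run_redox_pipeline", "gas_phase_report"]


class SyntheticConfig(BaseModel):
    """Synthetic-environment block of a run configuration.

    One stream is generated per ensemble; the reduced ensemble may carry a
    counterion (as the study's anion simulations did) and a stronger
    dipole-orientation bias, emulating solvent polarization around the
    anion.
    """

    model_config = ConfigDict(extra="forbid")
    n_frames: int = Field(default=200, ge=1)
    n_molecules: int = Field(default=64, ge=0)
    box_edge_angstrom: float = Field(default=30.0, gt=0)
    bias_oxidized: float = Field(default=0.0, ge=0, le=1)
    bias_reduced: float = Field(default=0.6, ge=0, le=1)
    counterion_charge_reduced: float = 1.0
    clash_shell_angstrom: float = Field(default=2.5, gt=0)


class TrajectoryConfig(BaseModel):
    """Trajectory-input block: one file per ensemble plus a charge sidecar."""

    model_config = ConfigDict(extra="forbid")
    trajectory_oxidized: str
    trajectory_reduced: str
    charges: str
    qc_selection: list[int]
    topology: Optional[str] = None
    stride_ps: Optional[float] = Field(default=2.0, gt=0)


class RunConfig(BaseModel):
    """Validated configuration of a condensed-phase redox run.

    Exactly one of ``synthetic`` / ``trajectories`` supplies the
    environment.  Unit-bearing keys carry the unit in their name.
    """

    model_config = ConfigDict(extra="forbid")
    qc_oxidized_path: str
    qc_reduced_path: str
    temperature_K: float = Field(default=300.0, gt=0)
    expansion_mode: str = "esp_diagonal"
    pbc_mode: str = "minimum_image"
    estimator: str = "eq1"
    she_volts: float = SHE_VOLTS
    seed: int = 0
    n_convergence_points: int = Field(default=10, ge=2)
    output_dir: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    trajectories: Optional[TrajectoryConfig] = None

    @model_validator(mode="after")
    def _check(self):
        if (self.synthetic is None) == (self.trajectories is None):
            raise ValueError(
                "exactly one of 'synthetic' or 'trajectories' must be set")
        if self.expansion_mode not in ("dipole", "esp_diagonal"):
            raise ValueError(f"expansion_mode {self.expansion_mode!r} "
                             "not in {'dipole', 'esp_diagonal'}")
        if self.pbc_mode not in ("none", "minimum_image"):
            raise ValueError(f"pbc_mode {self.pbc_mode!r} "
                             "not in {'none', 'minimum_image'}")
        if self.estimator not in ("eq1", "lr"):
            raise ValueError(f"estimator {self.estimator!r} "
                             "not in {'eq1', 'lr'}")
        for p in (self.qc_oxidized_path, self.qc_reduced_path):
            if not Path(p).is_file():
                raise ValueError(f"quantum-center file not found: {p}")
        if self.trajectories is not None:
            for p in (self.trajectories.trajectory_oxidized,
                      self.trajectories.trajectory_reduced):
                if not Path(p).is_file():
                    raise ValueError(f"trajectory file not found: {p}")
        return self


def _synthetic_streams(cfg: RunConfig, species: RedoxSpecies
                       ) -> tuple[FrameStream, FrameStream, np.ndarray]:
    from dataclasses import replace

    syn = cfg.synthetic
    offsets, charges = water_like_template()
    base = SolventSpec(site_offsets=offsets, site_charges=charges,
                       n_molecules=syn.n_molecules,
                       box_edge=syn.box_edge_angstrom,
                       clash_shell=syn.clash_shell_angstrom)
    spec_ox = replace(base, bias=syn.bias_oxidized)
    n_ions = 1 if syn.counterion_charge_reduced else 0
    spec_red = replace(base, bias=syn.bias_reduced,
                       counterion_charge=syn.counterion_charge_reduced,
                       n_counterions=n_ions)
    # center the quantum center in the box so clash shells make sense
    geom = species.oxidized.geometry
    shift = np.full(3, syn.box_edge_angstrom / 2.0) - geom.geometric_center()
    centered = type(geom)(elements=geom.elements,
                          coords=geom.coords + shift, tags=geom.tags)
    stream_ox = generate_frames(spec_ox, centered, syn.n_frames, cfg.seed)
    stream_red = generate_frames(spec_red, centered, syn.n_frames,
                                 cfg.seed + 1)
    return stream_ox, stream_red, shift


def _trajectory_streams(cfg: RunConfig) -> tuple[FrameStream, FrameStream]:
    tr = cfg.trajectories
    kwargs = dict(topology_charges=tr.charges, qc_selection=tr.qc_selection,
                  stride_ps=tr.stride_ps, topology=tr.topology)
    return (read_frames(tr.trajectory_oxidized, **kwargs),
            read_frames(tr.trajectory_reduced, **kwargs))


def run_redox_pipeline(config: RunConfig) -> dict:
    """Execute the full condensed-phase pipeline for one redox couple.

    Returns a result dictionary (also written to ``output_dir`` when set)
    with the free energy from the requested estimator and from linear
    response, the condensed-phase AEA, reduction potentials vs SHE, and a
    convergence curve.  Both estimators are always reported — they answer
    different questions and are never silently equated.
    """
    ox_qc = load_quantum_center(config.qc_oxidized_path)
    red_qc = load_quantum_center(config.qc_reduced_path)
    species = RedoxSpecies(oxidized=ox_qc, reduced=red_qc)

    shift = np.zeros(3)
    if config.synthetic is not None:
        stream_ox, stream_red, shift = _synthetic_streams(config, species)
        if not np.allclose(shift, 0.0):
            geom = species.oxidized.geometry
            centered = type(geom)(elements=geom.elements,
                                  coords=geom.coords + shift, tags=geom.tags)
            r0 = (None if ox_qc.r0 is None else ox_qc.r0 + shift)
            species = RedoxSpecies(
                oxidized=QuantumCenter(
                    name=ox_qc.name, redox=ox_qc.redox,
                    total_charge=ox_qc.total_charge, geometry=centered,
                    states=ox_qc.states,
                    transition_dipoles=ox_qc.transition_dipoles, r0=r0),
                reduced=QuantumCenter(
                    name=red_qc.name, redox=red_qc.redox,
                    total_charge=red_qc.total_charge, geometry=centered,
                    states=red_qc.states,
                    transition_dipoles=red_qc.transition_dipoles, r0=r0),
                gas_reference=species.gas_reference)
    else:
        stream_ox, stream_red = _trajectory_streams(config)

    traj_ox = perturbed_energy_trajectory(
        species, stream_ox, mode=config.expansion_mode,
        pbc_mode=config.pbc_mode)
    traj_red = perturbed_energy_trajectory(
        species, stream_red, mode=config.expansion_mode,
        pbc_mode=config.pbc_mode)

    constants = ThermoConstants(e_she=config.she_volts)
    gaps_ox = GapSamples(label="oxidized", gaps=traj_ox.gap,
                         temperature=config.temperature_K,
                         times_ps=traj_ox.times_ps)
    gaps_red = GapSamples(label="reduced", gaps=traj_red.gap,
                          temperature=config.temperature_K,
                          times_ps=traj_red.times_ps)

    res_eq1 = free_energy_eq1(gaps_ox, gaps_red, constants)
    res_lr = free_energy_linear_response(gaps_ox, gaps_red, constants)
    aea = solution_aea(gaps_ox, gaps_red)
    chosen = res_eq1 if config.estimator == "eq1" else res_lr
    curve = convergence_curve(gaps_ox, gaps_red,
                              estimator=config.estimator,
                              n_points=config.n_convergence_points,
                              constants=constants)

    results = {
        "species": ox_qc.name,
        "estimator": config.estimator,
        "expansion_mode": config.expansion_mode,
        "pbc_mode": config.pbc_mode,
        "temperature_K": config.temperature_K,
        "gap_sign_convention": "delta_u = u_red - u_ox",
        "delta_a_ev": chosen.delta_a,
        "delta_a_std_err_ev": chosen.std_err,
        "delta_a_eq1_ev": res_eq1.delta_a,
        "delta_a_eq1_std_err_ev": res_eq1.std_err,
        "delta_a_linear_response_ev": res_lr.delta_a,
        "delta_a_linear_response_std_err_ev": res_lr.std_err,
        "aea_solution_ev": aea.aea,
        "aea_solution_std_err_ev": aea.std_err,
        "e_abs_v": chosen.e_abs,
        "e_vs_she_v": chosen.e_vs_she,
        "she_volts": config.she_volts,
        "n_frames_ox": gaps_ox.n,
        "n_frames_red": gaps_red.n,
        "convergence": [{"time_ps": t, "delta_a_ev": a} for t, a in curve],
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(results, indent=1))
        for name, traj in (("oxidized", traj_ox), ("reduced", traj_red)):
            pd.DataFrame({
                "frame": np.arange(traj.times_ps.size),
                "time_ps": traj.times_ps,
                "u_ox_ev": traj.u_ox,
                "u_red_ev": traj.u_red,
                "gap_ev": traj.gap,
            }).to_csv(out / f"gaps_{name}.csv", index=False)
        pd.DataFrame(curve, columns=["time_ps", "delta_a_ev"]).to_csv(
            out / "convergence.csv", index=False)
        cfg_doc = config.model_dump()
        manifest = {
            "package": "pmmredox",
            "version": __version__,
            "config": cfg_doc,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_doc, sort_keys=True).encode()).hexdigest(),
            "qc_center_shift_angstrom": shift.tolist(),
            "frame_metadata": {
                "oxidized": _jsonable(stream_ox.metadata),
                "reduced": _jsonable(stream_red.metadata),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def gas_phase_report(oxidized: QuantumCenter, reduced: QuantumCenter,
                     e_neutral_min: float, e_anion_min: float,
                     e_anion_at_neutral: Optional[float] = None,
                     zpe_neutral: float = 0.0, zpe_anion: float = 0.0,
                     subset_tag: str = "base") -> pd.DataFrame:
    """One-row gas-phase observable table for a redox couple.

    Energies are the total electronic energies (eV, common reference) of
    each form at its own minimum, plus optionally the anion energy at the
    frozen neutral geometry for the vertical affinity.  Charge localization
    is reported for the reduced ground state on the ``subset_tag`` moiety
    when the geometry carries that tag, otherwise as missing (not an
    error).
    """
    if oxidized.geometry.elements != reduced.geometry.elements:
        raise SchemaError("gas-phase report needs a shared atom list")
    row = {
        "species": oxidized.name,
        "aea_ev": adiabatic_electron_affinity(e_neutral_min, e_anion_min),
        "aea_zpe_ev": adiabatic_electron_affinity(
            e_neutral_min, e_anion_min, zpe_neutral, zpe_anion),
        "vea_ev": (np.nan if e_anion_at_neutral is None else
                   vertical_electron_affinity(e_neutral_min,
                                              e_anion_at_neutral)),
        "rmsd_anion_vs_neutral_angstrom": kabsch_rmsd(oxidized.geometry,
                                                      reduced.geometry),
    }
    tags = reduced.geometry.tags
    if subset_tag in tags and reduced.total_charge != 0:
        row["charge_fraction_" + subset_tag] = charge_localization_fraction(
            reduced.states[0], tags[subset_tag], reduced.total_charge)
    else:
        row["charge_fraction_" + subset_tag] = np.nan
    return pd.DataFrame([row])
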