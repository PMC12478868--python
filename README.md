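# pmmredox

Condensed-phase redox thermodynamics of nucleic-acid building blocks by
perturbed-matrix-method (PMM) post-processing of point-charge environment
ensembles.

## The problem

Low-energy electrons are captured by nucleobases, and whether the resulting
radical anion is stable depends strongly on the environment: a base that
barely binds an electron in vacuum becomes a good electron acceptor in water.
Quantifying that requires condensed-phase adiabatic electron affinities
(AEA) and one-electron reduction potentials, which are hard to measure and
hard to compute with static implicit-solvent models.

`pmmredox` implements the QM/MM post-processing route for this problem: the
solute (the *quantum center*, QC) is described by a handful of vacuum
electronic states computed once with an electronic-structure code; each
environment configuration — thousands of solvent point charges from an MD
trajectory or from this package's synthetic generator — perturbs the QC
Hamiltonian electrostatically. Diagonalizing the perturbed matrix per frame
yields ground-state energies of the oxidized (neutral) and reduced (radical
anion) forms, whose difference is the per-frame reduction energy gap
ΔU_e = U_red − U_ox. The package is aimed at computational chemists who
already have vacuum QM properties and MD frames and need the statistical
mechanics done correctly — plus a fully synthetic path for method validation
without any MD or QM engine.

## The model

For each frame the perturbed electronic Hamiltonian in the basis of N
unperturbed states is built in one of two documented expansion modes:

- **dipole**: H̃_ll′ = ε_l δ_ll′ + q_T Φ(r₀) δ_ll′ − **E**(r₀)·**μ**_ll′
- **esp_diagonal**: diagonal ε_l + Σ_k q_k^(l) Φ(r_k) (per-state ESP
  charges against per-atom potentials), with the same dipole off-diagonals.

Φ and **E** are the Coulomb potential and field of the environment charges
(k_e = 14.399645 eV·Å·e⁻², minimum-image convention, no cutoff). The
Helmholtz free energy of reduction comes from the two-sided exponential
(Zwanzig-type) estimator over the two ensembles,

    ΔA = (k_B T / 2) [ ln⟨e^{βΔU_e}⟩_red − ln⟨e^{−βΔU_e}⟩_ox ],

with the linear-response alternative ΔA_LR = (⟨ΔU⟩_ox + ⟨ΔU⟩_red)/2, exact
for equal-variance Gaussian gap distributions. The condensed-phase AEA is
−ΔA_LR, and potentials follow the Nernst relation E = −ΔA/nF referenced to
the standard hydrogen electrode (absolute potential 4.281 V). Standard
errors come from block averaging; see `docs/methods.md` for the
tail-dominance handling of the exponential estimator.

## Worked example

`python examples/condensed_phase_pipeline.py` builds a two-state redox
couple (gas-phase AEA +0.18 eV), solvates the neutral form with isotropic
water-like charges and the anion with a counterion plus dipoles biased
toward the solute, and prints:

```
Delta A (eq1)            -2.307 +- 0.113 eV
Delta A (linear resp.)   -2.148 eV
AEA in solution          +2.148 +- 0.023 eV  (gas phase: +0.180 eV)
E vs SHE                 -1.974 V
```

ΔA < 0 means reduction is favorable in this environment; the solution AEA
sits ~2 eV above the gas-phase value because the polarized, counterion-
bearing ensemble stabilizes the anion — the qualitative signature of polar
solvation. The other examples cover the gas-phase observable chain
(`gas_phase_observables.py`), the Gaussian-limit identity of the estimator
(`estimator_gaussian_limit.py`), and a solvent-polarization sweep
(`solvent_stabilization.py`).

## Library tour

- `pmmredox.qc` — quantum-center JSON schema (versioned; Hartree/Debye/nm
  accepted and converted), VEA/AEA, Kabsch RMSD, charge localization.
- `pmmredox.frames` — environment frames from multi-frame GRO, multi-model
  PDB or XTC with a charge sidecar; QC masking, stride sampling, link-atom
  boundary policies; CSV/PDB serialization.
- `pmmredox.pmm` — fields, perturbed Hamiltonians, diagonalization, aligned
  two-form energy trajectories.
- `pmmredox.thermo` — estimators, Nernst/SHE, environment shifts,
  convergence curves, block errors.
- `pmmredox.synthetic` — seeded solvent-box and calibrated Gaussian-gap
  generators.
- `pmmredox.pipeline` — validated `RunConfig` plus `run_redox_pipeline`
  and `gas_phase_report`; every run writes a reproducibility manifest.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch: it builds a seeded
redox couple, generates both synthetic ensembles, executes the perturbed-
matrix pipeline and prints the gas-phase observables, both free-energy
estimates, the solution AEA and the potential vs SHE, then writes the
results JSON to `--out`.
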