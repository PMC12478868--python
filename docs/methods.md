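# Methods

This note documents the models, numerical choices and limitations of
`pmmredox` in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Perturbed-matrix scheme

The quantum center (QC) is assumed semirigid: one geometry per redox form,
no relaxation in the environment field. Its electronic structure enters as
N unperturbed states (default N = 5 for the target systems: ground plus
four excited states) with energies ε_l, permanent and transition dipoles
μ_ll′, and per-state ESP atomic charges q_k^(l). Both redox forms are
perturbed by the *same* field in every frame — the reduction is vertical
within a frame — so the gap ΔU_e = U_red − U_ox isolates the electronic
response plus the electrostatic coupling difference of the two charge
states.

Two expansion modes are implemented because the literature uses both and
the choice is not dictated by anything in the package's inputs:

- **dipole** — monopole + dipole expansion about the expansion center r₀:
  diagonal ε_l + q_T Φ(r₀) − E(r₀)·μ_ll, off-diagonal −E(r₀)·μ_ll′.
- **esp_diagonal** (default when per-state ESP charges are present) —
  diagonal ε_l + Σ_k q_k^(l) Φ(r_k), which captures potential variation
  across the QC; off-diagonals as in dipole mode.

The mode is recorded in every output. Both modes satisfy the same gauge
identity — a uniform potential Φ_c shifts every eigenvalue by exactly
q_T Φ_c (because each state's ESP charges sum to q_T) and the gap by
−Φ_c — which the tests assert at machine precision.

**r₀ convention.** The expansion center defaults to the geometric center
of the QC atoms and can be overridden in the QC file. Center of mass or
center of charge are equally defensible; the choice only matters in dipole
mode and is explicit so it can be varied.

**Degeneracy handling.** Eigenvalues from `numpy.linalg.eigh` are
ascending; when the two lowest are within 1e−9 eV and a previous frame's
ground eigenvector exists, the tie is broken by maximal overlap with it,
preventing state-swapping artifacts in gap series. Otherwise index order
decides.

**Electrostatics.** Φ(r) = k_e Σ q_j/|r−r_j| with k_e = 14.399645
eV·Å·e⁻²; minimum-image convention by default, no cutoff (every box charge
contributes). The real MD behind such data uses Ewald summation; a desk-
scale post-processor cannot reproduce that without the full neighbor
environment, and minimum-image/no-cutoff is the least arbitrary documented
choice. A source charge within 0.5 Å of r₀ or any QC atom raises an error
naming the frame, since that almost always means QC atoms were left in the
perturbing set.

## Units

Internal units are fixed: eV, Å, elementary charge; potentials in volts
(eV/e), fields in V/Å. The QC JSON reader accepts Hartree, Debye, nm and
bohr and converts once at load (CODATA factors). k_B = 8.617333262e−5
eV/K; the SHE absolute potential defaults to 4.281 V and is overridable.

## Free-energy estimators

The two-sided exponential estimator

ΔA = (k_B T/2)[ln⟨e^{βΔU}⟩_red − ln⟨e^{−βΔU}⟩_ox]

is the arithmetic mean of the forward (−k_BT ln⟨e^{−βΔU}⟩_ox) and reverse
(k_BT ln⟨e^{βΔU}⟩_red) one-sided Zwanzig estimates, so it always lies
between them (asserted as an exact property). Exponential means are
computed by log-sum-exp after centering the gaps by a shared constant that
is restored analytically: at 300 K, β ≈ 38.7 eV⁻¹, so raw exponentials of
eV-scale gaps overflow immediately.

The linear-response estimate (⟨ΔU⟩_ox + ⟨ΔU⟩_red)/2 is exact for Gaussian
gap distributions of equal variance. The condensed-phase AEA is defined
here as −ΔA_LR — "minus the mean perturbed energy difference" — while
reduction potentials may use either estimator; both are always computed
and labeled, never silently equated, because they only coincide in the
Gaussian limit.

**Sign conventions** (package-wide, labeled on every I/O surface):
ΔU_e = U_red − U_ox; AEA_sol = −ΔA_LR (positive ⇒ reduced form
stabilized); E_abs = −ΔA/n; E_vs_SHE = E_abs − E_SHE. Hence AEA↑ ⇒ ΔA↓ ⇒
E_vs_SHE↑.

## Standard errors

Mean-type observables (linear response, environment shifts) use block
averaging with a doubling block-size scan; the plateau criterion is two
successive SEs within 10%, and an inconclusive scan falls back to 5 equal
blocks. On uncorrelated data the scan plateaus at block size 1 and the SE
degrades gracefully to the plain standard error of the mean.

The exponential estimator needs more care. Its SE comes from recomputing
the estimator on paired contiguous blocks (5 by default). When either
exponential average is dominated by extreme samples — detected as the
largest single-sample weight exceeding 5% — the estimator's fluctuations
shrink only logarithmically with sample size (the relevant statistic is a
sample maximum, not a sum), so dividing the block scatter by √n_blocks
would understate the error several-fold. In that regime the SE switches to
10 blocks and scales the block scatter by √(ln m/ln n) (m = block length,
n = total) instead of 1/√n_blocks; the regime flag and settings are
recorded in the result's `details`. Empirically this restores ≈3σ coverage
for the Gaussian benchmark at σ = 0.5 eV, where the naive block SE fails
for roughly one seed in six. The study-style "±0.04 eV" error format is
produced by `SolutionAEA.__str__`.

## Synthetic environments

The generator replaces MD with i.i.d. configurations: rigid 3-site
water-like molecules (TIP3P geometry and charges: O −0.834 e, H +0.417 e)
placed uniformly in an orthorhombic box outside a 2.5 Å clash shell around
the QC, orientations Haar-uniform, optional monatomic counterion. The
defaults (a few tens of molecules in a ~26–30 Å box, frames 2 ps apart)
are a deliberately desk-scale version of the ~900-water, 30 Å, 2 ps-stride
setup the method is normally applied to.

A `bias` parameter in [0, 1] mixes each molecule's random dipole direction
with the unit vector toward the QC center, emulating the dielectric
alignment a charged solute induces; bias 0 is exactly isotropic. Biased
dipoles put positive ends nearer the QC, raising Φ at the solute and hence
stabilizing the more negative (reduced) form — the mechanism behind the
solvation shift of the AEA that the tests assert as an ordering, not a
value.

The calibrated Gaussian-gap generator places one distant probe charge
(150 Å) per frame and inverts the measured, nearly affine charge→gap map
(3-point stencil, linearity check at 2%) so Gaussian probe charges deliver
Gaussian gap ensembles with requested means and standard deviations.
Calibration metadata is stored in the stream.

What the synthetic world does *not* have: solvent structure (no radial
distribution), autocorrelation (frames are independent), polarizability,
or realistic charge magnitudes in the probe generator. A green test on
synthetic data therefore validates the estimator chain and the
electrostatics, not force-field or sampling quality.

All randomness flows through `numpy.random.default_rng(seed)` (PCG64);
a seed fixes every stream bit-for-bit across platforms.

## I/O and boundaries

Trajectory formats: multi-frame GRO (hand parser over the fixed-column
format, nm→Å), multi-model PDB and XTC via MDAnalysis (XTC requires a
topology file). Coordinate formats carry no charges, so a sidecar supplies
them (explicit list, name→charge map, or JSON/CSV). Only orthorhombic
boxes are supported; triclinic inputs are rejected with a clear error.
Counterions are part of the perturbing set by default and can be excluded
per atom index.

At a covalent QC boundary (nucleoside-type systems where a link hydrogen
caps the QC), the default policy excludes the charge of the single
environment atom the cap replaces; an alternative redistributes that
charge over its nearest three neighbors, conserving total environment
charge exactly. The applied policy is always recorded in stream metadata.

The Kabsch RMSD is unweighted (all atoms equal); mass weighting is a
defensible alternative but the unweighted convention is the one used for
the structural-reorganization comparisons this package targets, and the
choice is documented here rather than configurable.

## Known limitations

- No BAR/MBAR-style multi-state estimators; the two implemented ones are
  those the workflow defines.
- The exponential estimator is statistically fragile when βσ ≫ 1 even
  with the corrected SE; for σ ≈ 0.5 eV at 300 K it is dominated by rare
  frames, and linear response is the more stable number (this is visible
  in the worked examples' error bars).
- No polarizable environments and no QC geometry relaxation in the field
  (semirigid assumption).
- Energies are carried on each species' declared reference; users must
  supply both redox forms on a common reference for the gap to be
  physical.
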