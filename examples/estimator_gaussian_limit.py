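"""The Gaussian-limit identity of the two-sided exponential estimator.

Calibrated probe-charge streams give reduction gaps with exact Gaussian
targets in each ensemble; for equal variances the free energy must equal
(m_ox + m_red)/2 — here 1.5 eV — and agree with the linear-response
average.  This is the property that makes the estimator trustworthy on
well-behaved (near-Gaussian) gap distributions.
"""

import numpy as np

import pmmredox as pr

rng = np.random.default_rng(42)

geom = pr.Geometry(elements=("C", "N", "O"),
                   coords=rng.uniform(-1.0, 1.0, size=(3, 3)))


def form(redox, q_total, energies, seed):
    r = np.random.default_rng(seed)
    states = []
    for l, e in enumerate(energies):
        q = r.normal(0.0, 0.1, size=3)
        q += (q_total - q.sum()) / 3
        states.append(pr.ElectronicState(l, e, r.normal(0, 0.3, 3), q))
    return pr.QuantumCenter(name="gauss-demo", redox=redox,
                            total_charge=q_total, geometry=geom,
                            states=tuple(states),
                            transition_dipoles={(0, 1): r.normal(0, 0.2, 3)})


species = pr.RedoxSpecies(oxidized=form("oxidized", 0.0, [0.0, 2.0], 1),
                          reduced=form("reduced", -1.0, [-0.2, 1.6], 2))

stream_ox, stream_red = pr.generate_gaussian_gap_frames(
    species,
    pr.EnsembleTarget(mean=2.0, sd=0.5, label="oxidized"),
    pr.EnsembleTarget(mean=1.0, sd=0.5, label="reduced"),
    n_frames=20_000, seed=5)

gaps = {}
for label, stream in (("oxidized", stream_ox), ("reduced", stream_red)):
    traj = pr.perturbed_energy_trajectory(species, stream, mode="dipole",
                                          pbc_mode="none")
    gaps[label] = pr.GapSamples(label, traj.gap, 300.0, traj.times_ps)
    print(f"{label:9s} ensemble: mean gap {traj.gap.mean():+.3f} eV, "
          f"sd {traj.gap.std():.3f} eV")

eq1 = pr.free_energy_eq1(gaps["oxidized"], gaps["reduced"])
lr = pr.free_energy_linear_response(gaps["oxidized"], gaps["reduced"])

print(f"\nDelta A (two-sided exponential)  {eq1.delta_a:+.3f} "
      f"+- {eq1.std_err:.3f} eV")
print(f"Delta A (linear response)        {lr.delta_a:+.3f} "
      f"+- {lr.std_err:.3f} eV")
print("closed form (m_ox + m_red)/2     +1.500 eV")
print("\nBoth estimators recover the Gaussian closed form; the exponential"
      "\naverage carries a larger error because rare tail samples dominate"
      "\nit at this gap variance (0.5 eV at 300 K).")
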