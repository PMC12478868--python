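"""Gas-phase electron-affinity bookkeeping for a redox couple.

Builds a small two-form quantum center, then computes the vertical and
adiabatic electron affinities from total energies, the structural
reorganization (Kabsch RMSD) between the neutral and anion minima, and how
much of the extra electron sits on the tagged "base" moiety.
"""

import numpy as np

import pmmredox as pr

rng = np.random.default_rng(2024)

# a 6-atom toy molecule; the first five atoms are tagged as the "base"
coords_neutral = rng.uniform(-1.5, 1.5, size=(6, 3))
geom_neutral = pr.Geometry(elements=("C", "N", "C", "N", "O", "H"),
                           coords=coords_neutral,
                           tags={"base": (0, 1, 2, 3, 4)})
# the anion relaxes slightly out of plane
geom_anion = pr.Geometry(elements=geom_neutral.elements,
                         coords=coords_neutral
                         + rng.normal(0.0, 0.08, size=(6, 3)),
                         tags=geom_neutral.tags)

rmsd = pr.kabsch_rmsd(geom_neutral, geom_anion)

# total electronic energies (eV, common reference) from any QM engine:
e_neutral_min = 0.0          # neutral at its own minimum
e_anion_at_neutral = 0.29    # anion at the frozen neutral geometry
e_anion_min = -0.18          # anion at its own minimum

vea = pr.vertical_electron_affinity(e_neutral_min, e_anion_at_neutral)
aea = pr.adiabatic_electron_affinity(e_neutral_min, e_anion_min)

# ESP charges of the anion ground state: how localized is the electron?
q = np.array([-0.31, -0.25, -0.18, -0.12, -0.06, -0.08])
state = pr.ElectronicState(0, -0.18, np.zeros(3), q)
fraction = pr.charge_localization_fraction(state, geom_anion.tags["base"],
                                           total_charge=-1.0)

print(f"VEA                    {vea:+.2f} eV   (negative: anion "
      "vertically unbound)")
print(f"AEA                    {aea:+.2f} eV   (positive: relaxed anion "
      "is bound)")
print(f"anion-vs-neutral RMSD  {rmsd:.3f} angstrom  (structural "
      "reorganization)")
print(f"charge on base moiety  {fraction:.0%}      (electron localized "
      "on the base)")
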