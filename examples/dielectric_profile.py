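"""Local dielectric constant from dipole fluctuations (Kirkwood-Frohlich).

Builds dipole-moment snapshots with a layered variance profile (low in the
membrane core, high in the headgroup region, intermediate in water) and
converts them to a dielectric profile eps(z) = 1 + var M / (3 eps0 kB T V).
"""

import numpy as np

from scstrain.fields import dielectric_profile
from scstrain.synthetic import make_dipole_snapshots

z = np.linspace(-3.0, 3.0, 25)  # nm from the membrane midplane
core = 1e-5 * np.exp(-z**2 / 0.8)
head = 0.0080 * (np.exp(-(z - 2.0)**2 / 0.1) + np.exp(-(z + 2.0)**2 / 0.1))
water = 0.0039 / (1 + np.exp(-(np.abs(z) - 2.4) / 0.1))
variance = core + head + water  # e^2 nm^2 per component

d = make_dipole_snapshots(variance, n_snapshots=5000, seed=9, z_centers_nm=z)
prof = dielectric_profile(d, temperature=310.0)

print(" z (nm)   eps")
for zi, ei in zip(prof.z_nm, prof.epsilon):
    bar = "#" * int(ei / 5)
    print(f"  {zi:+.2f}   {ei:7.1f}  {bar}")
print()
print("The profile is ~1 in the hydrophobic core, peaks at the polar")
print("headgroup belts, and relaxes to the aqueous value outside - the")
print("local increase before the bulk decay seen around membrane surfaces.")
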