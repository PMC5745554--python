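"""Locate the chiral symmetry-breaking transition of the two-enantiomer model.

Monomers D and L polymerise randomly, hydrolyse, and — when k_lig > 0 —
uniform strands template the ligation of shorter uniform strands of the
same handedness.  Starting from a 50.5/49.5 monomer bias, this script scans
k_lig and then bisects for the critical value at which the bias stops
decaying and is amplified instead.
"""

import templig as tl
from templig.scans import find_critical, scan_klig

spec = tl.chirality_model()     # C_tot = 10, k_pol = k_hyd = k_int = 1, l_max = 6

print("k_lig   phi_D   phi_L   phi_M   mono    ee")
res = scan_klig(spec, [0.0, 2.0, 4.0, 5.0, 6.0, 10.0])
for k, fr in zip(res.values, res.branches["biased"]):
    print(f"{k:5.1f}  {fr.phi['D']:.4f}  {fr.phi['L']:.4f}  {fr.phi_M:.4f}"
          f"  {fr.monomer_fraction:.4f}  {fr.ee:+.4f}")

crit = find_critical(spec, bracket=(1.0, 10.0), tol=0.05)
print(f"\ncritical k_lig = {crit.value:.3f}  "
      f"(final bracket {crit.bracket[0]:.3f}..{crit.bracket[1]:.3f})")
print("Below this rate phi_D = phi_L (racemic); above it one enantiomer")
print("dominates the oligomer pool and mixed strands are depleted.")
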