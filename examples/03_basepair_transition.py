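"""Symmetry breaking with explicit bases and complementary templating.

Eight monomer types (A, U, G, C in both D and L forms) polymerise at equal
rates; a template must carry a uniform-chirality window whose bases are
complementary (AU/GC pairs only) to the product being ligated.  Requiring
complementarity shrinks the template pool for any particular product, so
the transition needs a roughly tenfold higher ligation rate than the
base-agnostic model.  The deterministic system (about 3e5 sequences at
l_max = 6) is integrated exactly on base-permutation symmetry orbits
(about 2e4 classes).

Runtime: a few minutes (one steady-state relaxation per bisection point).
"""

import templig as tl
from templig.scans import find_critical

spec = tl.basepair_model()
crit = find_critical(spec, bracket=(25.0, 60.0), tol=0.5)
print(f"critical k_lig (base-explicit) = {crit.value:.1f}")
print("classification history:")
for value, label in crit.history:
    print(f"  k_lig = {value:7.3f}: {label}")
print("Compare with the base-agnostic chirality model, whose transition")
print("sits near k_lig = 4.6 under the same conditions.")
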