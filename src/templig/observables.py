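"""Summary statistics: nucleotide fractions and excess observables.

``phi_t`` is the fraction of all nucleotides residing in *uniform* oligomers
(dimers and longer) of type ``t``; ``phi_M`` the fraction in mixed oligomers
(at least two types); free monomers are excluded from every phi class and
reported as the remainder, so the four numbers sum to one exactly.

The excess ``ee`` is defined for two-type variants over nucleotides
incorporated into oligomers (length >= 2, mixed strands included):
``(a - b) / (a + b)``.  For the regioselectivity variant the analogous
quantity is computed over backbone bonds.  Free monomers are excluded, which
is why the monomer-level excess stays identically zero whenever direct
interconversion is active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import ConcentrationState
from .network import ReactionNetwork


@dataclass(frozen=True)
class FractionSummary:
    """Nucleotide bookkeeping of one state; entries sum to 1 exactly."""

    phi: dict[str, float]          # per uniform type, oligomers only
    phi_M: float                   # mixed oligomers
    monomer_fraction: float        # free monomers (the exact remainder)
    ee: float | None = None        # oligomer excess, two-type variants only
    monomer_ee: float | None = None  # excess among free monomers

    @property
    def dominant_type(self) -> str:
        return max(self.phi, key=lambda t: self.phi[t])

    def as_dict(self) -> dict:
        out = {f"phi_{t}": v for t, v in self.phi.items()}
        out.update(phi_M=self.phi_M, monomer_fraction=self.monomer_fraction)
        if self.ee is not None:
            out["ee"] = self.ee
        if self.monomer_ee is not None:
            out["monomer_ee"] = self.monomer_ee
        return out


def fractions(state: ConcentrationState, net: ReactionNetwork) -> FractionSummary:
    """Nucleotide fractions and excess of a deterministic state."""
    spec = net.spec
    C = state.C
    nucl = net.length * net.weight * C       # nucleotides per class
    total = spec.C_tot
    phi = {}
    for t_idx, t in enumerate(spec.uniform_types):
        phi[t] = float(nucl[net.uniform_code == t_idx].sum()) / total
    phi_M = float(nucl[net.uniform_code == -1].sum()) / total
    mono = 1.0 - sum(phi.values()) - phi_M
    ee = mono_ee = None
    if net.ee_counts is not None:
        olig = net.length >= 2
        wa = net.ee_counts[0] * net.weight * C
        wb = net.ee_counts[1] * net.weight * C
        a, b = float(wa[olig].sum()), float(wb[olig].sum())
        ee = (a - b) / (a + b) if a + b > 0 else 0.0
        if spec.variant != "regioselectivity":
            am = float(wa[~olig].sum())
            bm = float(wb[~olig].sum())
            mono_ee = (am - bm) / (am + bm) if am + bm > 0 else 0.0
    return FractionSummary(phi, phi_M, mono, ee, mono_ee)


def oligomer_excess(state: ConcentrationState, net: ReactionNetwork) -> float:
    """The ee of nucleotides in oligomers (bonds, for regioselectivity)."""
    s = fractions(state, net)
    if s.ee is None:
        raise ValueError("excess is defined only for two-type variants")
    return s.ee


def length_distribution(state: ConcentrationState,
                        net: ReactionNetwork) -> np.ndarray:
    """Total strand concentration per length, index 1..l_max (index 0 unused)."""
    out = np.zeros(int(net.length.max()) + 1)
    np.add.at(out, net.length, net.weight * state.C)
    return out
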