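"""Detailed-balance equilibrium of the system without templating.

With ``k_lig = 0`` every reaction (joining at ``k_pol`` — ``w_b * k_pol``
per bond type in the regioselectivity variant — versus hydrolysis at
``k_hyd``, and monomer interconversion) is individually reversible, so the
equilibrium factorises over bonds and monomers:

    C(s) = prod_bonds (w_b * k_pol / k_hyd) * prod_monomers m_a

The monomer activities ``m_a`` satisfy the interconversion detailed-balance
ratios ``m_b / m_a = k_int(a->b) / k_int(b->a)`` and a single mass-balance
polynomial: with ``M = sum_a m_a`` and ``r = k_pol * sum_b w_b / k_hyd``,

    sum_{n=1..l_max} n * r**(n-1) * M**n = C_tot,

(geometric closed form ``M / (1 - r M)**2`` for unbounded length).  The
total strand concentration per length is then ``r**(n-1) * M**n``
independent of the variant, which is why all variants share one equilibrium
length distribution.

This closed form serves as an independent oracle for both engines in the
test suite and as a convenient reference state.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .kinetics import ConcentrationState
from .model import ModelSpec
from .network import ReactionNetwork


def _r_eff(spec: ModelSpec) -> float:
    w = sum(spec.pol_bond_weights.values()) if spec.has_bonds else 1.0
    return spec.k_pol * w / spec.k_hyd


def solve_monomer_activity_total(r: float, C_tot: float,
                                 l_max: int | None) -> float:
    """Solve sum_n n r^(n-1) M^n = C_tot for the total monomer activity M."""
    if r == 0:
        return C_tot

    if l_max is None:
        def f(M):
            return M / (1.0 - r * M) ** 2 - C_tot
        hi = (1.0 - 1e-12) / r
    else:
        def f(M):
            n = np.arange(1, l_max + 1)
            return float(np.sum(n * r ** (n - 1) * M ** n)) - C_tot
        hi = max(C_tot, 1.0 / r) * 2.0
        while f(hi) < 0:
            hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-15))


def monomer_activities(spec: ModelSpec) -> dict[str, float]:
    """Equilibrium activity m_a per monomer symbol (k_lig = 0).

    Within each interconversion-connected component the ratios follow
    detailed balance; each component's total nucleotide mass is taken as the
    equal-per-symbol share of C_tot (the symmetric initial condition used
    throughout).  One-way interconversion has no detailed-balance
    equilibrium and is rejected.
    """
    syms = spec.monomer_alphabet
    masses: dict[str, float] = {}  # per-symbol nucleotide mass at equilibrium
    # connected components over nonzero interconversion
    comp_of: dict[str, int] = {}
    ncomp = 0
    for s in syms:
        if s in comp_of:
            continue
        stack, comp_of[s] = [s], ncomp
        ratios = {s: 1.0}
        while stack:
            a = stack.pop()
            for b in syms:
                if b == a:
                    continue
                kab, kba = spec.k_int[(a, b)], spec.k_int[(b, a)]
                if kab == 0 and kba == 0:
                    continue
                if kab == 0 or kba == 0:
                    raise ValueError("one-way interconversion has no "
                                     "detailed-balance equilibrium")
                if b not in comp_of:
                    comp_of[b] = ncomp
                    ratios[b] = ratios[a] * kab / kba
                    stack.append(b)
                elif not math.isclose(ratios[b], ratios[a] * kab / kba,
                                      rel_tol=1e-9):
                    raise ValueError("interconversion rates violate detailed "
                                     "balance around a cycle")
        total = len(ratios) * spec.C_tot / len(syms)
        norm = sum(ratios.values())
        for a, ra in ratios.items():
            masses[a] = total * ra / norm
        ncomp += 1
    M = solve_monomer_activity_total(_r_eff(spec), spec.C_tot, spec.l_max)
    return {a: masses[a] / spec.C_tot * M for a in syms}


def equilibrium_state(net: ReactionNetwork) -> ConcentrationState:
    """Per-class equilibrium concentrations for k_lig = 0."""
    spec = net.spec
    m = monomer_activities(spec)
    r = spec.k_pol / spec.k_hyd
    C = np.empty(net.n_classes)
    for i, s in enumerate(net.reps):
        c = 1.0
        for sym in s.monomers:
            c *= m[sym]
        if spec.has_bonds:
            for b in s.bonds:
                c *= r * spec.pol_bond_weights[b]
        else:
            c *= r ** (s.n - 1)
        C[i] = c
    return ConcentrationState(C)


def equilibrium_length_distribution(spec: ModelSpec,
                                    n_max: int = 40) -> np.ndarray:
    """Total strand concentration per length (index 0 unused).

    For unbounded l_max the distribution is truncated at ``n_max``.
    """
    r = _r_eff(spec)
    M = solve_monomer_activity_total(r, spec.C_tot, spec.l_max)
    top = spec.l_max if spec.l_max is not None else n_max
    out = np.zeros(top + 1)
    for n in range(1, top + 1):
        out[n] = r ** (n - 1) * M ** n
    return out
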