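"""Exact symmetry groups used to lump the deterministic species set.

The base-explicit model has ``sum(8**n)`` species up to length ``l_max``
(about 3e5 at ``l_max = 6``), far too many to integrate species-by-species.
Its dynamics, however, commute with every base permutation that preserves
Watson-Crick pairing (the centraliser of the A<->U, G<->C involution, a
dihedral group of order 8) and with whole-strand reversal.  Starting from an
initial state that is symmetric under this group (equal monomer
concentrations per base within each chirality), the concentration vector
stays exactly constant on group orbits for all time, so the system can be
integrated on orbit representatives with orbit sizes as weights.  This is an
exact reduction, not an approximation; the test suite checks lumped against
unlumped trajectories on a small system.

Strand reversal deserves a note: it maps the antiparallel (reverse
complement) template convention onto the parallel one, so along
reversal-symmetric trajectories the two complement orientations give
identical dynamics.

Group elements act on the network's internal single-character string
encoding of strands: ``(translation_table, reverse_flag)``.
"""

from __future__ import annotations

from .model import ModelSpec

#: monomer index -> encoding character (alphabet position order)
MONO_CHARS = "ABCDEFGHIJKLMNOP"
#: bond index -> encoding character (regioselectivity)
BOND_CHARS = "01"


def identity_group() -> list[tuple[dict | None, bool]]:
    return [(None, False)]


def _pairing_permutations() -> list[tuple[int, ...]]:
    """All permutations of (A,U,G,C) indices commuting with complementation."""
    comp = (1, 0, 3, 2)  # A<->U, G<->C on base indices
    gens = [
        (1, 0, 2, 3),    # swap A,U
        (0, 1, 3, 2),    # swap G,C
        (2, 3, 0, 1),    # swap the AU pair with the GC pair
    ]
    group = {(0, 1, 2, 3)}
    frontier = list(group)
    while frontier:
        g = frontier.pop()
        for h in gens:
            gh = tuple(g[h[i]] for i in range(4))
            if gh not in group:
                group.add(gh)
                frontier.append(gh)
    assert all(tuple(comp[g[i]] for i in range(4)) ==
               tuple(g[comp[i]] for i in range(4)) for g in group)
    return sorted(group)


def basepair_group(include_reversal: bool = True) -> list[tuple[dict | None, bool]]:
    """Lumping group for the base-explicit variant (order 8, or 16 with reversal).

    Monomer encoding characters follow the alphabet order dA,dU,dG,dC,
    lA,lU,lG,lC: index = 4*mark + base.
    """
    elements = []
    for perm in _pairing_permutations():
        table = {}
        for mark in range(2):
            for base in range(4):
                src = MONO_CHARS[4 * mark + base]
                dst = MONO_CHARS[4 * mark + perm[base]]
                if src != dst:
                    table[ord(src)] = dst
        table = table or None
        elements.append((table, False))
        if include_reversal:
            elements.append((table, True))
    return elements


def lumping_group(spec: ModelSpec) -> list[tuple[dict | None, bool]]:
    """Default lumping group for a spec: nontrivial only for chirality_basepair."""
    if spec.variant == "chirality_basepair":
        return basepair_group()
    return identity_group()


def apply_element(s: str, element: tuple[dict | None, bool]) -> str:
    table, rev = element
    if table is not None:
        s = s.translate(table)
    return s[::-1] if rev else s


def canonical(s: str, group) -> str:
    """Lexicographically smallest group image — the orbit representative."""
    if len(group) == 1:
        return s
    return min(apply_element(s, g) for g in group)
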