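"""Strands, species enumeration and template-qualification rules.

A strand is an ordered oligomer: a sequence of monomer symbols plus, in the
regioselectivity variant only, a sequence of backbone-bond symbols (one per
internal linkage).  Order matters: ``concat(i, j)`` puts ``i`` on the left.

The templating rules implemented here are the model's central assumption:
uniform strands template the ligation of two shorter uniform strands of the
same kind, mixed strands template nothing.  Concretely, a strand qualifies as
a template for a product when it carries a *contiguous* uniform stretch at
least as long as the product (chirality, monomer selection), a contiguous
uniform-chirality window whose bases are complementary to the product
(base-explicit variant), or a contiguous run of identical bonds at least as
long as the product's bond sequence (regioselectivity).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .model import BASE_COMPLEMENT, ModelSpec


@dataclass(frozen=True, order=True)
class Strand:
    """One oligomer: monomer symbols plus (regioselectivity only) bond symbols."""

    monomers: tuple[str, ...]
    bonds: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(self.monomers) < 1:
            raise ValueError("a strand has at least one monomer")
        if self.bonds and len(self.bonds) != len(self.monomers) - 1:
            raise ValueError(
                f"{len(self.monomers)} monomers need {len(self.monomers) - 1} "
                f"bond symbols, got {len(self.bonds)}"
            )

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def n(self) -> int:
        """Number of monomers."""
        return len(self.monomers)


def check_strand(s: Strand, spec: ModelSpec) -> None:
    """Raise ValueError if ``s`` uses symbols outside the spec's alphabets."""
    bad = set(s.monomers) - set(spec.monomer_alphabet)
    if bad:
        raise ValueError(f"monomer symbols {sorted(bad)} not in alphabet")
    if spec.has_bonds:
        if len(s.bonds) != s.n - 1:
            raise ValueError("regioselectivity strands carry n-1 bond symbols")
        bad = set(s.bonds) - set(spec.bond_alphabet)
        if bad:
            raise ValueError(f"bond symbols {sorted(bad)} not in alphabet")
    elif s.bonds:
        raise ValueError(f"variant {spec.variant!r} strands carry no bond symbols")


# ----------------------------------------------------------------------
# elementary strand algebra


def concat(i: Strand, j: Strand, new_bond: str | None = None) -> Strand:
    """Join ``i`` (left) and ``j`` (right) into the longer strand ``ij``.

    Variants without a bond alphabet pass ``new_bond=None``; the
    regioselectivity variant passes the symbol of the newly formed bond.
    """
    if new_bond is None:
        if i.bonds or j.bonds:
            raise ValueError("bond-carrying strands need a new_bond symbol")
        return Strand(i.monomers + j.monomers)
    return Strand(i.monomers + j.monomers, i.bonds + (new_bond,) + j.bonds)


def hydrolysis_products(s: Strand, bond_index: int) -> tuple[Strand, Strand]:
    """Severs bond ``bond_index`` (0-based, left to right); returns fragments.

    ``concat`` of the fragments, re-using the severed bond symbol, reproduces
    ``s`` exactly.
    """
    if not 0 <= bond_index < s.n - 1:
        raise IndexError(f"bond index {bond_index} out of range for n={s.n}")
    left = Strand(s.monomers[: bond_index + 1],
                  s.bonds[:bond_index] if s.bonds else ())
    right = Strand(s.monomers[bond_index + 1:],
                   s.bonds[bond_index + 1:] if s.bonds else ())
    return left, right


# ----------------------------------------------------------------------
# uniformity and templating


def is_uniform(s: Strand, spec: ModelSpec) -> bool:
    """Is the strand uniform in the sense of the variant's templating rule?

    Chirality / monomer selection: all monomer symbols identical (a single
    monomer is trivially uniform).  Base-explicit: all chirality marks
    identical, any bases.  Regioselectivity: all bond symbols identical, so
    monomers and dimers are trivially uniform.
    """
    return bool(uniform_types(s, spec))


def uniform_types(s: Strand, spec: ModelSpec) -> tuple[str, ...]:
    """Uniform-type labels the strand is compatible with as a ligation substrate.

    Returns () for mixed strands.  In the regioselectivity variant a bare
    monomer carries no bonds and is compatible with both bond types.
    """
    if spec.variant == "regioselectivity":
        if s.n == 1:
            return spec.bond_alphabet
        first = s.bonds[0]
        return (first,) if all(b == first for b in s.bonds) else ()
    if spec.variant == "chirality_basepair":
        mark = s.monomers[0][0]
        return (mark,) if all(m[0] == mark for m in s.monomers) else ()
    first = s.monomers[0]
    return (first,) if all(m == first for m in s.monomers) else ()


def complement_base_strings(bases: str, orientation: str) -> tuple[str, ...]:
    """Base string(s) a template window may carry to pair with ``bases``.

    ``antiparallel`` is the oriented duplex convention (reverse complement),
    ``parallel`` the position-by-position complement; ``either`` accepts
    both, the natural rule for strands that carry no 5'/3' orientation and
    can present a window in both alignments.
    """
    comp = "".join(BASE_COMPLEMENT[b] for b in bases)
    if orientation == "parallel":
        return (comp,)
    if orientation == "antiparallel":
        return (comp[::-1],)
    return tuple({comp, comp[::-1]})


def template_match_count(template: Strand, product: Strand,
                         spec: ModelSpec) -> int:
    """Number of alignment sites at which ``template`` can template ``product``.

    Zero means the template does not qualify.  A site is a contiguous
    window of the template satisfying the variant's rule: a uniform run of
    the product's monomer type at least as long as the product (chirality,
    monomer selection), a uniform-chirality window carrying the required
    complementary base string (base-explicit; under the ``either``
    orientation each alignment direction counts separately), or a run of
    identical bonds at least as long as the product's bond sequence
    (regioselectivity).  The product must itself be fully uniform — mixed
    products are never template-made and count zero.
    """
    n = product.n
    if n < 2:
        return 0  # ligation products are dimers or longer
    if template.n < n and spec.variant != "regioselectivity":
        return 0
    if spec.variant in ("chirality", "monomer_selection"):
        t = product.monomers[0]
        if any(m != t for m in product.monomers):
            return 0
        return _window_count(template.monomers, t, n)
    if spec.variant == "chirality_basepair":
        mark = product.monomers[0][0]
        if any(m[0] != mark for m in product.monomers):
            return 0
        orientation = spec.complement_orientation
        comp = "".join(BASE_COMPLEMENT[m[1]] for m in product.monomers)
        wants = []
        if orientation in ("parallel", "either"):
            wants.append(comp)
        if orientation in ("antiparallel", "either"):
            wants.append(comp[::-1])
        marks = [m[0] for m in template.monomers]
        bases = "".join(m[1] for m in template.monomers)
        count = 0
        for start in range(template.n - n + 1):
            if all(c == mark for c in marks[start:start + n]):
                count += sum(bases[start:start + n] == w for w in wants)
        return count
    # regioselectivity: contiguous run of n-1 bonds of the product's type
    tau = product.bonds[0]
    if any(b != tau for b in product.bonds):
        return 0
    return _window_count(template.bonds, tau, n - 1)


def templates_product(template: Strand, product: Strand, spec: ModelSpec) -> bool:
    """Does ``template`` qualify as a template for forming ``product``?"""
    return template_match_count(template, product, spec) > 0


def _window_count(symbols: tuple[str, ...], t: str, n: int) -> int:
    """Number of length-n windows lying inside runs of symbol ``t``."""
    count = cur = 0
    for m in symbols:
        cur = cur + 1 if m == t else 0
        if cur >= n:
            count += 1
    return count


def catalyzed_products(template: Strand, i: Strand, j: Strand,
                       spec: ModelSpec) -> tuple[Strand, ...]:
    """Products ``ij`` whose templated ligation ``template`` catalyses.

    Both ``i`` and ``j`` must be uniform and of a common type; the template
    must qualify for the joined product.  Non-regioselectivity variants yield
    at most one product; in the regioselectivity variant two bare monomers
    can be joined by either bond type, so up to two products are possible.
    """
    shared = [t for t in uniform_types(i, spec) if t in uniform_types(j, spec)]
    if not shared:
        return ()
    out = []
    for t in shared:
        product = concat(i, j, t if spec.has_bonds else None)
        if templates_product(template, product, spec):
            out.append(product)
    return tuple(out)


def template_qualifies(template: Strand, i: Strand, j: Strand,
                       spec: ModelSpec) -> bool:
    """True if ``template`` catalyses the ligation of ``i`` and ``j``."""
    return bool(catalyzed_products(template, i, j, spec))


# ----------------------------------------------------------------------
# species enumeration


def enumerate_species(spec: ModelSpec) -> list[Strand]:
    """Every distinct strand of length 1..l_max, in canonical order.

    Canonical order: by length, then lexicographically by alphabet position
    of the monomer symbols (and bond symbols, regioselectivity).  Requires a
    finite ``l_max``.
    """
    if spec.l_max is None:
        raise ValueError("species enumeration requires a finite l_max")
    out: list[Strand] = []
    for n in range(1, spec.l_max + 1):
        for mono in itertools.product(spec.monomer_alphabet, repeat=n):
            if spec.has_bonds:
                for bonds in itertools.product(spec.bond_alphabet, repeat=n - 1):
                    out.append(Strand(mono, bonds))
            else:
                out.append(Strand(mono))
    return out


def template_pool_size(product: Strand, spec: ModelSpec) -> int:
    """Size of the template pool for ``product`` over the full species list.

    Under the default ``per_strand`` counting this is the number of species
    qualifying as templates; under ``per_site`` every matching alignment
    window contributes, so the pool is measured in binding sites.  Computed
    by brute force; the kinetics engine's precomputed template-incidence
    structure is validated against this in the test suite.
    """
    if spec.l_max is not None and product.n > spec.l_max:
        return 0
    species = enumerate_species(spec)
    if spec.template_counting == "per_site":
        return sum(template_match_count(t, product, spec) for t in species)
    return sum(templates_product(t, product, spec) for t in species)


# ----------------------------------------------------------------------
# plain-string serialization
#
# Grammar: if every monomer (and bond) symbol is a single character the
# strand serialises as a bare concatenation, interleaving bonds in the
# regioselectivity variant ("DLLDL", "N3N3N2N"); otherwise tokens are
# space-separated ("dA lG uC"-style for the base-explicit variant).


def strand_to_str(s: Strand, spec: ModelSpec) -> str:
    check_strand(s, spec)
    single = all(len(m) == 1 for m in spec.monomer_alphabet) and \
        all(len(b) == 1 for b in spec.bond_alphabet)
    if spec.has_bonds:
        parts = [s.monomers[0]]
        for b, m in zip(s.bonds, s.monomers[1:]):
            parts.extend((b, m))
    else:
        parts = list(s.monomers)
    return ("" if single else " ").join(parts)


def strand_from_str(text: str, spec: ModelSpec) -> Strand:
    single = all(len(m) == 1 for m in spec.monomer_alphabet) and \
        all(len(b) == 1 for b in spec.bond_alphabet)
    tokens = list(text) if single else text.split()
    if not tokens:
        raise ValueError("empty strand string")
    if spec.has_bonds:
        if len(tokens) % 2 == 0:
            raise ValueError("regioselectivity strings alternate monomer/bond")
        mono, bonds = tuple(tokens[::2]), tuple(tokens[1::2])
        s = Strand(mono, bonds)
    else:
        s = Strand(tuple(tokens))
    check_strand(s, spec)
    return s


def relabel(s: Strand, monomer_map=None, bond_map=None) -> Strand:
    """Apply a symbol permutation (e.g. D<->L) to a strand."""
    mono = tuple((monomer_map or {}).get(m, m) for m in s.monomers)
    bonds = tuple((bond_map or {}).get(b, b) for b in s.bonds)
    return Strand(mono, bonds)
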