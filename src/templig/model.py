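"""Model specifications for the templated-polymerization reaction schemes.

A :class:`ModelSpec` names one of four model variants and carries every rate
constant and system-size parameter:

``chirality``
    Two mirror-image monomers ``D`` and ``L``.  Uniform strands of one
    handedness template ligation of shorter uniform strands of the same
    handedness.  Exact D/L symmetry is required.
``chirality_basepair``
    Eight monomers: bases A, U, G, C in both D and L form.  A template must
    contain a uniform-chirality run whose base sequence is complementary
    (A-U and G-C pairs only) to the ligated product.
``monomer_selection``
    A ribonucleotide ``R`` competing with chemically distinct alternatives
    ``X`` (or ``X1``, ``X2``); rates need not be symmetric.
``regioselectivity``
    A single monomer ``N`` with two backbone bond isomers, ``3`` (3'-5')
    and ``2`` (2'-5').  Templating requires a uniform run of bonds.

Rates follow mass-action conventions: ``k_pol`` per time per concentration,
``k_hyd`` per time, ``k_lig`` per time per concentration squared, ``k_int``
per time (monomer interconversion, free monomers only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

VARIANTS = ("chirality", "chirality_basepair", "monomer_selection", "regioselectivity")

#: bases and Watson-Crick partners used by the base-explicit variant
BASES = ("A", "U", "G", "C")
BASE_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
CHIRALITY_MARKS = ("d", "l")


def _as_matrix(k_int, alphabet) -> dict[tuple[str, str], float]:
    """Normalise k_int input (scalar or mapping) to a dense pair mapping."""
    out: dict[tuple[str, str], float] = {}
    if k_int is None:
        k_int = 0.0
    if np.isscalar(k_int):
        for a in alphabet:
            for b in alphabet:
                if a != b:
                    out[(a, b)] = float(k_int)
        return out
    for (a, b), v in dict(k_int).items():
        if a == b and v != 0:
            raise ValueError("k_int diagonal must be zero")
        if a != b:
            out[(a, b)] = float(v)
    for a in alphabet:
        for b in alphabet:
            if a != b:
                out.setdefault((a, b), 0.0)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterisation of one reaction scheme.

    ``k_lig`` maps a uniform-strand type to its templated-ligation rate:
    monomer symbols for ``chirality``/``monomer_selection``, chirality marks
    ``d``/``l`` for ``chirality_basepair``, bond symbols for
    ``regioselectivity``.  ``l_max`` of ``None`` means unbounded (Monte Carlo
    only).
    """

    variant: str
    monomer_alphabet: tuple[str, ...]
    bond_alphabet: tuple[str, ...] = ()
    k_pol: float = 1.0
    k_hyd: float = 1.0
    k_lig: Mapping[str, float] = field(default_factory=dict)
    k_int: Mapping[tuple[str, str], float] = field(default_factory=dict)
    C_tot: float = 10.0
    l_max: int | None = 6
    complement_orientation: str = "antiparallel"
    # how C_temp aggregates qualifying templates: "per_strand" counts each
    # qualifying strand once; "per_site" counts every matching alignment
    # window (a strand with several binding sites contributes several times)
    template_counting: str = "per_strand"
    # spontaneous-join weight per bond type (regioselectivity); the weights
    # multiply k_pol and sum to 1 so the total join rate stays k_pol*Ci*Cj
    pol_bond_weights: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "regioselectivity":
            if len(self.bond_alphabet) != 2:
                raise ValueError("regioselectivity needs exactly two bond types")
        elif self.bond_alphabet:
            raise ValueError(f"variant {self.variant!r} takes no bond alphabet")
        if self.k_pol < 0 or self.k_hyd < 0:
            raise ValueError("k_pol and k_hyd must be >= 0")
        if self.C_tot <= 0:
            raise ValueError("C_tot must be > 0")
        if self.l_max is not None and self.l_max < 1:
            raise ValueError("l_max must be >= 1 or None")
        if self.complement_orientation not in ("antiparallel", "parallel", "either"):
            raise ValueError(
                "complement_orientation: 'antiparallel', 'parallel' or 'either'")
        if self.template_counting not in ("per_strand", "per_site"):
            raise ValueError("template_counting: 'per_strand' or 'per_site'")
        object.__setattr__(self, "monomer_alphabet", tuple(self.monomer_alphabet))
        object.__setattr__(self, "bond_alphabet", tuple(self.bond_alphabet))
        klig = {t: float(v) for t, v in dict(self.k_lig).items()}
        for t in self.uniform_types:
            klig.setdefault(t, 0.0)
        unknown = set(klig) - set(self.uniform_types)
        if unknown:
            raise ValueError(f"k_lig keys {sorted(unknown)} not valid uniform types")
        if any(v < 0 for v in klig.values()):
            raise ValueError("k_lig rates must be >= 0")
        object.__setattr__(self, "k_lig", klig)
        object.__setattr__(self, "k_int", _as_matrix(self.k_int, self.monomer_alphabet))
        if any(v < 0 for v in self.k_int.values()):
            raise ValueError("k_int rates must be >= 0")
        if self.variant == "regioselectivity":
            w = self.pol_bond_weights
            if w is None:
                w = {b: 0.5 for b in self.bond_alphabet}
            w = {b: float(w.get(b, 0.0)) for b in self.bond_alphabet}
            if any(v < 0 for v in w.values()):
                raise ValueError("pol_bond_weights must be >= 0")
            object.__setattr__(self, "pol_bond_weights", w)
        elif self.pol_bond_weights is not None:
            raise ValueError("pol_bond_weights is regioselectivity-only")
        if self.variant == "chirality":
            vals = {self.k_lig[t] for t in self.monomer_alphabet}
            if len(vals) > 1:
                raise ValueError(
                    "chirality variant requires exactly symmetric k_lig; "
                    "use monomer_selection for asymmetric rates"
                )
            ints = {self.k_int[(a, b)] for a in self.monomer_alphabet
                    for b in self.monomer_alphabet if a != b}
            if len(ints) > 1:
                raise ValueError("chirality variant requires symmetric k_int")

    # ------------------------------------------------------------------
    @property
    def uniform_types(self) -> tuple[str, ...]:
        """Labels of the uniform-strand classes that can act as templates."""
        if self.variant == "regioselectivity":
            return self.bond_alphabet
        if self.variant == "chirality_basepair":
            return CHIRALITY_MARKS
        return self.monomer_alphabet

    @property
    def has_bonds(self) -> bool:
        return self.variant == "regioselectivity"

    def monomer_type(self, symbol: str) -> str:
        """Uniform-type label contributed by a single monomer symbol."""
        if self.variant == "chirality_basepair":
            return symbol[0]
        if self.variant == "regioselectivity":
            raise ValueError("bond types are carried by bonds, not monomers")
        return symbol

    def with_klig(self, k_lig) -> "ModelSpec":
        """Copy of this spec with the ligation rate(s) replaced.

        A scalar sets every uniform type to the same value; a mapping is
        merged over the existing one.
        """
        if np.isscalar(k_lig):
            new = {t: float(k_lig) for t in self.uniform_types}
        else:
            new = {**self.k_lig, **{t: float(v) for t, v in dict(k_lig).items()}}
        return replace(self, k_lig=new)

    def with_Ctot(self, C_tot: float) -> "ModelSpec":
        return replace(self, C_tot=float(C_tot))

    def without_interconversion(self) -> "ModelSpec":
        return replace(self, k_int=0.0)


# ----------------------------------------------------------------------
# Preset constructors: the shipped defaults are the study conditions
# (C_tot = 10, k_pol = k_hyd = k_int = 1, l_max = 6).


def chirality_model(k_lig: float = 0.0, *, C_tot: float = 10.0, k_pol: float = 1.0,
                    k_hyd: float = 1.0, k_int: float = 1.0,
                    l_max: int | None = 6) -> ModelSpec:
    """Two-enantiomer (D/L) model with exact mirror symmetry."""
    return ModelSpec(
        variant="chirality", monomer_alphabet=("D", "L"), k_pol=k_pol,
        k_hyd=k_hyd, k_lig={"D": k_lig, "L": k_lig},
        k_int=k_int, C_tot=C_tot, l_max=l_max,
    )


def basepair_model(k_lig: float = 0.0, *, C_tot: float = 10.0, k_pol: float = 1.0,
                   k_hyd: float = 1.0, k_int: float = 1.0, l_max: int | None = 6,
                   complement_orientation: str = "either",
                   template_counting: str = "per_site") -> ModelSpec:
    """Base-explicit model: A,U,G,C in D and L form, complementary templating.

    Interconversion flips chirality of a free monomer without changing its
    base (dA <-> lA etc.).  The default templating convention treats strands
    as carrying no 5'/3' orientation — a template window may align with the
    product in either direction — and counts every matching window as a
    distinct binding site; this is the convention that reproduces the
    reported transition near k_lig = 40 (the oriented per-strand
    alternatives shift it upward and are available through
    ``complement_orientation`` / ``template_counting``).
    """
    alphabet = tuple(f"{m}{b}" for m in CHIRALITY_MARKS for b in BASES)
    kint = {}
    for b in BASES:
        kint[(f"d{b}", f"l{b}")] = float(k_int)
        kint[(f"l{b}", f"d{b}")] = float(k_int)
    return ModelSpec(
        variant="chirality_basepair", monomer_alphabet=alphabet,
        k_pol=k_pol, k_hyd=k_hyd, k_lig={"d": k_lig, "l": k_lig}, k_int=kint,
        C_tot=C_tot, l_max=l_max, complement_orientation=complement_orientation,
        template_counting=template_counting,
    )


def monomer_selection_model(k_lig_R: float = 0.0, k_lig_X=None, *,
                            n_alternatives: int = 1, C_tot: float = 10.0,
                            k_pol: float = 1.0, k_hyd: float = 1.0,
                            k_int_RX=1.0, k_int_XR=1.0,
                            l_max: int | None = 6) -> ModelSpec:
    """R (ribonucleotide) versus one or two alternative monomer types X.

    ``k_lig_X`` defaults to ``k_lig_R`` (the fully symmetric case, identical
    to the chirality problem up to labels).  With two alternatives the same
    ``k_lig_X`` applies to X1 and X2.  ``k_int_RX`` is the R -> X rate and
    ``k_int_XR`` the X -> R rate; interconversion between X1 and X2 uses the
    symmetric mean of the two.
    """
    if k_lig_X is None:
        k_lig_X = k_lig_R
    if n_alternatives == 1:
        alts = ("X",)
    elif n_alternatives == 2:
        alts = ("X1", "X2")
    else:
        raise ValueError("n_alternatives must be 1 or 2")
    alphabet = ("R",) + alts
    klig = {"R": k_lig_R, **{x: k_lig_X for x in alts}}
    kint = {}
    for x in alts:
        kint[("R", x)] = float(k_int_RX)
        kint[(x, "R")] = float(k_int_XR)
    if len(alts) == 2:
        kxx = 0.5 * (float(k_int_RX) + float(k_int_XR))
        kint[(alts[0], alts[1])] = kxx
        kint[(alts[1], alts[0])] = kxx
    return ModelSpec(
        variant="monomer_selection", monomer_alphabet=alphabet, k_pol=k_pol,
        k_hyd=k_hyd, k_lig=klig, k_int=kint, C_tot=C_tot, l_max=l_max,
    )


def regioselectivity_model(k_lig_3: float = 0.0, k_lig_2=None, *,
                           C_tot: float = 10.0, k_pol: float = 1.0,
                           k_hyd: float = 1.0, l_max: int | None = 6,
                           pol_bond_weights=None) -> ModelSpec:
    """Single monomer N with 3'-5' (``3``) and 2'-5' (``2``) backbone bonds.

    There is no interconversion reaction: bond-type numbers change only
    through hydrolysis and re-joining.
    """
    if k_lig_2 is None:
        k_lig_2 = k_lig_3
    return ModelSpec(
        variant="regioselectivity", monomer_alphabet=("N",),
        bond_alphabet=("3", "2"), k_pol=k_pol, k_hyd=k_hyd,
        k_lig={"3": k_lig_3, "2": k_lig_2}, k_int=0.0, C_tot=C_tot,
        l_max=l_max, pol_bond_weights=pol_bond_weights,
    )


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class IntegratorConfig:
    """Settings for the deterministic (reaction-kinetics) integrator.

    The integrator is forward Euler with an adaptive step: ``dt`` is chosen
    each step so that no concentration changes by more than ``rtol_step``
    relative (with absolute floor ``atol_step``), capped at ``dt_max`` and by
    a linear-stability bound.  Steady state is declared when the maximum
    per-unit-time concentration change relative to C_tot stays below
    ``ss_tol`` for ``ss_window`` consecutive steps.
    """

    dt_max: float = 0.05
    rtol_step: float = 0.05
    atol_step: float = 1e-7
    max_time: float = 1e5
    ss_tol: float = 1e-10
    ss_window: int = 100
    check_every: int = 10

    def __post_init__(self):
        if self.dt_max <= 0 or self.ss_tol <= 0 or self.rtol_step <= 0:
            raise ValueError("dt_max, rtol_step and ss_tol must be > 0")


@dataclass(frozen=True)
class MCConfig:
    """Settings for the stochastic fixed-timestep simulation."""

    N_tot: int = 100_000
    V: float = 10_000.0
    dt_init: float = 5e-5
    target_prob: float = 0.05     # adapt dt so max(p_pol, p_lig) stays here
    adapt_every: int = 20
    sample_every: float = 1.0     # model-time cadence of observable samples
    burn_in: float = 50.0
    total_time: float = 250.0
    n_blocks: int = 10            # block averaging for standard errors
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.target_prob < 1):
            raise ValueError("target_prob must be in (0, 1)")
        if self.N_tot < 1 or self.V <= 0:
            raise ValueError("N_tot >= 1 and V > 0 required")
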