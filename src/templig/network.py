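"""Precompiled reaction network for the deterministic kinetics engine.

The network enumerates every strand up to ``l_max``, optionally lumps the
species set over an exact symmetry group (see :mod:`templig.symmetry`), and
flattens all mass-action terms into index arrays so that a time derivative
is a handful of vectorised gather/scatter operations:

* formation entries — one per (product, cut): spontaneous polymerisation at
  ``k_pol`` (``w_b * k_pol`` per bond type in the regioselectivity variant)
  plus, for uniform products, templated ligation at
  ``k_lig * C_i * C_j * C_temp``;
* a sparse template-incidence matrix giving ``C_temp`` for every uniform
  product as a weighted sum over qualifying template classes (self-templating
  included: concentrations are continuum quantities, so a species is never
  excluded from its own template pool);
* hydrolysis gain entries (every parent/cut producing a given fragment);
* templated-consumption entries (reactant side of the ligation terms);
* aggregated spontaneous consumption via cumulative length sums;
* monomer interconversion entries.

Rate constants enter only through :meth:`ReactionNetwork.set_rates`, so one
structure (the expensive part) serves a whole scan over ``k_lig`` or
``C_tot``.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np
import scipy.sparse as sp

from .model import ModelSpec
from .strands import Strand
from .symmetry import BOND_CHARS, MONO_CHARS, canonical, lumping_group

_UNIFORM_MONOMER = -2
_MIXED = -1


class ReactionNetwork:
    """Species classes plus flattened reaction terms for one model structure.

    Two specs share a structure when they differ only in rate constants /
    C_tot; use :meth:`set_rates` to retarget without rebuilding.
    """

    def __init__(self, spec: ModelSpec, group=None):
        if spec.l_max is None:
            raise ValueError("the deterministic engine needs a finite l_max")
        self.spec = spec
        self.group = lumping_group(spec) if group is None else group
        self._structure_key = _structure_key(spec)
        self._build_structure(spec)
        self.set_rates(spec)

    # ------------------------------------------------------------------
    # encoding helpers

    def encode(self, s: Strand) -> str:
        mono = [MONO_CHARS[self._mono_index[m]] for m in s.monomers]
        if not self._has_bonds:
            return "".join(mono)
        out = [mono[0]]
        for b, m in zip(s.bonds, mono[1:]):
            out.append(BOND_CHARS[self._bond_index[b]])
            out.append(m)
        return "".join(out)

    def decode(self, enc: str) -> Strand:
        if not self._has_bonds:
            return Strand(tuple(self._mono_syms[MONO_CHARS.index(c)] for c in enc))
        mono = tuple(self._mono_syms[MONO_CHARS.index(c)] for c in enc[::2])
        bonds = tuple(self._bond_syms[BOND_CHARS.index(c)] for c in enc[1::2])
        return Strand(mono, bonds)

    def class_index(self, s: Strand) -> int:
        """Class index of an arbitrary strand (length <= l_max)."""
        return self.index[canonical(self.encode(s), self.group)]

    # ------------------------------------------------------------------

    def _build_structure(self, spec: ModelSpec) -> None:
        self._has_bonds = spec.has_bonds
        self._mono_syms = spec.monomer_alphabet
        self._bond_syms = spec.bond_alphabet
        self._mono_index = {m: i for i, m in enumerate(spec.monomer_alphabet)}
        self._bond_index = {b: i for i, b in enumerate(spec.bond_alphabet)}
        lmax = spec.l_max
        mono_chars = MONO_CHARS[: len(spec.monomer_alphabet)]
        bond_chars = BOND_CHARS[: len(spec.bond_alphabet)]

        # --- full species, by length -----------------------------------
        fulls_by_len: dict[int, list[str]] = {}
        for n in range(1, lmax + 1):
            if self._has_bonds:
                species = []
                for m in itertools.product(mono_chars, repeat=n):
                    for b in itertools.product(bond_chars, repeat=n - 1):
                        parts = [m[0]]
                        for bb, mm in zip(b, m[1:]):
                            parts.append(bb)
                            parts.append(mm)
                        species.append("".join(parts))
            else:
                species = ["".join(m)
                           for m in itertools.product(mono_chars, repeat=n)]
            fulls_by_len[n] = species
        self.n_full_species = sum(len(v) for v in fulls_by_len.values())

        # --- canonicalisation / classes --------------------------------
        group = self.group
        full_to_canon: dict[str, str] = {}
        canon_set = set()
        for n in range(1, lmax + 1):
            for s in fulls_by_len[n]:
                c = canonical(s, group)
                full_to_canon[s] = c
                canon_set.add(c)
        reps_encoded = sorted(canon_set, key=lambda s: (len(s), s))
        self.reps_encoded = reps_encoded
        self.index = {s: i for i, s in enumerate(reps_encoded)}
        self.n_classes = len(reps_encoded)
        self.full_to_class = {s: self.index[c] for s, c in full_to_canon.items()}
        del full_to_canon

        weight = np.zeros(self.n_classes, dtype=np.int64)
        for s, ci in self.full_to_class.items():
            weight[ci] += 1
        self.weight = weight
        self.length = np.array(
            [self._strand_len(s) for s in reps_encoded], dtype=np.int64)
        self.reps = [self.decode(s) for s in reps_encoded]

        # --- per-class metadata ----------------------------------------
        ucode = np.full(self.n_classes, _MIXED, dtype=np.int64)
        for i, s in enumerate(reps_encoded):
            if self._strand_len(s) == 1:
                ucode[i] = _UNIFORM_MONOMER
            else:
                t = self._uniform_type_enc(s, spec)
                if t is not None:
                    ucode[i] = t
        self.uniform_code = ucode
        self.ee_counts = self._build_ee_counts(spec)

        # --- formation entries -----------------------------------------
        f_out, f_left, f_right, f_bond, f_type, f_trow = [], [], [], [], [], []
        trow_of_class = np.zeros(self.n_classes, dtype=np.int64)  # 0 = sentinel
        templatable = [i for i in range(self.n_classes) if ucode[i] >= 0]
        for row, ci in enumerate(templatable):
            trow_of_class[ci] = row + 1
        for ci, s in enumerate(reps_encoded):
            n = self._strand_len(s)
            if n < 2:
                continue
            trow = trow_of_class[ci]
            ptype = ucode[ci] if ucode[ci] >= 0 else -1
            for cut in range(1, n):
                if self._has_bonds:
                    pos = 2 * cut - 1
                    left, right = s[:pos], s[pos + 1:]
                    bidx = BOND_CHARS.index(s[pos])
                else:
                    left, right = s[:cut], s[cut:]
                    bidx = -1
                f_out.append(ci)
                f_left.append(self.full_to_class[left])
                f_right.append(self.full_to_class[right])
                f_bond.append(bidx)
                f_type.append(ptype)
                f_trow.append(trow)
        self.form_out = np.array(f_out, dtype=np.int64)
        self.form_left = np.array(f_left, dtype=np.int64)
        self.form_right = np.array(f_right, dtype=np.int64)
        self.form_bond = np.array(f_bond, dtype=np.int64)
        self.form_type = np.array(f_type, dtype=np.int64)
        self.form_trow = np.array(f_trow, dtype=np.int64)

        # --- template incidence ----------------------------------------
        rows: dict[int, dict[int, int]] = defaultdict(lambda: defaultdict(int))
        for n in range(1, lmax + 1):
            for t in fulls_by_len[n]:
                tcls = self.full_to_class[t]
                for prod in self._templated_products_enc(t, spec):
                    pcls = self.index.get(prod)
                    if pcls is None:
                        continue  # product string is not a canonical rep
                    r = trow_of_class[pcls]
                    if r:
                        rows[r - 1][tcls] += 1
        n_rows = len(templatable)
        data, ri, cj = [], [], []
        for r, cols in rows.items():
            for c, cnt in cols.items():
                ri.append(r + 1)  # +1: row 0 is the zero sentinel
                cj.append(c)
                data.append(float(cnt))
        self.Tmat = sp.csr_matrix(
            (data, (ri, cj)), shape=(n_rows + 1, self.n_classes))
        self.templatable_classes = np.array(templatable, dtype=np.int64)

        # --- hydrolysis gain entries -----------------------------------
        gains: dict[tuple[int, int], int] = defaultdict(int)
        for ci, s in enumerate(reps_encoded):
            n = self._strand_len(s)
            for lu in range(1, lmax - n + 1):
                for u in fulls_by_len[lu]:
                    if self._has_bonds:
                        for bc in bond_chars:
                            gains[(ci, self.full_to_class[s + bc + u])] += 1
                            gains[(ci, self.full_to_class[u + bc + s])] += 1
                    else:
                        gains[(ci, self.full_to_class[s + u])] += 1
                        gains[(ci, self.full_to_class[u + s])] += 1
        self.gain_out = np.array([k[0] for k in gains], dtype=np.int64)
        self.gain_src = np.array([k[1] for k in gains], dtype=np.int64)
        self.gain_cnt = np.array(list(gains.values()), dtype=np.float64)

        # --- templated consumption entries -----------------------------
        # uniform full species per (type, length)
        fulls_uniform: dict[tuple[int, int], list[str]] = defaultdict(list)
        for n in range(1, lmax + 1):
            for s in fulls_by_len[n]:
                for t in self._compat_types_enc(s, spec):
                    fulls_uniform[(t, n)].append(s)
        tcons: dict[tuple[int, int, int, int], int] = defaultdict(int)
        for ci, s in enumerate(reps_encoded):
            n = self._strand_len(s)
            for tau in self._compat_types_enc(s, spec):
                for lu in range(1, lmax - n + 1):
                    for u in fulls_uniform[(tau, lu)]:
                        for prod in self._join_enc(s, u, tau), self._join_enc(u, s, tau):
                            pcls = self.full_to_class[prod]
                            r = trow_of_class[pcls]
                            ucls = self.full_to_class[u]
                            tcons[(ci, ucls, int(r), tau)] += 1
        self.tc_i = np.array([k[0] for k in tcons], dtype=np.int64)
        self.tc_j = np.array([k[1] for k in tcons], dtype=np.int64)
        self.tc_trow = np.array([k[2] for k in tcons], dtype=np.int64)
        self.tc_type = np.array([k[3] for k in tcons], dtype=np.int64)
        self.tc_cnt = np.array(list(tcons.values()), dtype=np.float64)

        # --- interconversion -------------------------------------------
        mono_cls, mono_sym = [], []
        for ci, s in enumerate(reps_encoded):
            if self._strand_len(s) == 1:
                mono_cls.append(ci)
                mono_sym.append(MONO_CHARS.index(s))
        self.mono_classes = np.array(mono_cls, dtype=np.int64)
        self.mono_sym = np.array(mono_sym, dtype=np.int64)
        # class index of every *full* monomer symbol
        self.full_mono_class = np.array(
            [self.full_to_class[MONO_CHARS[i]]
             for i in range(len(spec.monomer_alphabet))], dtype=np.int64)

        # remaining partner length for spontaneous consumption
        self.Lrem = np.clip(lmax - self.length, 0, lmax)

        # nucleotide-count mass vector
        self.mass_vector = (self.length * self.weight).astype(np.float64)

    # ------------------------------------------------------------------
    # encoded-string analysis helpers

    def _strand_len(self, s: str) -> int:
        return (len(s) + 1) // 2 if self._has_bonds else len(s)

    def _uniform_type_enc(self, s: str, spec: ModelSpec):
        """Uniform-type index of an encoded oligomer, or None if mixed."""
        if self._has_bonds:
            bonds = s[1::2]
            if bonds and bonds.count(bonds[0]) == len(bonds):
                return BOND_CHARS.index(bonds[0])
            return None
        if spec.variant == "chirality_basepair":
            marks = [MONO_CHARS.index(c) // 4 for c in s]
            return marks[0] if len(set(marks)) == 1 else None
        if s.count(s[0]) == len(s):
            return MONO_CHARS.index(s[0])
        return None

    def _compat_types_enc(self, s: str, spec: ModelSpec) -> tuple[int, ...]:
        """Uniform types an encoded strand can ligate as (monomers: all)."""
        if self._has_bonds and self._strand_len(s) == 1:
            return tuple(range(len(spec.bond_alphabet)))
        t = (self._uniform_type_enc(s, spec)
             if self._strand_len(s) > 1 else self._monomer_type_enc(s, spec))
        return () if t is None else (t,)

    def _monomer_type_enc(self, s: str, spec: ModelSpec) -> int:
        if spec.variant == "chirality_basepair":
            return MONO_CHARS.index(s) // 4
        return MONO_CHARS.index(s)

    def _join_enc(self, a: str, b: str, tau: int) -> str:
        if self._has_bonds:
            return a + BOND_CHARS[tau] + b
        return a + b

    def _templated_products_enc(self, t: str, spec: ModelSpec):
        """Full product strings whose formation strand ``t`` templates.

        Under per_strand counting each product appears at most once; under
        per_site counting a product is repeated once per alignment site, so
        the incidence accumulation weights templates by site multiplicity.
        """
        lmax = spec.l_max
        per_site = spec.template_counting == "per_site"
        out: list[str] = []
        if self._has_bonds:
            bonds = t[1::2]
            mchar = t[0]  # single monomer type in this variant
            i = 0
            while i < len(bonds):
                j = i
                while j < len(bonds) and bonds[j] == bonds[i]:
                    j += 1
                run = j - i
                bc = bonds[i]
                for q in range(2, min(run + 1, lmax) + 1):
                    mult = run - q + 2 if per_site else 1  # q-1 bonds needed
                    out.extend([mchar + (bc + mchar) * (q - 1)] * mult)
                i = j
        elif spec.variant == "chirality_basepair":
            marks = [MONO_CHARS.index(c) // 4 for c in t]
            comp = {0: 1, 1: 0, 2: 3, 3: 2}  # base indices: A<->U, G<->C
            orientation = spec.complement_orientation
            i = 0
            n = len(t)
            while i < n:
                j = i
                while j < n and marks[j] == marks[i]:
                    j += 1
                mark = marks[i]
                for a in range(i, j - 1):
                    for b in range(a + 2, min(j, a + lmax) + 1):
                        window = t[a:b]
                        pb = [comp[MONO_CHARS.index(c) % 4] for c in window]
                        prods = []
                        if orientation in ("parallel", "either"):
                            prods.append(pb)
                        if orientation in ("antiparallel", "either"):
                            prods.append(pb[::-1])
                        for p in prods:
                            out.append(
                                "".join(MONO_CHARS[4 * mark + x] for x in p))
                i = j
        else:
            # chirality / monomer_selection: runs of identical monomers
            i = 0
            n = len(t)
            while i < n:
                j = i
                while j < n and t[j] == t[i]:
                    j += 1
                run = j - i
                for q in range(2, min(run, lmax) + 1):
                    mult = run - q + 1 if per_site else 1
                    out.extend([t[i] * q] * mult)
                i = j
        return out if per_site else set(out)

    def _build_ee_counts(self, spec: ModelSpec) -> np.ndarray | None:
        """Per-class counts of the two 'poles' used for the excess observable.

        Nucleotide counts per uniform type for two-type monomer variants
        (chirality: D/L; base-explicit: d/l marks; two-monomer selection),
        bond counts per bond type for regioselectivity.  None when the
        variant has more than two uniform types.
        """
        types = spec.uniform_types
        if len(types) != 2:
            return None
        counts = np.zeros((2, self.n_classes), dtype=np.float64)
        for ci, s in enumerate(self.reps_encoded):
            if self._has_bonds:
                bonds = s[1::2]
                for k in range(2):
                    counts[k, ci] = bonds.count(BOND_CHARS[k])
            elif spec.variant == "chirality_basepair":
                idx = [MONO_CHARS.index(c) // 4 for c in s]
                counts[0, ci] = sum(1 for x in idx if x == 0)
                counts[1, ci] = len(idx) - counts[0, ci]
            else:
                counts[0, ci] = s.count(MONO_CHARS[0])
                counts[1, ci] = s.count(MONO_CHARS[1])
        return counts

    # ------------------------------------------------------------------
    # rates

    def set_rates(self, spec: ModelSpec) -> None:
        """Load the rate constants of ``spec`` (same structure) into the tables."""
        if _structure_key(spec) != self._structure_key:
            raise ValueError("spec is structurally incompatible with this network")
        self.spec = spec
        kp, kh = spec.k_pol, spec.k_hyd
        if self._has_bonds:
            w = np.array([spec.pol_bond_weights[b] for b in spec.bond_alphabet])
            self.form_spont = kp * w[self.form_bond]
            self.wsum = float(w.sum())
        else:
            self.form_spont = np.full(self.form_out.shape, kp)
            self.wsum = 1.0
        klig_by_type = np.array(
            [spec.k_lig[t] for t in spec.uniform_types], dtype=np.float64)
        self.form_klig = np.where(
            self.form_type >= 0, klig_by_type[np.clip(self.form_type, 0, None)], 0.0)
        self.tc_klig = klig_by_type[self.tc_type]
        self.k_hyd = float(kh)
        self.k_pol = float(kp)
        # interconversion: gains (dst_class, src_class, rate) and per-class loss
        gd, gs, gr = [], [], []
        loss = np.zeros(self.n_classes)
        syms = spec.monomer_alphabet
        for ci, a in zip(self.mono_classes, self.mono_sym):
            for b_idx, b in enumerate(syms):
                if b == syms[a]:
                    continue
                r_in = spec.k_int[(b, syms[a])]
                if r_in > 0:
                    gd.append(ci)
                    gs.append(self.full_mono_class[b_idx])
                    gr.append(r_in)
                loss[ci] += spec.k_int[(syms[a], b)]
        self.int_dst = np.array(gd, dtype=np.int64)
        self.int_src = np.array(gs, dtype=np.int64)
        self.int_rate = np.array(gr, dtype=np.float64)
        self.int_loss = loss

    # ------------------------------------------------------------------

    def template_concentrations(self, C: np.ndarray) -> np.ndarray:
        """C_temp for every templatable class, as the sentinel-padded row vector."""
        return self.Tmat.dot(C)

    def derivative(self, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Time derivative dC/dt and the per-class loss coefficient lambda.

        lambda_i (total consumption rate per unit concentration of class i)
        bounds the fastest local decay and is used for the Euler stability
        cap.
        """
        n = self.n_classes
        tv = self.Tmat.dot(C)
        form_rate = (self.form_spont + self.form_klig * tv[self.form_trow]) \
            * C[self.form_left] * C[self.form_right]
        dC = np.bincount(self.form_out,
                         weights=form_rate - self.k_hyd * C[self.form_out],
                         minlength=n)
        dC += self.k_hyd * np.bincount(
            self.gain_out, weights=self.gain_cnt * C[self.gain_src], minlength=n)
        # aggregated spontaneous consumption
        lensum = np.bincount(self.length, weights=self.weight * C,
                             minlength=self.spec.l_max + 1)
        scum = np.cumsum(lensum)
        spont_coeff = 2.0 * self.k_pol * self.wsum * scum[self.Lrem]
        spont_coeff[self.Lrem < 1] = 0.0
        # templated consumption
        tc_coeff = np.bincount(
            self.tc_i,
            weights=self.tc_klig * self.tc_cnt * C[self.tc_j] * tv[self.tc_trow],
            minlength=n)
        lam = self.k_hyd * (self.length - 1) + spont_coeff + tc_coeff + self.int_loss
        dC -= (spont_coeff + tc_coeff + self.int_loss) * C
        if self.int_dst.size:
            dC += np.bincount(self.int_dst, weights=self.int_rate * C[self.int_src],
                              minlength=n)
        return dC, lam

    def total_nucleotides(self, C: np.ndarray) -> float:
        return float(self.mass_vector @ C)


def _structure_key(spec: ModelSpec):
    return (spec.variant, spec.monomer_alphabet, spec.bond_alphabet,
            spec.l_max, spec.complement_orientation, spec.template_counting)
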