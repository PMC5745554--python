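"""Strand algebra, species enumeration and template-qualification rules."""

import pytest
from hypothesis import given, settings, strategies as st

import templig as tl
from templig.strands import (Strand, catalyzed_products, check_strand, concat,
                             enumerate_species, hydrolysis_products,
                             is_uniform, relabel, strand_from_str,
                             strand_to_str, template_pool_size,
                             template_qualifies, templates_product,
                             uniform_types)


def S(text):
    """Shorthand: chirality/monomer-selection strand from a plain string."""
    return Strand(tuple(text))


CHI = tl.chirality_model()
REG = tl.regioselectivity_model()
BP = tl.basepair_model()


class TestStrandInvariants:
    def test_needs_at_least_one_monomer(self):
        with pytest.raises(ValueError):
            Strand(())

    def test_bond_count_must_be_n_minus_1(self):
        with pytest.raises(ValueError):
            Strand(("N", "N", "N"), ("3",))
        Strand(("N", "N", "N"), ("3", "2"))  # fine

    def test_alphabet_checked_against_spec(self):
        with pytest.raises(ValueError):
            check_strand(S("DQ"), CHI)
        with pytest.raises(ValueError):
            check_strand(S("DD"), REG)  # missing bond symbols


class TestConcatHydrolysis:
    def test_concat_examples(self):
        assert concat(S("LL"), S("LLL")) == S("LLLLL")
        assert concat(S("D"), S("D")) == S("DD")
        tri = concat(Strand(("N", "N"), ("3",)), Strand(("N",)), new_bond="2")
        assert tri == Strand(("N", "N", "N"), ("3", "2"))

    def test_concat_order_matters(self):
        assert concat(S("D"), S("L")) != concat(S("L"), S("D"))

    def test_bond_symbol_required_iff_bonds_present(self):
        with pytest.raises(ValueError):
            concat(Strand(("N", "N"), ("3",)), Strand(("N",)))  # missing bond

    def test_hydrolysis_example(self):
        left, right = hydrolysis_products(S("DLLLL"), 0)
        assert (left, right) == (S("D"), S("LLLL"))

    def test_pentamer_has_four_bonds(self):
        s = S("DDDDD")
        for k in range(4):
            hydrolysis_products(s, k)
        for bad in (-1, 4):
            with pytest.raises(IndexError):
                hydrolysis_products(s, bad)

    @given(st.text(alphabet="DL", min_size=2, max_size=8).map(S),
           st.data())
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_chirality(self, s, data):
        k = data.draw(st.integers(0, s.n - 2))
        left, right = hydrolysis_products(s, k)
        assert concat(left, right) == s

    @given(st.lists(st.sampled_from("32"), min_size=1, max_size=6),
           st.data())
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_regioselectivity(self, bonds, data):
        s = Strand(("N",) * (len(bonds) + 1), tuple(bonds))
        k = data.draw(st.integers(0, s.n - 2))
        left, right = hydrolysis_products(s, k)
        assert concat(left, right, new_bond=s.bonds[k]) == s


class TestUniformity:
    @pytest.mark.parametrize("text,expect", [
        ("LLLLL", True), ("DLLLL", False), ("D", True), ("DL", False)])
    def test_chirality_uniformity(self, text, expect):
        assert is_uniform(S(text), CHI) is expect

    def test_regio_bond_uniformity(self):
        assert not is_uniform(Strand(("N",) * 4, ("3", "3", "2")), REG)
        assert is_uniform(Strand(("N", "N"), ("2",)), REG)
        # a bare monomer is compatible with both bond types
        assert uniform_types(Strand(("N",)), REG) == ("3", "2")

    def test_basepair_uniformity_ignores_bases(self):
        assert is_uniform(Strand(("dA", "dG", "dC")), BP)
        assert not is_uniform(Strand(("dA", "lA")), BP)


class TestTemplateQualification:
    def test_embedded_run_qualifies(self):
        assert template_qualifies(S("DLLLLLLDDD"), S("LL"), S("LLL"), CHI)

    def test_run_shorter_than_product_fails(self):
        assert not template_qualifies(S("LLLL"), S("LL"), S("LLL"), CHI)

    def test_mixed_substrate_never_qualifies(self):
        for template in (S("LLLLLL"), S("DLLLLL")):
            assert not template_qualifies(template, S("DL"), S("L"), CHI)

    def test_regio_pentamer_needs_four_bond_run(self):
        i = Strand(("N", "N"), ("3",))
        j = Strand(("N", "N", "N"), ("3", "3"))
        good = Strand(("N",) * 5, ("3",) * 4)
        short = Strand(("N",) * 5, ("3", "3", "3", "2"))
        assert template_qualifies(good, i, j, REG)
        assert not template_qualifies(short, i, j, REG)
        prods = catalyzed_products(good, i, j, REG)
        assert [p.bonds for p in prods] == [("3",) * 4]

    def test_basepair_needs_complement(self):
        i, j = Strand(("dA",)), Strand(("dG",))
        anti = tl.basepair_model(complement_orientation="antiparallel")
        par = tl.basepair_model(complement_orientation="parallel")
        # product dA-dG; antiparallel complement run is dC-dU
        assert templates_product(Strand(("dC", "dU")), concat(i, j), anti)
        assert not templates_product(Strand(("dU", "dC")), concat(i, j), anti)
        assert not templates_product(Strand(("lC", "lU")), concat(i, j), anti)
        assert templates_product(Strand(("dU", "dC")), concat(i, j), par)
        # the default convention accepts both alignment directions
        for t in (Strand(("dC", "dU")), Strand(("dU", "dC"))):
            assert templates_product(t, concat(i, j), BP)
        assert not templates_product(Strand(("dC", "dC")), concat(i, j), BP)

    def test_site_counting(self):
        from templig.strands import template_match_count
        # a 6-long L run offers two alignment windows for a pentamer product
        assert template_match_count(S("LLLLLL"), S("LLLLL"), CHI) == 2
        assert template_match_count(S("LLLLLD"), S("LLLLL"), CHI) == 1
        # palindromic complement: both alignment directions match the same
        # window and count as two sites under the default convention
        prod = Strand(("dA", "dA"))
        assert template_match_count(Strand(("dU", "dU")), prod, BP) == 2

    def test_relabel_symmetry_preserves_qualification(self):
        swap = {"D": "L", "L": "D"}
        species = enumerate_species(tl.chirality_model(l_max=4))
        pairs = [(S("L"), S("L")), (S("LL"), S("L")), (S("DD"), S("D")),
                 (S("LL"), S("LL"))]
        for t in species:
            for i, j in pairs:
                assert template_qualifies(t, i, j, CHI) == template_qualifies(
                    relabel(t, swap), relabel(i, swap), relabel(j, swap), CHI)


class TestEnumeration:
    def test_chirality_counts(self):
        species = enumerate_species(CHI)
        assert len(species) == 126           # sum of 2^n, n = 1..6
        assert sum(1 for s in species if s.n == 6) == 64

    def test_l_max_1_is_monomers_only(self):
        assert enumerate_species(tl.chirality_model(l_max=1)) == [S("D"), S("L")]

    def test_regio_l_max_3(self):
        species = enumerate_species(tl.regioselectivity_model(l_max=3))
        assert len(species) == 7             # 1 + 2 + 4 bond strings

    def test_canonical_order(self):
        species = enumerate_species(tl.chirality_model(l_max=2))
        assert species == [S("D"), S("L"), S("DD"), S("DL"), S("LD"), S("LL")]

    def test_unbounded_rejected(self):
        with pytest.raises(ValueError):
            enumerate_species(tl.chirality_model(l_max=None))


class TestTemplatePool:
    def test_hexamer_pool_is_itself(self):
        assert template_pool_size(S("LLLLLL"), CHI) == 1

    def test_pentamer_pool(self):
        # strands containing a 5-long L run among lengths 5 and 6
        assert template_pool_size(S("LLLLL"), CHI) == 4

    def test_product_longer_than_l_max(self):
        assert template_pool_size(S("L" * 7), CHI) == 0

    def test_mirror_symmetric(self):
        for n in range(2, 7):
            assert (template_pool_size(S("L" * n), CHI)
                    == template_pool_size(S("D" * n), CHI))


class TestSerialization:
    def test_grammar_examples(self):
        assert strand_to_str(S("DLLDL"), CHI) == "DLLDL"
        s = Strand(("N", "N", "N", "N"), ("3", "3", "2"))
        assert strand_to_str(s, REG) == "N3N3N2N"
        assert strand_to_str(Strand(("dA", "lG")), BP) == "dA lG"

    @pytest.mark.parametrize("spec,l_max", [(CHI, 4), (REG, 4), (BP, 2)])
    def test_roundtrip_all_species(self, spec, l_max):
        import dataclasses
        small = dataclasses.replace(spec, l_max=l_max)
        for s in enumerate_species(small):
            assert strand_from_str(strand_to_str(s, small), small) == s

    def test_parse_rejects_bad_symbols(self):
        with pytest.raises(ValueError):
            strand_from_str("DQL", CHI)
        with pytest.raises(ValueError):
            strand_from_str("N3N2", REG)  # even token count
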