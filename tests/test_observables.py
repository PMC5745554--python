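"""Nucleotide fractions and excess observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import templig as tl
from templig.kinetics import ConcentrationState, KineticsEngine, biased_monomer_state
from templig.network import ReactionNetwork
from templig.observables import fractions, length_distribution
from templig.strands import Strand


def state_from(net, conc: dict[str, float]) -> ConcentrationState:
    C = np.zeros(net.n_classes)
    for text, v in conc.items():
        C[net.class_index(Strand(tuple(text)))] = v
    return ConcentrationState(C)


@pytest.fixture(scope="module")
def chi_net():
    return ReactionNetwork(tl.chirality_model(k_lig=1.0))


def test_worked_fraction_example(chi_net):
    # C_tot = 10 with {DD: 1, DL: 1, D: 3, L: 3}
    fr = fractions(state_from(chi_net, {"DD": 1, "DL": 1, "D": 3, "L": 3}),
                   chi_net)
    assert fr.phi["D"] == pytest.approx(0.2)
    assert fr.phi["L"] == 0.0
    assert fr.phi_M == pytest.approx(0.2)
    assert fr.monomer_fraction == pytest.approx(0.6)


def test_oligomer_excess_example(chi_net):
    # 6 D-nucleotides vs 4 L-nucleotides in oligomers -> ee = 0.2
    fr = fractions(state_from(chi_net, {"DD": 3, "LL": 2}), chi_net)
    assert fr.ee == pytest.approx((6 - 4) / (6 + 4))


def test_all_monomer_state_has_zero_phi(chi_net):
    fr = fractions(state_from(chi_net, {"D": 5, "L": 5}), chi_net)
    assert fr.phi == {"D": 0.0, "L": 0.0}
    assert fr.phi_M == 0.0
    assert fr.monomer_fraction == pytest.approx(1.0)
    assert fr.ee == 0.0   # no oligomer nucleotides at all


_NET_CACHE: list = []


@given(values=st.lists(st.floats(0.0, 5.0), min_size=126, max_size=126))
@settings(max_examples=15, deadline=None)
def test_fractions_normalise(values):
    if not _NET_CACHE:
        _NET_CACHE.append(ReactionNetwork(tl.chirality_model(k_lig=1.0)))
    net = _NET_CACHE[0]
    C = np.array(values)
    fr = fractions(ConcentrationState(C), net)
    # monomer_fraction is constructed as the remainder, so the classes
    # always account for every nucleotide
    total = sum(fr.phi.values()) + fr.phi_M + fr.monomer_fraction
    assert total == pytest.approx(1.0, abs=1e-12)
    assert all(v >= 0 for v in fr.phi.values())
    assert fr.ee is None or -1.0 <= fr.ee <= 1.0


def test_monomer_excess_zero_with_interchange_on():
    """Direct interchange equalises free monomers, so their excess vanishes
    even deep in the broken phase."""
    eng = KineticsEngine(tl.chirality_model(k_lig=10.0))
    state, _ = eng.run_to_steady_state(biased_monomer_state(eng.net))
    fr = fractions(state, eng.net)
    assert abs(fr.ee) > 0.5            # oligomers strongly biased
    assert abs(fr.monomer_ee) < 1e-6   # monomers not


def test_regio_bond_excess():
    spec = tl.regioselectivity_model(l_max=3)
    net = ReactionNetwork(spec)
    C = np.zeros(net.n_classes)
    C[net.class_index(Strand(("N", "N", "N"), ("3", "3")))] = 2.0   # 4 bonds 3
    C[net.class_index(Strand(("N", "N"), ("2",)))] = 1.0            # 1 bond 2
    fr = fractions(ConcentrationState(C), net)
    assert fr.ee == pytest.approx((4 - 1) / (4 + 1))
    assert fr.phi["3"] == pytest.approx(0.6)
    assert fr.phi["2"] == pytest.approx(0.2)


def test_length_distribution_totals(chi_net):
    st_ = state_from(chi_net, {"D": 2, "L": 1, "DD": 0.5, "DLLDLL": 0.25})
    dist = length_distribution(st_, chi_net)
    assert dist[1] == pytest.approx(3.0)
    assert dist[2] == pytest.approx(0.5)
    assert dist[6] == pytest.approx(0.25)
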