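"""Deterministic engine: elementary steps, conservation, equilibria."""

import numpy as np
import pytest

import templig as tl
from templig.closedform import equilibrium_state
from templig.kinetics import (ConcentrationState, KineticsEngine,
                              biased_monomer_state, pure_monomer_state,
                              uniform_monomer_state)
from templig.model import IntegratorConfig
from templig.observables import fractions
from templig.strands import Strand, relabel


def test_first_step_dimer_formation_rate():
    """From monomers only, one step gives dC_dimer = k_pol C_i C_j dt."""
    spec = tl.chirality_model(k_lig=0.0)
    eng = KineticsEngine(spec)
    net = eng.net
    state = biased_monomer_state(net, f_majority=0.6)
    dt = 1e-4
    cD = state.C[net.class_index(Strand(("D",)))]
    cL = state.C[net.class_index(Strand(("L",)))]
    nxt = eng.step(state, dt=dt)
    assert nxt.C[net.class_index(Strand(("D", "D")))] == pytest.approx(
        spec.k_pol * cD * cD * dt)
    assert nxt.C[net.class_index(Strand(("D", "L")))] == pytest.approx(
        spec.k_pol * cD * cL * dt)


def test_interconversion_step_rate():
    """dC_L = -dC_D = k_int (C_D - C_L) dt for free monomers."""
    spec = tl.chirality_model(k_lig=0.0, k_pol=0.0, C_tot=10.0)
    eng = KineticsEngine(spec)
    net = eng.net
    C = np.zeros(net.n_classes)
    iD = net.class_index(Strand(("D",)))
    iL = net.class_index(Strand(("L",)))
    C[iD], C[iL] = 6.0, 4.0
    dt = 1e-3
    nxt = eng.step(ConcentrationState(C), dt=dt)
    assert nxt.C[iL] - 4.0 == pytest.approx(2.0 * dt)
    assert nxt.C[iD] - 6.0 == pytest.approx(-2.0 * dt)


def test_symmetric_state_stays_symmetric():
    spec = tl.chirality_model(k_lig=8.0)
    eng = KineticsEngine(spec)
    net = eng.net
    s = uniform_monomer_state(net)
    for _ in range(200):
        s = eng.step(s)
    swap = {"D": "L", "L": "D"}
    for i, rep in enumerate(net.reps):
        j = net.class_index(relabel(rep, swap))
        assert s.C[i] == pytest.approx(s.C[j], rel=1e-12, abs=1e-300)


@pytest.mark.parametrize("spec", [
    tl.chirality_model(k_lig=0.0),
    tl.monomer_selection_model(0.0, k_int_RX=2.0, k_int_XR=1.0, l_max=5),
    tl.regioselectivity_model(0.0, l_max=5),
], ids=["chirality", "monomer_selection", "regioselectivity"])
def test_detailed_balance_steady_state(spec):
    """k_lig = 0 steady state equals the closed-form equilibrium to 1e-6."""
    eng = KineticsEngine(spec)
    state, rep = eng.run_to_steady_state(uniform_monomer_state(eng.net))
    assert rep.converged
    eq = equilibrium_state(eng.net)
    rel = np.abs(state.C - eq.C) / eq.C
    assert rel.max() < 1e-6
    assert rep.mass_error < 1e-9


def test_monomer_ratio_matches_interconversion_equilibrium():
    """C_X / C_R = k_int(R->X) / k_int(X->R) for free monomers."""
    spec = tl.monomer_selection_model(0.0, k_int_RX=3.0, k_int_XR=1.5,
                                      k_pol=0.0, l_max=3)
    eng = KineticsEngine(spec)
    state, rep = eng.run_to_steady_state(pure_monomer_state(eng.net, "R"))
    net = eng.net
    cR = state.C[net.class_index(Strand(("R",)))]
    cX = state.C[net.class_index(Strand(("X",)))]
    assert rep.converged
    assert cX / cR == pytest.approx(3.0 / 1.5, rel=1e-8)


def test_mass_conserved_through_transition_run():
    spec = tl.chirality_model(k_lig=10.0)
    eng = KineticsEngine(spec)
    state, rep = eng.run_to_steady_state(biased_monomer_state(eng.net))
    assert rep.mass_error < 1e-9
    assert eng.net.total_nucleotides(state.C) == pytest.approx(spec.C_tot,
                                                               rel=1e-9)


def test_steady_state_independent_of_step_size():
    """Halving the dt cap leaves steady-state observables unchanged (<1e-6):
    fixed points of the Euler map are exact steady states at any dt."""
    spec = tl.chirality_model(k_lig=10.0)
    obs = []
    for dt_max in (0.05, 0.025):
        eng = KineticsEngine(spec, IntegratorConfig(dt_max=dt_max))
        state, rep = eng.run_to_steady_state(biased_monomer_state(eng.net))
        assert rep.converged
        obs.append(fractions(state, eng.net))
    for key, v in obs[0].as_dict().items():
        assert abs(v - obs[1].as_dict()[key]) < 1e-6


def test_bias_decays_below_transition_grows_above():
    spec = tl.chirality_model()
    eng = KineticsEngine(spec.with_klig(1.0))
    state, _ = eng.run_to_steady_state(biased_monomer_state(eng.net))
    fr = fractions(state, eng.net)
    assert abs(fr.ee) < 1e-6
    assert fr.phi["D"] == pytest.approx(fr.phi["L"], abs=1e-6)
    eng.with_spec(spec.with_klig(10.0))
    state, _ = eng.run_to_steady_state(biased_monomer_state(eng.net))
    fr = fractions(state, eng.net)
    assert fr.ee > 0.5
    assert fr.phi["D"] > fr.phi["L"]


def test_two_start_protocol_mono_vs_bistable():
    spec = tl.chirality_model(k_lig=1.0)
    eng = KineticsEngine(spec)
    res = eng.run_two_start_protocol()
    eeD = fractions(res["D"][0], eng.net).ee
    eeL = fractions(res["L"][0], eng.net).ee
    assert abs(eeD) < 1e-6 and abs(eeL) < 1e-6  # same symmetric solution

    eng.with_spec(spec.with_klig(10.0))
    res = eng.run_two_start_protocol()
    eeD = fractions(res["D"][0], eng.net).ee
    eeL = fractions(res["L"][0], eng.net).ee
    assert eeD > 0.5 and eeL < -0.5             # mirror-image branches
    assert eeD == pytest.approx(-eeL, abs=1e-6)


def test_two_start_monomer_selection_two_branches():
    spec = tl.monomer_selection_model(10.0, 9.0)
    eng = KineticsEngine(spec)
    res = eng.run_two_start_protocol()
    frR = fractions(res["R"][0], eng.net)
    frX = fractions(res["X"][0], eng.net)
    assert frR.phi["R"] > frR.phi["X"]
    assert frX.phi["X"] > frX.phi["R"]          # distinct X-dominant branch


def test_excessive_step_size_is_diagnosed():
    spec = tl.chirality_model(k_lig=0.0)
    eng = KineticsEngine(spec)
    flat = ConcentrationState(np.full(eng.net.n_classes, 1e-3))
    with pytest.raises(RuntimeError, match="step size"):
        eng.step(flat, dt=1e9)
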