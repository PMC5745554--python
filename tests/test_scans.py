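"""Scans, bifurcation detection, branch tracing."""

import pytest

import templig as tl
from templig.model import IntegratorConfig
from templig.scans import (BracketError, branch_persists, find_branch_limit,
                           find_critical, scan_klig, scan_concentration)
from templig.kinetics import KineticsEngine


def test_scan_klig_qualitative_shape():
    """phi_M dominates without templating; strong templating selects one
    enantiomer and depletes mixed strands."""
    res = scan_klig(tl.chirality_model(), [0.0, 10.0])
    lo, hi = res.branches["biased"]
    assert lo.phi_M > max(lo.phi["D"], lo.phi["L"], lo.monomer_fraction)
    assert lo.phi["D"] == pytest.approx(lo.phi["L"], abs=1e-8)
    assert hi.phi["D"] > 5 * hi.phi["L"]
    assert hi.phi_M < lo.phi_M
    assert all(res.converged["biased"])
    df = res.to_dataframe()
    assert len(df) == 2 and set(df["k_lig"]) == {0.0, 10.0}


def test_scan_rejects_bad_grids():
    with pytest.raises(ValueError):
        scan_klig(tl.chirality_model(), [])
    with pytest.raises(ValueError):
        scan_klig(tl.chirality_model(), [2.0, 1.0])


def test_bracket_error_reports_endpoint_excess():
    with pytest.raises(BracketError, match=r"\|ee\|"):
        find_critical(tl.chirality_model(), bracket=(0.2, 1.0), tol=0.2)


def test_fast_classifier_agrees_with_steady_state_criterion(chirality_kc):
    """The accelerated trend classifier and the literal steady-state
    |ee| > 0.01 rule bracket the same transition at coarse tolerance."""
    cfg = IntegratorConfig(ss_tol=1e-9)
    res = find_critical(tl.chirality_model(), bracket=(3.6, 5.6), tol=0.5,
                        cfg=cfg, fast=False)
    assert res.value == pytest.approx(chirality_kc, abs=0.5)


def test_critical_in_concentration(chirality_kc):
    """Symmetry breaking also occurs on a C_tot scan at fixed k_lig."""
    res = find_critical(tl.chirality_model(k_lig=10.0), param="C_tot",
                        bracket=(1.0, 10.0), tol=0.2)
    assert 1.0 < res.value < 10.0
    lo = scan_concentration(tl.chirality_model(k_lig=10.0), [1.0])
    fr = lo.branches["biased"][0]
    assert fr.phi["D"] == pytest.approx(fr.phi["L"], abs=1e-7)


def test_equal_and_opposite_branches_above_transition():
    eng = KineticsEngine(tl.chirality_model(k_lig=10.0))
    res = eng.run_two_start_protocol()
    from templig.observables import fractions
    ee = {t: fractions(state, eng.net).ee for t, (state, _) in res.items()}
    assert ee["D"] > 0.5
    assert abs(ee["D"] + ee["L"]) < 1e-3


def test_branch_limit_brackets_must_straddle():
    def spec_for(k):
        return tl.monomer_selection_model(k_lig_R=k, k_lig_X=0.9 * k)
    with pytest.raises(BracketError):
        find_branch_limit(spec_for, "X", bracket=(8.0, 12.0), tol=0.5)


def test_minority_branch_persistence_flips_with_rate():
    """The X branch collapses at low k_ligR and persists at high k_ligR."""
    def spec_for(k):
        return tl.monomer_selection_model(k_lig_R=k, k_lig_X=0.9 * k)
    eng = KineticsEngine(spec_for(3.0))
    ok_low, _ = branch_persists(eng, "X")
    eng.with_spec(spec_for(10.0))
    ok_high, fr = branch_persists(eng, "X")
    assert not ok_low and ok_high
    assert fr.phi["X"] > fr.phi["R"]


def test_favoured_monomer_branch_exists_at_all_rates():
    """With an equilibrium abundance advantage to X (Eq-(8) bias 2:1) and a
    rate advantage to R, the X branch survives even at low ligation rates,
    while the R branch needs high rates."""
    def spec_for(k):
        return tl.monomer_selection_model(
            k_lig_R=k, k_lig_X=0.5 * k, k_int_RX=2.0, k_int_XR=1.0)
    eng = KineticsEngine(spec_for(2.0))
    okX, _ = branch_persists(eng, "X")
    okR, _ = branch_persists(eng, "R")
    assert okX and not okR
    eng.with_spec(spec_for(25.0))
    okR_hi, _ = branch_persists(eng, "R")
    assert okR_hi


def test_regioselectivity_minority_bond_branch_only_at_high_rates():
    """3'-5'-dominant solutions exist at all rates; the 2'-5' branch only
    above a minimum ligation rate."""
    def spec_for(k):
        return tl.regioselectivity_model(k_lig_3=k, k_lig_2=0.9 * k)
    eng = KineticsEngine(spec_for(3.0))
    ok3, _ = branch_persists(eng, "3")
    ok2, _ = branch_persists(eng, "2")
    assert ok3 and not ok2
    eng.with_spec(spec_for(12.0))
    ok2_hi, fr = branch_persists(eng, "2")
    assert ok2_hi and fr.phi["2"] > fr.phi["3"]


def test_three_monomer_alternative_branches_are_equivalent():
    """With X1 and X2 equivalent (equal rates and interchange), their
    dominant branches are numerically identical up to relabeling."""
    spec = tl.monomer_selection_model(10.0, 9.0, n_alternatives=2)
    eng = KineticsEngine(spec)
    from templig.observables import fractions
    _, fr1 = branch_persists(eng, "X1")
    _, fr2 = branch_persists(eng, "X2")
    assert fr1.phi["X1"] == pytest.approx(fr2.phi["X2"], rel=1e-6)
    assert fr1.phi["R"] == pytest.approx(fr2.phi["R"], rel=1e-6)
    assert fr1.phi["X2"] == pytest.approx(fr2.phi["X1"], rel=1e-6)
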