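"""Stochastic engine: event probabilities, conservation, calibration."""

import numpy as np
import pytest

import templig as tl
from templig.closedform import equilibrium_length_distribution
from templig.model import MCConfig
from templig.montecarlo import (MonteCarloEngine, _match_count,
                                monomer_population)


def small_cfg(**kw):
    base = dict(N_tot=1000, V=100.0, total_time=60.0, burn_in=20.0, seed=7,
                target_prob=0.02)
    base.update(kw)
    return MCConfig(**base)


class TestEventProbabilities:
    def test_polymerisation_and_ligation_formulas(self):
        spec = tl.chirality_model(k_lig=3.0)
        mc = MonteCarloEngine(spec, MCConfig(N_tot=100, V=50.0))
        p = mc.channel_probabilities(N_strands=20, dt=1e-3)
        assert p["pol"] == pytest.approx(19 / 50.0 * 1.0 * 1e-3)
        assert p["lig"] == pytest.approx(19 * 18 / 50.0 ** 2 * 3.0 * 1e-3)

    def test_hydrolysis_probability_for_pentamer(self):
        # a strand of length 5 has 4 bonds: p_hyd = 4 k_hyd dt
        n, k_hyd, dt = 5, 1.0, 1e-3
        assert (n - 1) * k_hyd * dt == pytest.approx(4e-3)

    def test_two_strands_cannot_ligate(self):
        spec = tl.chirality_model(k_lig=100.0)
        mc = MonteCarloEngine(spec, MCConfig(N_tot=2, V=1.0))
        assert mc.channel_probabilities(N_strands=2, dt=1.0)["lig"] == 0.0

    def test_adapt_dt_targets_and_caps(self):
        spec = tl.chirality_model(k_lig=10.0)
        cfg = MCConfig(N_tot=1000, V=100.0, dt_init=5e-5, target_prob=0.05)
        mc = MonteCarloEngine(spec, cfg)
        pop = monomer_population(spec, cfg)
        mc.adapt_dt(pop)
        assert mc.dt <= 2 * cfg.dt_init           # never more than doubling
        for _ in range(30):
            dt_before = mc.dt
            mc.adapt_dt(pop)
            assert mc.dt <= 2 * dt_before
        p = mc.channel_probabilities(pop.N_strands, mc.dt)
        assert max(p.values()) == pytest.approx(cfg.target_prob)
        # fewer strands -> larger admissible dt, same target probability
        dt_full = mc.dt
        pop.strands = pop.strands[:500]
        for _ in range(10):
            mc.adapt_dt(pop)
        assert mc.dt > dt_full
        assert max(mc.channel_probabilities(
            500, mc.dt).values()) == pytest.approx(cfg.target_prob)


def test_probability_guard_halves_dt():
    """Any per-strand probability reaching 1 halves dt and retries."""
    spec = tl.chirality_model(k_lig=0.0)
    cfg = MCConfig(N_tot=200, V=2.0, dt_init=1.0, seed=0)
    mc = MonteCarloEngine(spec, cfg)
    pop = monomer_population(spec, cfg)
    mc.dt = 1.0   # p_pol = 199/2 * 1 >> 1
    mc.step(pop)
    assert mc.dt < 1.0
    assert mc.channel_probabilities(200, mc.dt)["pol"] < 1.0


def test_l_max_vetoes_joins():
    spec = tl.chirality_model(k_lig=0.0, k_hyd=0.0, l_max=2)
    cfg = MCConfig(N_tot=400, V=10.0, total_time=3.0, burn_in=1.0, seed=1)
    res = MonteCarloEngine(spec, cfg).run()
    assert max(s.n for s in res.final_strands()) <= 2


def test_match_count_site_semantics():
    spec = tl.basepair_model()
    # product dA dA (indices 0,0): complement UU both directions
    dU = 1
    assert _match_count((dU, dU), (0, 0), spec) == 2
    assert _match_count((dU, dU, dU), (0, 0), spec) == 4   # two windows x two


def test_nucleotide_count_exactly_conserved():
    spec = tl.chirality_model(k_lig=8.0)
    cfg = small_cfg(total_time=20.0, burn_in=5.0)
    mc = MonteCarloEngine(spec, cfg)
    res = mc.run()   # run() itself asserts conservation at every sample
    total = sum(len(s) for s in res.final_population.strands)
    assert total == cfg.N_tot


def test_same_seed_reproduces_trajectory_bitwise():
    spec = tl.chirality_model(k_lig=5.0)
    runs = [MonteCarloEngine(spec, small_cfg(total_time=15.0)).run()
            for _ in range(2)]
    assert runs[0].trajectory.equals(runs[1].trajectory)


def test_dimerisation_rate_matches_mass_action():
    """Join events from an all-monomer pool occur at rate k_pol C^2 V."""
    spec = tl.chirality_model(k_lig=0.0, k_hyd=0.0, l_max=None)
    cfg = MCConfig(N_tot=4000, V=400.0, dt_init=1e-4, seed=11)
    mc = MonteCarloEngine(spec, cfg)
    pop = monomer_population(spec, cfg)
    dt = 2e-4
    mc.dt = dt
    events = 0
    trials = 0
    for _ in range(40):
        before = pop.N_strands
        mc.step(pop)
        events += before - pop.N_strands     # each join removes one strand
        trials += before
        pop.t = 0.0
    # expected per-strand join probability (strand as left partner)
    p = (cfg.N_tot - 1) / cfg.V * spec.k_pol * dt
    expect = trials * p
    # loose 5-sigma binomial band, plus tolerance for within-step collisions
    sigma = np.sqrt(expect)
    assert abs(events - expect) < 5 * sigma + 0.02 * expect


def test_length_distribution_matches_detailed_balance():
    """k_lig = 0 equilibrium lengths agree with the closed form within 3 SE
    (small systematic first-order-in-dt bias controlled by target_prob)."""
    spec = tl.chirality_model(k_lig=0.0)
    cfg = small_cfg(N_tot=1000, V=100.0, total_time=120.0, burn_in=30.0,
                    target_prob=0.015, seed=3)
    res = MonteCarloEngine(spec, cfg).run()
    mean, se = res.mean_length_distribution()
    pred = equilibrium_length_distribution(spec) * cfg.V
    for n in range(1, 7):
        assert abs(mean[n] - pred[n]) < 3 * se[n] + 0.02 * pred[n], \
            f"length {n}: MC {mean[n]:.1f} +- {se[n]:.1f} vs {pred[n]:.1f}"


def test_unbounded_lengths_supported():
    spec = tl.chirality_model(k_lig=0.0, l_max=None)
    cfg = small_cfg(N_tot=500, V=50.0, total_time=25.0, burn_in=10.0)
    res = MonteCarloEngine(spec, cfg).run()
    lens = [s.n for s in res.final_strands()]
    assert max(lens) > 6   # no cap: strands exceed the kinetics l_max


def test_symmetric_start_breaks_symmetry_above_transition():
    """Fluctuations alone drive |ee| away from zero when k_lig is high:
    no imposed bias, growth seeded purely by interchange noise."""
    spec = tl.chirality_model(k_lig=12.0)
    cfg = small_cfg(N_tot=500, V=50.0, total_time=150.0, burn_in=40.0,
                    target_prob=0.05, seed=5)
    res = MonteCarloEngine(spec, cfg).run()   # exactly equal D/L start
    tr = res.trajectory
    early = tr["ee"].iloc[:10].abs().mean()
    late = tr["ee"].iloc[-20:].abs().mean()
    assert early < 0.1
    assert late > 0.3


def test_either_direction_with_equal_probability():
    """Repeated symmetric-start runs go D- or L-dominant about equally."""
    spec = tl.chirality_model(k_lig=10.0)
    signs = []
    for seed in range(8):
        cfg = MCConfig(N_tot=400, V=40.0, total_time=40.0, burn_in=20.0,
                       target_prob=0.05, seed=seed)
        res = MonteCarloEngine(spec, cfg).run()
        signs.append(np.sign(res.summary()["ee"]))
    ups = sum(1 for s in signs if s > 0)
    # binomial(8, 1/2): both outcomes should occur
    assert 0 < ups < 8
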