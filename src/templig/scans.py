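"""Parameter scans, bifurcation detection, and branch tracing.

The symmetry-breaking transition is located by bisection on a control
parameter (``k_lig`` or ``C_tot``).  A point is classified *broken* when the
steady state reached from a slightly biased all-monomer start (default
0.505/0.495) retains an oligomer excess ``|ee|`` above a threshold (default
0.01), and *symmetric* when the bias decays.  Because the deterministic
trajectories are smooth, the classification can almost always be made long
before full convergence: the integrator is stopped early once ``|ee|``
either exceeds a high-water mark, falls far below the initial bias, or shows
a sustained exponential trend in either direction.  Near the bifurcation the
asymptotic excess rises steeply from zero, so the threshold crossing and the
stability boundary coincide to well within the bisection tolerance.

Branch limits (the smallest control value at which a minority-type solution
still exists) use the two-phase protocol: relax from a pure-type pool with
interconversion off, then enable interconversion and test whether the
starting type remains dominant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import pandas as pd

from .kinetics import (ConcentrationState, KineticsEngine,
                       biased_monomer_state, pure_monomer_state,
                       uniform_monomer_state)
from .model import IntegratorConfig, MCConfig, ModelSpec
from .observables import FractionSummary, fractions


class BracketError(ValueError):
    """The bisection bracket does not straddle the transition."""


def _set_param(spec: ModelSpec, param: str, value: float) -> ModelSpec:
    if param == "k_lig":
        return spec.with_klig(value)
    if param == "C_tot":
        return spec.with_Ctot(value)
    raise ValueError(f"unknown control parameter {param!r}")


# ----------------------------------------------------------------------
# early-exit classification of a biased-start relaxation


@dataclass
class ClassifyOutcome:
    label: str            # "broken" | "symmetric"
    ee_final: float
    t_final: float
    converged: bool
    via: str              # which rule decided


def classify_biased_relaxation(
        engine: KineticsEngine, *, f_bias: float = 0.505,
        majority: str | None = None, threshold: float = 0.01,
        ee_high: float = 0.05, ee_low_factor: float = 0.05,
        trend_burn: float = 60.0, trend_window: float = 15.0,
        trend_eps: float = 5e-3, force_time: float = 400.0,
        fast: bool = True) -> ClassifyOutcome:
    """Relax from the biased monomer start and classify the endpoint.

    The fast path stops as soon as |ee| crosses a high or low water mark or
    shows a sustained exponential trend after ``trend_burn``; at
    ``force_time`` (well past all fast transients) the raw sign of the trend
    decides.  With ``fast=False`` the run always continues to full steady
    state and the plain ``|ee| > threshold`` criterion is applied.
    """
    net = engine.net
    init = biased_monomer_state(net, f_majority=f_bias, majority=majority)
    ee0 = abs(2 * f_bias - 1)
    history: list[tuple[float, float]] = []
    hits = {"grow": 0, "decay": 0}

    def observer(state: ConcentrationState):
        ee = abs(fractions(state, net).ee)
        history.append((state.t, ee))
        if not fast:
            return None
        if ee >= ee_high:
            return "ee_high"
        if ee <= ee0 * ee_low_factor and state.t > 1.0:
            return "ee_low"
        if state.t > trend_burn:
            past = next((e for t, e in reversed(history)
                         if t <= state.t - trend_window), None)
            if past is not None and past > 0:
                r = ee / past
                if state.t > force_time:
                    return "ee_trend_up" if r > 1.0 else "ee_trend_down"
                if r > 1 + trend_eps:
                    hits["grow"] += 1
                    hits["decay"] = 0
                elif r < 1 - trend_eps:
                    hits["decay"] += 1
                    hits["grow"] = 0
                else:
                    hits["grow"] = hits["decay"] = 0
                if hits["grow"] >= 2:
                    return "ee_trend_up"
                if hits["decay"] >= 2:
                    return "ee_trend_down"
        return None

    state, report = engine.run_to_steady_state(init, observer=observer)
    ee = abs(fractions(state, net).ee)
    via = report.stop_reason
    if via in ("ee_high", "ee_trend_up"):
        label = "broken"
    elif via in ("ee_low", "ee_trend_down"):
        label = "symmetric"
    else:
        label = "broken" if ee > threshold else "symmetric"
    return ClassifyOutcome(label, ee, state.t, report.converged, via)


# ----------------------------------------------------------------------


@dataclass
class CriticalResult:
    value: float
    bracket: tuple[float, float]
    param: str
    n_evaluations: int
    history: list[tuple[float, str]] = field(default_factory=list)


def find_critical(spec: ModelSpec, *, param: str = "k_lig",
                  bracket: tuple[float, float], tol: float = 0.05,
                  threshold: float = 0.01, f_bias: float = 0.505,
                  majority: str | None = None,
                  cfg: IntegratorConfig | None = None,
                  engine: str = "kinetics", mc_cfg: MCConfig | None = None,
                  mc_threshold: float = 0.25, seed: int = 0,
                  fast: bool = True) -> CriticalResult:
    """Bisect for the symmetry-breaking transition of the control parameter.

    Each bisection point is evaluated from a cold biased start (no
    continuation), so hysteresis cannot contaminate the estimate.  The
    bracket endpoints must classify differently (symmetric below, broken
    above) or a :class:`BracketError` is raised listing the endpoint excess
    values.  ``engine="montecarlo"`` classifies by the time-averaged
    ``|ee|`` of a stochastic run against ``mc_threshold``.
    """
    lo, hi = map(float, bracket)
    if not lo < hi:
        raise ValueError("bracket must be increasing")
    history: list[tuple[float, str]] = []

    if engine == "kinetics":
        kin = KineticsEngine(_set_param(spec, param, lo), cfg)

        def classify(value: float) -> tuple[str, float]:
            kin.with_spec(_set_param(spec, param, value))
            out = classify_biased_relaxation(
                kin, f_bias=f_bias, majority=majority, threshold=threshold,
                fast=fast)
            return out.label, out.ee_final
    elif engine == "montecarlo":
        from .montecarlo import MonteCarloEngine

        def classify(value: float) -> tuple[str, float]:
            c = mc_cfg or MCConfig()
            c = _dc_replace(c, seed=seed + int(round(value * 1000)) % 100000)
            mc = MonteCarloEngine(_set_param(spec, param, value), c)
            pop = mc.new_population("biased", f_majority=f_bias,
                                    majority=majority)

            def obs(_pop, fr):
                # far above the transition the verdict is clear early
                if abs(fr.ee) > 3 * mc_threshold and _pop.t > c.burn_in:
                    return "ee_high"
                return None

            res = mc.run(pop, observer=obs)
            tr = res.trajectory
            if len(tr) and tr["t"].iloc[-1] < c.total_time - c.sample_every:
                return "broken", float(abs(tr["ee"].iloc[-1]))
            # judge the late-time excess only: a strongly biased start may
            # still be decaying through the middle of the run
            tail = tr["ee"].iloc[-max(10, len(tr) // 3):]
            ee = float(tail.abs().mean())
            return ("broken" if ee > mc_threshold else "symmetric"), ee
    else:
        raise ValueError(f"unknown engine {engine!r}")

    lab_lo, ee_lo = classify(lo)
    lab_hi, ee_hi = classify(hi)
    history += [(lo, lab_lo), (hi, lab_hi)]
    if lab_lo != "symmetric" or lab_hi != "broken":
        raise BracketError(
            f"bracket does not straddle the transition: |ee|({param}={lo}) = "
            f"{ee_lo:.3g} -> {lab_lo}, |ee|({param}={hi}) = {ee_hi:.3g} -> {lab_hi}")
    n_eval = 2
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lab, _ = classify(mid)
        history.append((mid, lab))
        n_eval += 1
        if lab == "broken":
            hi = mid
        else:
            lo = mid
    return CriticalResult(0.5 * (lo + hi), (lo, hi), param, n_eval, history)


# ----------------------------------------------------------------------
# two-phase protocol and branch limits


def two_phase_endpoint(engine: KineticsEngine, start_type: str, *,
                       early_exit: bool = True):
    """Pure-type phase 1 (no interconversion) then full dynamics phase 2.

    Returns the phase-2 endpoint state and report.  With ``early_exit`` the
    phase-2 run stops as soon as the starting type has lost dominance (the
    collapse onto the competing branch is irreversible).
    """
    spec = engine.spec
    net = engine.net
    if spec.variant == "regioselectivity":
        w = {b: (0.5 if b == start_type else 0.0) for b in spec.bond_alphabet}
        p1 = _dc_replace(spec, pol_bond_weights=w)
        init = uniform_monomer_state(net)
    else:
        p1 = spec.without_interconversion()
        init = None
    net.set_rates(p1)
    if init is None:
        init = pure_monomer_state(net, start_type)
    s1, _ = engine.run_to_steady_state(init)
    net.set_rates(spec)

    others = [t for t in spec.uniform_types if t != start_type]
    hits = {"lost": 0}

    def observer(state: ConcentrationState):
        fr = fractions(state, net)
        if fr.phi[start_type] < max(fr.phi[o] for o in others):
            hits["lost"] += 1
            if hits["lost"] >= 2:
                return "dominance_lost"
        else:
            hits["lost"] = 0
        return None

    s2, rep = engine.run_to_steady_state(
        ConcentrationState(s1.C.copy(), 0.0),
        observer=observer if early_exit else None)
    return s2, rep


def branch_persists(engine: KineticsEngine, start_type: str) -> tuple[bool, FractionSummary]:
    """Does the start_type-dominant solution survive the two-phase protocol?"""
    state, rep = two_phase_endpoint(engine, start_type)
    fr = fractions(state, engine.net)
    others = [t for t in engine.spec.uniform_types if t != start_type]
    ok = (rep.stop_reason != "dominance_lost"
          and fr.phi[start_type] > max(fr.phi[o] for o in others))
    return ok, fr


def find_branch_limit(spec_for, branch: str, *,
                      bracket: tuple[float, float], tol: float = 0.1,
                      cfg: IntegratorConfig | None = None) -> CriticalResult:
    """Smallest control value at which the ``branch``-dominant solution exists.

    ``spec_for(value)`` maps the scanned control parameter (e.g. the R-type
    ligation rate, with the X rate slaved to it) to a full ModelSpec.  At the
    low endpoint the branch must collapse, at the high endpoint persist.
    """
    lo, hi = map(float, bracket)
    engine = KineticsEngine(spec_for(lo), cfg)
    history = []

    def persists(value: float) -> bool:
        engine.with_spec(spec_for(value))
        ok, _ = branch_persists(engine, branch)
        history.append((value, "persists" if ok else "collapses"))
        return ok

    if persists(lo):
        raise BracketError(f"branch {branch!r} already exists at {lo}")
    if not persists(hi):
        raise BracketError(f"branch {branch!r} absent at {hi}")
    n_eval = 2
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if persists(mid):
            hi = mid
        else:
            lo = mid
        n_eval += 1
    return CriticalResult(0.5 * (lo + hi), (lo, hi), "branch_limit", n_eval,
                          history)


# ----------------------------------------------------------------------
# grid scans


@dataclass
class ScanResult:
    """Equilibrium observables along a control-parameter grid, per branch."""

    param: str
    values: list[float]
    branches: dict[str, list[FractionSummary]]
    converged: dict[str, list[bool]]
    critical: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label, summaries in self.branches.items():
            for v, fr, conv in zip(self.values, summaries,
                                   self.converged[label]):
                rows.append({self.param: v, "branch": label,
                             "converged": conv, **fr.as_dict()})
        return pd.DataFrame(rows)


def scan_klig(spec: ModelSpec, grid, *, protocol: str = "biased",
              f_bias: float = 0.505, warm_start: bool = True,
              cfg: IntegratorConfig | None = None) -> ScanResult:
    """Steady-state observables over an ascending k_lig grid.

    ``protocol="biased"`` relaxes from the slightly biased monomer start and
    reports one branch (warm-started along the grid for continuation);
    ``protocol="two_start"`` runs the two-phase pure-type protocol per
    uniform type and reports one branch per starting type.
    """
    return _scan(spec, "k_lig", grid, protocol, f_bias, warm_start, cfg)


def scan_concentration(spec: ModelSpec, grid, *, protocol: str = "biased",
                       f_bias: float = 0.505, warm_start: bool = True,
                       cfg: IntegratorConfig | None = None) -> ScanResult:
    """Steady-state observables over an ascending C_tot grid."""
    return _scan(spec, "C_tot", grid, protocol, f_bias, warm_start, cfg)


def _rebias_monomers(net, state: ConcentrationState, f_bias: float) -> None:
    """Redistribute the free-monomer mass to the f/(1-f) type split in place.

    No-op for single-monomer (regioselectivity) systems; preserves the total
    nucleotide concentration exactly.
    """
    spec = net.spec
    types = spec.uniform_types
    if spec.variant == "regioselectivity" or len(types) < 2:
        return
    mono = net.mono_classes
    total = float((net.weight[mono] * state.C[mono]).sum())
    if total <= 0:
        return
    shares = {t: (f_bias if t == types[0] else (1 - f_bias) / (len(types) - 1))
              for t in types}
    for ci, sym_i in zip(mono, net.mono_sym):
        sym = spec.monomer_alphabet[sym_i]
        if spec.variant == "chirality_basepair":
            share = shares[sym[0]] / 4.0
        else:
            share = shares[sym]
        state.C[ci] = share * total / net.weight[ci]


def _scan(spec, param, grid, protocol, f_bias, warm_start, cfg) -> ScanResult:
    grid = [float(g) for g in grid]
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be sorted ascending")
    if not grid:
        raise ValueError("empty scan grid")
    engine = KineticsEngine(_set_param(spec, param, grid[0]), cfg)
    net = engine.net
    if protocol == "biased":
        labels = ["biased"]
    elif protocol == "two_start":
        labels = list(spec.uniform_types)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    branches: dict[str, list[FractionSummary]] = {l: [] for l in labels}
    converged: dict[str, list[bool]] = {l: [] for l in labels}
    prev: dict[str, ConcentrationState] = {}
    for v in grid:
        engine.with_spec(_set_param(spec, param, v))
        for label in labels:
            if protocol == "biased":
                if warm_start and label in prev:
                    init = prev[label].copy()
                    if param == "C_tot":
                        init.C *= v / net.total_nucleotides(init.C)
                    # re-apply the monomer bias so continuation cannot pin
                    # the run to the (unstable) symmetric manifold
                    _rebias_monomers(net, init, f_bias)
                else:
                    init = biased_monomer_state(net, f_majority=f_bias)
                state, rep = engine.run_to_steady_state(init)
                conv = rep.converged
            else:
                state, rep = two_phase_endpoint(engine, label,
                                                early_exit=False)
                conv = rep.converged
            prev[label] = state
            branches[label].append(fractions(state, net))
            converged[label].append(conv)
    return ScanResult(param, grid, branches, converged)
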