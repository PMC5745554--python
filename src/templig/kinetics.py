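"""Deterministic mass-action integration of the templated-polymer system.

The integrator is forward Euler, exactly the scheme of iterating the
concentration updates in small time steps, with two safeguards: the step is
capped by a linear-stability bound (a safety factor over the inverse of the
largest per-class loss coefficient) and by a maximum per-step relative
concentration change.  Because steady states are fixed points of the Euler
map for *any* step size, converged results are independent of the step-size
policy; the safeguards only shape the transient path and keep the iteration
stable.

Mass is conserved exactly by construction: interconversion changes monomer
type, never nucleotide count, and every join/severing moves whole fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Callable

import numpy as np

from .model import IntegratorConfig, ModelSpec
from .network import ReactionNetwork


@dataclass
class ConcentrationState:
    """Concentration vector over the network's canonical class order."""

    C: np.ndarray
    t: float = 0.0

    def copy(self) -> "ConcentrationState":
        return ConcentrationState(self.C.copy(), self.t)


@dataclass
class ConvergenceReport:
    converged: bool
    residual: float          # max |dC/dt| / C_tot at the final state
    t_final: float
    n_steps: int
    mass_error: float        # relative drift of total nucleotide concentration
    stop_reason: str = "steady_state"


# ----------------------------------------------------------------------
# initial conditions


def biased_monomer_state(net: ReactionNetwork, f_majority: float = 0.505,
                         majority: str | None = None) -> ConcentrationState:
    """All-monomer start with a small composition bias.

    A fraction ``f_majority`` of C_tot goes to the monomers of the majority
    uniform type (default: the first type — D, R, ...), the remainder is
    split equally over the other types.  Within the base-explicit variant
    each chirality's share is split equally over the four bases, which keeps
    the state symmetric under the base-permutation lumping group.
    """
    spec = net.spec
    types = spec.uniform_types
    if spec.variant == "regioselectivity":
        raise ValueError("regioselectivity has a single monomer; no biased start")
    if majority is None:
        majority = types[0]
    if majority not in types:
        raise ValueError(f"majority {majority!r} not one of {types}")
    shares = {t: (f_majority if t == majority else
                  (1.0 - f_majority) / (len(types) - 1)) for t in types}
    return _monomer_state(net, shares)


def pure_monomer_state(net: ReactionNetwork, mono_type: str) -> ConcentrationState:
    """All of C_tot in free monomers of a single uniform type."""
    return _monomer_state(net, {mono_type: 1.0})


def uniform_monomer_state(net: ReactionNetwork) -> ConcentrationState:
    """Exactly symmetric all-monomer start."""
    types = net.spec.uniform_types
    if net.spec.variant == "regioselectivity":
        return _monomer_state(net, {types[0]: 1.0})  # single monomer species
    return _monomer_state(net, {t: 1.0 / len(types) for t in types})


def _monomer_state(net: ReactionNetwork, shares: dict[str, float]) -> ConcentrationState:
    spec = net.spec
    C = np.zeros(net.n_classes)
    for sym_idx, sym in enumerate(spec.monomer_alphabet):
        if spec.variant == "regioselectivity":
            share = 1.0 / len(spec.monomer_alphabet)
        elif spec.variant == "chirality_basepair":
            mark = sym[0]
            share = shares.get(mark, 0.0) / 4.0
        else:
            share = shares.get(sym, 0.0)
        cls = net.full_mono_class[sym_idx]
        C[cls] += share * spec.C_tot / net.weight[cls]
    return ConcentrationState(C)


# ----------------------------------------------------------------------


class KineticsEngine:
    """Deterministic engine bound to one reaction-network structure.

    Building the network is the expensive part; ``with_spec`` retargets the
    rate constants in place so parameter scans and bisections reuse it.
    """

    def __init__(self, spec: ModelSpec, cfg: IntegratorConfig | None = None,
                 group=None):
        self.net = ReactionNetwork(spec, group=group)
        self.cfg = cfg or IntegratorConfig()

    @property
    def spec(self) -> ModelSpec:
        return self.net.spec

    def with_spec(self, spec: ModelSpec) -> "KineticsEngine":
        self.net.set_rates(spec)
        return self

    # ------------------------------------------------------------------

    def step(self, state: ConcentrationState,
             dt: float | None = None) -> ConcentrationState:
        """One forward-Euler step (adaptive dt unless given explicitly)."""
        dC, lam = self.net.derivative(state.C)
        used = dt if dt is not None else self._choose_dt(state.C, dC, lam)
        C = state.C + used * dC
        self._guard_negative(C)
        return ConcentrationState(C, state.t + used)

    def _choose_dt(self, C, dC, lam) -> float:
        cfg = self.cfg
        dt = cfg.dt_max
        lmax = lam.max(initial=0.0)
        if lmax > 0:
            dt = min(dt, 0.8 / lmax)
        adC = np.abs(dC)
        m = adC > 0
        if m.any():
            allowed = cfg.rtol_step * C[m] + cfg.atol_step * self.spec.C_tot
            dt = min(dt, float(np.min(allowed / adC[m])))
        return dt

    def _guard_negative(self, C: np.ndarray) -> None:
        tol = 1e-12 * self.spec.C_tot
        if C.min(initial=0.0) < -tol:
            worst = int(np.argmin(C))
            raise RuntimeError(
                f"concentration of class {worst} driven to {C[worst]:.3e}; "
                "the step size safeguards failed — reduce dt_max")
        np.clip(C, 0.0, None, out=C)

    # ------------------------------------------------------------------

    def run_to_steady_state(
            self, state: ConcentrationState | None = None, *,
            observer: Callable[[ConcentrationState], str | None] | None = None,
    ) -> tuple[ConcentrationState, ConvergenceReport]:
        """Integrate until the residual stays below tolerance for a window.

        ``observer`` (called every ``cfg.check_every`` steps) may return a
        non-None string to stop early; it becomes the report's stop_reason.
        """
        cfg = self.cfg
        net = self.net
        if state is None:
            state = biased_monomer_state(net)
        C = state.C.copy()
        t = state.t
        mass0 = net.total_nucleotides(C)
        below = 0
        steps = 0
        residual = np.inf
        reason = "max_time"
        converged = False
        while t < cfg.max_time:
            dC, lam = net.derivative(C)
            residual = float(np.max(np.abs(dC))) / self.spec.C_tot
            if residual < cfg.ss_tol:
                below += 1
                if below >= cfg.ss_window:
                    converged = True
                    reason = "steady_state"
                    break
            else:
                below = 0
            dt = self._choose_dt(C, dC, lam)
            C += dt * dC
            self._guard_negative(C)
            t += dt
            steps += 1
            if observer is not None and steps % cfg.check_every == 0:
                verdict = observer(ConcentrationState(C, t))
                if verdict is not None:
                    reason = verdict
                    converged = residual < cfg.ss_tol
                    break
        mass_err = abs(net.total_nucleotides(C) - mass0) / mass0
        return (ConcentrationState(C, t),
                ConvergenceReport(converged, residual, t, steps, mass_err, reason))

    # ------------------------------------------------------------------

    def run_two_start_protocol(
            self, *, phase1_specs: dict[str, ModelSpec] | None = None,
    ) -> dict[str, tuple[ConcentrationState, ConvergenceReport]]:
        """Relax from each pure-type extreme, then restore the full dynamics.

        Phase 1 runs with interconversion disabled (so a pure-type strand
        pool builds up), phase 2 re-enables it and relaxes to steady state.
        For the regioselectivity variant — which has no interconversion —
        the analogue manufactures a pure-bond-type pool by restricting
        spontaneous polymerisation to one bond type in phase 1.

        Returns the phase-2 endpoint per starting type, so the caller can
        detect mono- versus bi-stability.
        """
        spec = self.spec
        out = {}
        if phase1_specs is None:
            phase1_specs = {}
            if spec.variant == "regioselectivity":
                for b in spec.bond_alphabet:
                    w = {bb: (0.5 if bb == b else 0.0) for bb in spec.bond_alphabet}
                    phase1_specs[b] = _dc_replace(spec, pol_bond_weights=w)
            else:
                if len(spec.uniform_types) < 2:
                    raise ValueError("two-start protocol needs >= 2 types")
                for t in spec.uniform_types:
                    phase1_specs[t] = spec.without_interconversion()
        for start_type, p1 in phase1_specs.items():
            self.net.set_rates(p1)
            if spec.variant == "regioselectivity":
                init = uniform_monomer_state(self.net)
            else:
                init = pure_monomer_state(self.net, start_type)
            s1, _ = self.run_to_steady_state(init)
            self.net.set_rates(spec)
            s2, rep2 = self.run_to_steady_state(ConcentrationState(s1.C, 0.0))
            out[start_type] = (s2, rep2)
        self.net.set_rates(spec)
        return out
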