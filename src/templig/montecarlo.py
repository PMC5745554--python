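"""Stochastic fixed-timestep simulation of an explicit strand population.

A population of ``N_tot`` nucleotides in volume ``V`` evolves in small time
steps.  In each step, iterating over a snapshot of the strand list taken at
step start:

* each strand hydrolyses with probability ``(n-1) k_hyd dt`` at a uniformly
  chosen bond;
* each strand, as the left partner, joins a uniformly chosen other strand
  with probability ``(N_strands - 1) / V * k_pol * dt``;
* for each strand a partner and one candidate template are drawn; if the
  candidate qualifies, ligation occurs with probability
  ``(N_strands - 1)(N_strands - 2) / V**2 * k_lig * dt``;
* each free monomer switches type with probability ``k_int dt`` per
  destination type.

Strands consumed earlier within a step are skipped by later channels, and
strands created within a step only react from the next step on; with these
snapshot semantics the expected per-step rates match the deterministic
mass-action rates evaluated at step start.  ``dt`` is adapted so that the
larger of the polymerisation and ligation probabilities stays near a target
(default 5%), never growing by more than a factor 2 per adjustment, and any
probability reaching 1 halves ``dt`` and retries the step.

Strands are stored as tuples of alphabet indices (regioselectivity:
monomer and bond indices interleaved), so the total nucleotide count is an
exact integer invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MCConfig, ModelSpec
from .observables import FractionSummary
from .strands import Strand


def _encode(s: Strand, spec: ModelSpec) -> tuple[int, ...]:
    mi = {m: k for k, m in enumerate(spec.monomer_alphabet)}
    if not spec.has_bonds:
        return tuple(mi[m] for m in s.monomers)
    bi = {b: k for k, b in enumerate(spec.bond_alphabet)}
    out = [mi[s.monomers[0]]]
    for b, m in zip(s.bonds, s.monomers[1:]):
        out.append(bi[b])
        out.append(mi[m])
    return tuple(out)


def _decode(t: tuple[int, ...], spec: ModelSpec) -> Strand:
    if not spec.has_bonds:
        return Strand(tuple(spec.monomer_alphabet[i] for i in t))
    mono = tuple(spec.monomer_alphabet[i] for i in t[::2])
    bonds = tuple(spec.bond_alphabet[i] for i in t[1::2])
    return Strand(mono, bonds)


def _strand_len(t: tuple[int, ...], has_bonds: bool) -> int:
    return (len(t) + 1) // 2 if has_bonds else len(t)


@dataclass
class Population:
    """Explicit strand multiset; total nucleotide count is exactly conserved."""

    strands: list
    N_tot: int
    V: float
    t: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def N_strands(self) -> int:
        return len(self.strands)


def monomer_population(spec: ModelSpec, cfg: MCConfig,
                       counts: dict[str, int] | None = None,
                       rng: np.random.Generator | None = None) -> Population:
    """All-monomer population; ``counts`` per monomer symbol (default: equal,
    remainders to the earliest symbols)."""
    n_sym = len(spec.monomer_alphabet)
    if counts is None:
        base, extra = divmod(cfg.N_tot, n_sym)
        counts = {m: base + (1 if k < extra else 0)
                  for k, m in enumerate(spec.monomer_alphabet)}
    if sum(counts.values()) != cfg.N_tot:
        raise ValueError("monomer counts must sum to N_tot")
    strands = []
    for k, m in enumerate(spec.monomer_alphabet):
        strands.extend([(k,)] * counts.get(m, 0))
    return Population(strands, cfg.N_tot, cfg.V,
                      rng=rng or np.random.default_rng(cfg.seed))


def biased_monomer_population(spec: ModelSpec, cfg: MCConfig,
                              f_majority: float = 0.505,
                              majority: str | None = None) -> Population:
    """All-monomer start with a small bias toward one uniform type."""
    types = spec.uniform_types
    if majority is None:
        majority = types[0]
    shares = {t: (f_majority if t == majority else
                  (1 - f_majority) / (len(types) - 1)) for t in types}
    counts = {}
    left = cfg.N_tot
    syms = spec.monomer_alphabet
    for m in syms:
        t = m[0] if spec.variant == "chirality_basepair" else m
        per = shares.get(t, 0.0) / (4 if spec.variant == "chirality_basepair" else 1)
        c = int(round(per * cfg.N_tot))
        counts[m] = c
        left -= c
    counts[syms[0]] += left  # rounding remainder
    return monomer_population(spec, cfg, counts)


def population_from_strands(strands, spec: ModelSpec, V: float,
                            seed: int = 0) -> Population:
    """Build a population from explicit :class:`Strand` objects.

    Useful for seeding runs with a prepared oligomer pool; ``N_tot`` is the
    total nucleotide count of the given strands.
    """
    encoded = [_encode(s, spec) for s in strands]
    n_tot = sum(_strand_len(t, spec.has_bonds) for t in encoded)
    return Population(encoded, n_tot, V, rng=np.random.default_rng(seed))


# ----------------------------------------------------------------------
# per-strand typing helpers on encoded tuples


def _compat_types(t: tuple[int, ...], spec: ModelSpec) -> tuple[int, ...]:
    """Uniform-type indices this strand can be ligated as; () if mixed."""
    if spec.has_bonds:
        if len(t) == 1:
            return tuple(range(len(spec.bond_alphabet)))
        bonds = t[1::2]
        return (bonds[0],) if all(b == bonds[0] for b in bonds) else ()
    if spec.variant == "chirality_basepair":
        mark = t[0] // 4
        return (mark,) if all(x // 4 == mark for x in t) else ()
    return (t[0],) if all(x == t[0] for x in t) else ()


def _match_count(template: tuple[int, ...], product: tuple[int, ...],
                 spec: ModelSpec) -> int:
    """Alignment sites at which the template qualifies for the product.

    Under per_strand counting the templated reaction uses only whether this
    is nonzero; under per_site counting the acceptance probability is
    weighted by it.
    """
    if spec.has_bonds:
        need = (len(product) - 1) // 2   # bonds in the product
        tau = product[1]
        count = run = 0
        for b in template[1::2]:
            run = run + 1 if b == tau else 0
            if run >= need:
                count += 1
        return count
    n = len(product)
    if len(template) < n:
        return 0
    if spec.variant == "chirality_basepair":
        mark = product[0] // 4
        comp = (1, 0, 3, 2)
        want = [4 * mark + comp[x % 4] for x in product]
        orientation = spec.complement_orientation
        wants = []
        if orientation in ("parallel", "either"):
            wants.append(want)
        if orientation in ("antiparallel", "either"):
            wants.append(want[::-1])
        count = 0
        for s in range(len(template) - n + 1):
            win = list(template[s:s + n])
            if all(x // 4 == mark for x in win):
                count += sum(win == w for w in wants)
        return count
    tau = product[0]
    count = run = 0
    for x in template:
        run = run + 1 if x == tau else 0
        if run >= n:
            count += 1
    return count


def _join(a: tuple, b: tuple, tau: int | None, has_bonds: bool) -> tuple:
    return a + (tau,) + b if has_bonds else a + b


# ----------------------------------------------------------------------


class MonteCarloEngine:
    """Stochastic engine for one spec; owns the seeded random generator."""

    def __init__(self, spec: ModelSpec, cfg: MCConfig | None = None):
        self.spec = spec
        self.cfg = cfg or MCConfig()
        self.dt = self.cfg.dt_init
        self.dt_log: list[tuple[float, float]] = []
        if spec.has_bonds:
            w = np.array([spec.pol_bond_weights[b] for b in spec.bond_alphabet])
            self._wsum = float(w.sum())
            self._wcum = np.cumsum(w / w.sum()) if self._wsum > 0 else None
        else:
            self._wsum = 1.0
            self._wcum = None
        self._klig = np.array([spec.k_lig[t] for t in spec.uniform_types])
        self._kmax = float(self._klig.max(initial=0.0))
        # interconversion: per source symbol, destination symbols and rates
        self._int_dst = []
        self._int_rate = []
        for a in spec.monomer_alphabet:
            dsts = [(b_idx, spec.k_int[(a, b)])
                    for b_idx, b in enumerate(spec.monomer_alphabet)
                    if b != a and spec.k_int[(a, b)] > 0]
            self._int_dst.append([d for d, _ in dsts])
            self._int_rate.append(np.array([r for _, r in dsts]))

    # ------------------------------------------------------------------

    def new_population(self, init: str = "equal", f_majority: float = 0.505,
                       majority: str | None = None) -> Population:
        if init == "equal":
            return monomer_population(self.spec, self.cfg)
        if init == "biased":
            return biased_monomer_population(self.spec, self.cfg, f_majority,
                                             majority)
        raise ValueError(f"unknown init {init!r}")

    def channel_probabilities(self, N_strands: int, dt: float) -> dict[str, float]:
        """Per-strand event probabilities of Eqs. for the current population size."""
        V = self.cfg.V
        p_pol = max(N_strands - 1, 0) / V * self.spec.k_pol * self._wsum * dt
        p_lig = (max(N_strands - 1, 0) * max(N_strands - 2, 0) / V ** 2
                 * self._kmax * dt)
        return {"pol": p_pol, "lig": p_lig}

    def adapt_dt(self, pop: Population) -> float:
        """Retarget dt so max(p_pol, p_lig) hits the configured target."""
        p = self.channel_probabilities(pop.N_strands, self.dt)
        pmax = max(p["pol"], p["lig"])
        if pmax > 0:
            new = self.dt * self.cfg.target_prob / pmax
            new = min(new, 2.0 * self.dt)     # never more than doubling
            if new != self.dt:
                self.dt_log.append((pop.t, new))
            self.dt = new
        return self.dt

    # ------------------------------------------------------------------

    def step(self, pop: Population) -> None:
        """Advance the population by one time step (in place)."""
        spec = self.spec
        cfg = self.cfg
        has_bonds = spec.has_bonds
        lmax = spec.l_max
        rng = pop.rng
        kh = spec.k_hyd

        while True:
            snapshot = pop.strands
            N = len(snapshot)
            lengths = np.fromiter(
                (_strand_len(s, has_bonds) for s in snapshot), dtype=np.int64,
                count=N)
            p = self.channel_probabilities(N, self.dt)
            p_hyd_max = (int(lengths.max(initial=1)) - 1) * kh * self.dt
            if max(p["pol"], p["lig"], p_hyd_max) < 1.0:
                break
            self.dt *= 0.5          # probability guard: halve and retry
            self.dt_log.append((pop.t, self.dt))

        consumed = np.zeros(N, dtype=bool)
        new_strands: list = []

        # (a) hydrolysis
        u = rng.random(N)
        for i in np.flatnonzero(u < (lengths - 1) * kh * self.dt):
            s = snapshot[i]
            nb = lengths[i] - 1
            k = int(rng.integers(nb))
            if has_bonds:
                pos = 2 * k + 1
                new_strands.append(s[:pos])
                new_strands.append(s[pos + 1:])
            else:
                new_strands.append(s[:k + 1])
                new_strands.append(s[k + 1:])
            consumed[i] = True

        # (b) spontaneous polymerisation (strand i as left partner)
        if p["pol"] > 0 and N >= 2:
            u = rng.random(N)
            for i in np.flatnonzero(u < p["pol"]):
                if consumed[i]:
                    continue
                j = int(rng.integers(N - 1))
                j += j >= i
                if consumed[j]:
                    continue
                if lmax is not None and lengths[i] + lengths[j] > lmax:
                    continue
                tau = None
                if has_bonds:
                    tau = int(np.searchsorted(self._wcum, rng.random()))
                new_strands.append(_join(snapshot[i], snapshot[j], tau, has_bonds))
                consumed[i] = consumed[j] = True

        # (c) template-directed ligation
        if self._kmax > 0 and N >= 3:
            base = (N - 1) * (N - 2) / cfg.V ** 2 * self.dt
            u = rng.random(N)
            for i in np.flatnonzero(u < base * self._kmax):
                if consumed[i]:
                    continue
                j, k = rng.choice(N - 1, size=2, replace=False)
                j, k = int(j), int(k)
                j += j >= i
                k += k >= i
                if consumed[j] or consumed[k] or j == k:
                    continue
                si, sj, sk = snapshot[i], snapshot[j], snapshot[k]
                if lmax is not None and lengths[i] + lengths[j] > lmax:
                    continue
                taus = [t for t in _compat_types(si, spec)
                        if t in _compat_types(sj, spec)]
                if not taus:
                    continue
                if len(taus) > 1:
                    rng.shuffle(taus)
                per_site = spec.template_counting == "per_site"
                for tau in taus:
                    prod = _join(si, sj, tau if has_bonds else None, has_bonds)
                    sites = _match_count(sk, prod, spec)
                    if not sites:
                        continue
                    weight = sites if per_site else 1
                    if u[i] < base * self._klig[tau] * weight:
                        new_strands.append(prod)
                        consumed[i] = consumed[j] = True
                    break

        # (d) monomer interconversion
        if any(len(d) for d in self._int_dst):
            u = rng.random(N)
            for i in np.flatnonzero((lengths == 1) & ~consumed):
                a = snapshot[i][0]
                rates = self._int_rate[a]
                if not rates.size:
                    continue
                x = u[i]
                acc = 0.0
                for d, r in zip(self._int_dst[a], rates):
                    acc += r * self.dt
                    if x < acc:
                        consumed[i] = True
                        new_strands.append((d,))
                        break

        survivors = [s for i, s in enumerate(snapshot) if not consumed[i]]
        survivors.extend(new_strands)
        pop.strands = survivors
        pop.t += self.dt

    # ------------------------------------------------------------------

    def population_fractions(self, pop: Population) -> FractionSummary:
        """Nucleotide fractions / excess of the current population."""
        spec = self.spec
        types = spec.uniform_types
        phi_counts = dict.fromkeys(types, 0)
        mixed = mono = 0
        a_cnt = b_cnt = 0   # oligomer pole counts for the excess
        am = bm = 0         # free-monomer pole counts
        two = len(types) == 2
        for s in pop.strands:
            n = _strand_len(s, spec.has_bonds)
            if n == 1:
                mono += 1
                if two and not spec.has_bonds:
                    mark = s[0] // 4 if spec.variant == "chirality_basepair" else s[0]
                    if mark == 0:
                        am += 1
                    elif mark == 1:
                        bm += 1
                continue
            ts = _compat_types(s, spec)
            if ts:
                phi_counts[types[ts[0]]] += n
            else:
                mixed += n
            if two:
                if spec.has_bonds:
                    bonds = s[1::2]
                    a_cnt += sum(1 for b in bonds if b == 0)
                    b_cnt += sum(1 for b in bonds if b == 1)
                elif spec.variant == "chirality_basepair":
                    a_cnt += sum(1 for x in s if x // 4 == 0)
                    b_cnt += sum(1 for x in s if x // 4 == 1)
                else:
                    a_cnt += sum(1 for x in s if x == 0)
                    b_cnt += sum(1 for x in s if x == 1)
        tot = pop.N_tot
        phi = {t: phi_counts[t] / tot for t in types}
        phi_M = mixed / tot
        ee = mono_ee = None
        if two:
            ee = (a_cnt - b_cnt) / (a_cnt + b_cnt) if a_cnt + b_cnt else 0.0
            if not spec.has_bonds:
                mono_ee = (am - bm) / (am + bm) if am + bm else 0.0
        return FractionSummary(phi, phi_M, 1.0 - sum(phi.values()) - phi_M,
                               ee, mono_ee)

    def length_counts(self, pop: Population, n_max: int = 40) -> np.ndarray:
        out = np.zeros(n_max + 1)
        for s in pop.strands:
            n = _strand_len(s, self.spec.has_bonds)
            if n <= n_max:
                out[n] += 1
        return out

    # ------------------------------------------------------------------

    def run(self, pop: Population | None = None, *,
            observer=None) -> "MCResult":
        """Run to cfg.total_time, sampling observables on a fixed cadence.

        Samples before cfg.burn_in are kept in the trajectory but excluded
        from the block-averaged summary statistics.
        """
        cfg = self.cfg
        if pop is None:
            pop = self.new_population()
        rows = []
        lencounts = []
        next_sample = pop.t
        steps = 0
        while pop.t < cfg.total_time:
            if pop.t >= next_sample:
                fr = self.population_fractions(pop)
                conserved = sum(_strand_len(s, self.spec.has_bonds)
                                for s in pop.strands)
                if conserved != pop.N_tot:
                    raise AssertionError("nucleotide count not conserved")
                rows.append({"t": pop.t, "N_strands": pop.N_strands,
                             "dt": self.dt, **fr.as_dict()})
                lencounts.append(self.length_counts(pop))
                next_sample += cfg.sample_every
                if observer is not None:
                    verdict = observer(pop, fr)
                    if verdict is not None:
                        break
            if steps % cfg.adapt_every == 0:
                self.adapt_dt(pop)
            self.step(pop)
            steps += 1
        traj = pd.DataFrame(rows)
        return MCResult(self.spec, cfg, traj, np.array(lencounts), pop)


@dataclass
class MCResult:
    """Trajectory plus block-averaged equilibrium summaries."""

    spec: ModelSpec
    cfg: MCConfig
    trajectory: pd.DataFrame
    length_counts: np.ndarray
    final_population: Population

    def _blocks(self, values: np.ndarray) -> tuple[float, float]:
        nb = self.cfg.n_blocks
        if len(values) < nb:
            return float(np.mean(values)), float("nan")
        chunks = np.array_split(np.asarray(values, dtype=float), nb)
        means = np.array([c.mean() for c in chunks])
        return float(means.mean()), float(means.std(ddof=1) / np.sqrt(nb))

    @property
    def _eq_mask(self) -> np.ndarray:
        return (self.trajectory["t"] >= self.cfg.burn_in).to_numpy()

    def time_average(self, column: str) -> tuple[float, float]:
        """Block-averaged mean and standard error of a trajectory column."""
        return self._blocks(self.trajectory.loc[self._eq_mask, column].to_numpy())

    def summary(self, relabel_dominant: bool = False) -> dict:
        """Time-averaged phi / ee with standard errors.

        With ``relabel_dominant`` (symmetric two-type variants above the
        transition) the larger time-averaged uniform fraction is reported
        first, the convention used when comparing runs that may have broken
        symmetry in either direction.
        """
        cols = [c for c in self.trajectory.columns if c not in ("t", "N_strands", "dt")]
        out = {}
        for c in cols:
            mean, se = self.time_average(c)
            out[c] = mean
            out[f"{c}_se"] = se
        if relabel_dominant:
            types = self.spec.uniform_types
            if len(types) == 2:
                a, b = (f"phi_{t}" for t in types)
                if out[a] < out[b]:
                    for k1, k2 in ((a, b), (f"{a}_se", f"{b}_se")):
                        out[k1], out[k2] = out[k2], out[k1]
                    for k in ("ee", "ee_se"):
                        if k in out:
                            out[k] = -out[k] if k == "ee" else out[k]
        mean_abs_ee, se_abs_ee = (self._blocks(
            np.abs(self.trajectory.loc[self._eq_mask, "ee"].to_numpy()))
            if "ee" in self.trajectory else (None, None))
        if mean_abs_ee is not None:
            out["abs_ee"] = mean_abs_ee
            out["abs_ee_se"] = se_abs_ee
        return out

    def final_strands(self) -> list[Strand]:
        """The final population decoded to :class:`Strand` objects."""
        return [_decode(s, self.spec) for s in self.final_population.strands]

    def mean_length_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Block-averaged strand counts per length (mean, standard error)."""
        lc = self.length_counts[self._eq_mask]
        nb = self.cfg.n_blocks
        chunks = np.array_split(lc, nb)
        means = np.array([c.mean(axis=0) for c in chunks])
        return means.mean(axis=0), means.std(axis=0, ddof=1) / np.sqrt(nb)
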