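"""TOML run configuration: schema, validation, and experiment execution.

A run configuration has four blocks::

    [model]       variant, rate constants, C_tot, l_max, ...
    [kinetics]    deterministic integrator settings (optional)
    [montecarlo]  stochastic engine settings (optional)
    [run]         engine selection, protocol, output directory
    [scan]        optional: grid scan / critical-point / branch-limit mode

``k_lig`` is a scalar (applied to every uniform type) or a table keyed by
uniform type (``{D = 10.0, L = 10.0}``; bond symbols for regioselectivity).
``k_int`` is a scalar or a table with directed keys like ``"R->X"``.
``l_max = 0`` means unbounded (Monte Carlo only).

Identical configuration plus seed yields byte-identical CSV/JSON artifacts;
run metadata that varies between invocations (wall-clock time, step-size
adaptations) goes to the run log instead.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .kinetics import KineticsEngine, biased_monomer_state, uniform_monomer_state
from .model import (BASES, CHIRALITY_MARKS, IntegratorConfig, MCConfig,
                    ModelSpec)
from .observables import fractions
from .scans import find_branch_limit, find_critical, scan_concentration, scan_klig


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field path."""


@dataclass(frozen=True)
class ScanConfig:
    mode: str = "scan"            # scan | critical | branch_limit
    parameter: str = "k_lig"      # k_lig | C_tot
    grid: tuple[float, ...] = ()
    bracket: tuple[float, float] | None = None
    tol: float = 0.05
    protocol: str = "biased"      # biased | two_start
    branch: str | None = None     # branch_limit only


@dataclass(frozen=True)
class RunConfig:
    spec: ModelSpec
    kinetics: IntegratorConfig
    montecarlo: MCConfig
    engine: str = "kinetics"      # kinetics | montecarlo | both
    protocol: str = "biased"      # biased | symmetric | two_start
    f_bias: float = 0.505
    output_dir: str = "out"
    seed: int = 0
    scan: ScanConfig | None = None


# ----------------------------------------------------------------------
# parsing


def _fail(path: str, msg: str):
    raise ConfigError(f"[{path}]: {msg}")


def _build_spec(m: dict) -> ModelSpec:
    variant = m.get("variant")
    if variant is None:
        _fail("model.variant", "required")
    kwargs = {}
    for key in ("k_pol", "k_hyd", "C_tot"):
        if key in m:
            kwargs[key] = float(m[key])
    l_max = m.get("l_max", 6)
    l_max = None if l_max in (0, "inf") else int(l_max)

    if variant == "chirality":
        alphabet = ("D", "L")
    elif variant == "chirality_basepair":
        alphabet = tuple(f"{c}{b}" for c in CHIRALITY_MARKS for b in BASES)
    elif variant == "monomer_selection":
        n_alt = int(m.get("n_alternatives", 1))
        alphabet = ("R", "X") if n_alt == 1 else ("R", "X1", "X2")
    elif variant == "regioselectivity":
        alphabet = ("N",)
    else:
        _fail("model.variant", f"unknown variant {variant!r}")

    bond_alphabet = ("3", "2") if variant == "regioselectivity" else ()
    # uniform-type labels for k_lig keys
    if variant == "chirality_basepair":
        types = CHIRALITY_MARKS
    elif variant == "regioselectivity":
        types = bond_alphabet
    else:
        types = alphabet
    klig_in = m.get("k_lig", 0.0)
    if isinstance(klig_in, dict):
        bad = set(klig_in) - set(types)
        if bad:
            _fail("model.k_lig", f"unknown uniform types {sorted(bad)}; "
                  f"expected keys from {list(types)}")
        k_lig = {t: float(v) for t, v in klig_in.items()}
    else:
        k_lig = {t: float(klig_in) for t in types}

    kint_in = m.get("k_int", 1.0 if variant != "regioselectivity" else 0.0)
    if isinstance(kint_in, dict):
        k_int = {}
        for key, v in kint_in.items():
            parts = key.split("->")
            if len(parts) != 2 or not all(p in alphabet for p in parts):
                _fail("model.k_int", f"key {key!r} must be '<from>-><to>' over "
                      f"{list(alphabet)}")
            k_int[(parts[0], parts[1])] = float(v)
    elif variant == "chirality_basepair":
        k_int = {}
        for b in BASES:
            k_int[(f"d{b}", f"l{b}")] = float(kint_in)
            k_int[(f"l{b}", f"d{b}")] = float(kint_in)
    else:
        k_int = float(kint_in)

    try:
        return ModelSpec(
            variant=variant, monomer_alphabet=alphabet,
            bond_alphabet=bond_alphabet, k_lig=k_lig, k_int=k_int,
            l_max=l_max,
            complement_orientation=m.get(
                "complement_orientation",
                "either" if variant == "chirality_basepair" else "antiparallel"),
            template_counting=m.get(
                "template_counting",
                "per_site" if variant == "chirality_basepair" else "per_strand"),
            pol_bond_weights=m.get("pol_bond_weights"),
            **kwargs)
    except ValueError as e:
        _fail("model", str(e))


def _build_block(cls, block: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(block) - names
    if bad:
        _fail(path, f"unknown keys {sorted(bad)}; allowed: {sorted(names)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as e:
        _fail(path, str(e))


def parse_config(data: dict) -> RunConfig:
    if "model" not in data:
        _fail("model", "required block")
    spec = _build_spec(data["model"])
    kin = _build_block(IntegratorConfig, data.get("kinetics", {}), "kinetics")
    mc = _build_block(MCConfig, data.get("montecarlo", {}), "montecarlo")
    run = data.get("run", {})
    engine = run.get("engine", "kinetics")
    if engine not in ("kinetics", "montecarlo", "both"):
        _fail("run.engine", f"got {engine!r}")
    protocol = run.get("protocol", "biased")
    if protocol not in ("biased", "symmetric", "two_start"):
        _fail("run.protocol", f"got {protocol!r}")
    scan = None
    if "scan" in data:
        s = data["scan"]
        mode = s.get("mode", "scan")
        if mode not in ("scan", "critical", "branch_limit"):
            _fail("scan.mode", f"got {mode!r}")
        grid = tuple(float(x) for x in s.get("grid", ()))
        bracket = s.get("bracket")
        if bracket is not None:
            if len(bracket) != 2 or not bracket[0] < bracket[1]:
                _fail("scan.bracket", "need [lo, hi] with lo < hi")
            bracket = (float(bracket[0]), float(bracket[1]))
        if mode == "scan" and not grid:
            _fail("scan.grid", "scan mode needs a non-empty grid")
        if mode in ("critical", "branch_limit") and bracket is None:
            _fail("scan.bracket", f"{mode} mode needs a bracket")
        parameter = s.get("parameter", "k_lig")
        if parameter not in ("k_lig", "C_tot"):
            _fail("scan.parameter", f"got {parameter!r}")
        branch = s.get("branch")
        if mode == "branch_limit" and branch not in spec.uniform_types:
            _fail("scan.branch", f"branch_limit needs one of "
                  f"{list(spec.uniform_types)}")
        scan = ScanConfig(mode, parameter, grid, bracket,
                          float(s.get("tol", 0.05)),
                          s.get("protocol", "biased"), branch)
    if engine == "montecarlo" and spec.l_max is None:
        pass  # unbounded lengths are fine stochastically
    elif spec.l_max is None:
        _fail("model.l_max", "deterministic engines need a finite l_max "
              "(set run.engine = 'montecarlo')")
    return RunConfig(spec, kin, mc, engine, protocol,
                     float(run.get("f_bias", 0.505)),
                     run.get("output_dir", "out"),
                     int(run.get("seed", data.get("montecarlo", {}).get("seed", 0))),
                     scan)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        return parse_config(tomllib.load(fh))


def resolved_dict(cfg: RunConfig) -> dict:
    """Fully resolved, JSON-serialisable echo of the configuration."""
    spec = cfg.spec

    def specd(s: ModelSpec) -> dict:
        return {
            "variant": s.variant,
            "monomer_alphabet": list(s.monomer_alphabet),
            "bond_alphabet": list(s.bond_alphabet),
            "k_pol": s.k_pol, "k_hyd": s.k_hyd,
            "k_lig": dict(s.k_lig),
            "k_int": {f"{a}->{b}": v for (a, b), v in s.k_int.items() if v},
            "C_tot": s.C_tot,
            "l_max": 0 if s.l_max is None else s.l_max,
            "complement_orientation": s.complement_orientation,
            "template_counting": s.template_counting,
            "pol_bond_weights": dict(s.pol_bond_weights or {}),
        }

    out = {
        "templig_version": __version__,
        "model": specd(spec),
        "kinetics": dataclasses.asdict(cfg.kinetics),
        "montecarlo": dataclasses.asdict(cfg.montecarlo),
        "run": {"engine": cfg.engine, "protocol": cfg.protocol,
                "f_bias": cfg.f_bias, "seed": cfg.seed,
                "output_dir": cfg.output_dir},
    }
    if cfg.scan:
        out["scan"] = dataclasses.asdict(cfg.scan)
    return out


# ----------------------------------------------------------------------
# execution


def run_experiment(cfg: RunConfig, outdir: str | Path | None = None,
                   log=print) -> dict:
    """Execute the configured experiment, writing artifacts to output_dir.

    Returns the summary dictionary (also written to summary.json).  The
    summary carries ``converged`` flags; callers decide how to treat
    non-convergence.
    """
    outdir = Path(outdir if outdir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": resolved_dict(cfg)}

    if cfg.scan is not None:
        summary["results"] = _run_scan(cfg, outdir, log)
    else:
        summary["results"] = _run_single(cfg, outdir, log)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log(f"wrote {outdir / 'summary.json'}")
    return summary


def _run_single(cfg: RunConfig, outdir: Path, log) -> dict:
    out: dict = {}
    if cfg.engine in ("kinetics", "both"):
        engine = KineticsEngine(cfg.spec, cfg.kinetics)
        net = engine.net
        rows = []

        def observer(state):
            rows.append({"t": state.t, **fractions(state, net).as_dict()})
            return None

        if cfg.protocol == "two_start":
            res = engine.run_two_start_protocol()
            out["kinetics"] = {
                start: {"fractions": fractions(st, net).as_dict(),
                        "converged": rep.converged,
                        "residual": rep.residual,
                        "t_final": rep.t_final}
                for start, (st, rep) in res.items()}
        else:
            init = (uniform_monomer_state(net) if cfg.protocol == "symmetric"
                    or cfg.spec.variant == "regioselectivity"
                    else biased_monomer_state(net, f_majority=cfg.f_bias))
            state, rep = engine.run_to_steady_state(init, observer=observer)
            traj = pd.DataFrame(rows)
            traj.to_csv(outdir / "kinetics_timeseries.csv", index=False)
            out["kinetics"] = {"fractions": fractions(state, net).as_dict(),
                               "converged": rep.converged,
                               "residual": rep.residual,
                               "t_final": rep.t_final,
                               "n_steps": rep.n_steps,
                               "mass_error": rep.mass_error}
            if net.n_classes <= 256:
                from .strands import strand_to_str
                pd.DataFrame({
                    "species": [strand_to_str(s, cfg.spec) for s in net.reps],
                    "weight": net.weight,
                    "concentration": state.C,
                }).to_csv(outdir / "kinetics_steady_state.csv", index=False)
            log(f"kinetics: converged={rep.converged} "
                f"residual={rep.residual:.2e} t={rep.t_final:.1f}")
    if cfg.engine in ("montecarlo", "both"):
        from .montecarlo import MonteCarloEngine
        mc = MonteCarloEngine(cfg.spec, cfg.montecarlo)
        init = ("equal" if cfg.protocol == "symmetric"
                or cfg.spec.variant == "regioselectivity" else "biased")
        res = mc.run(mc.new_population(init, f_majority=cfg.f_bias))
        res.trajectory.to_csv(outdir / "mc_timeseries.csv", index=False)
        out["montecarlo"] = {"summary": res.summary(),
                             "N_strands_final": res.final_population.N_strands}
        log(f"montecarlo: {len(res.trajectory)} samples, "
            f"final N_strands={res.final_population.N_strands}")
    if cfg.engine == "both" and "kinetics" in out and "montecarlo" in out \
            and cfg.protocol != "two_start":
        kin = out["kinetics"]["fractions"]
        mcs = out["montecarlo"]["summary"]
        comp = []
        for key, v in kin.items():
            if key in mcs:
                comp.append({"observable": key, "kinetics": v,
                             "montecarlo": mcs[key],
                             "mc_se": mcs.get(f"{key}_se")})
        pd.DataFrame(comp).to_csv(outdir / "comparison.csv", index=False)
        out["comparison"] = comp
    return out


def _run_scan(cfg: RunConfig, outdir: Path, log) -> dict:
    sc = cfg.scan
    spec = cfg.spec
    if sc.mode == "critical":
        res = find_critical(
            spec, param=sc.parameter, bracket=sc.bracket, tol=sc.tol,
            f_bias=cfg.f_bias, cfg=cfg.kinetics,
            engine="montecarlo" if cfg.engine == "montecarlo" else "kinetics",
            mc_cfg=cfg.montecarlo, seed=cfg.seed)
        out = {"critical_value": res.value, "parameter": sc.parameter,
               "final_bracket": list(res.bracket),
               "n_evaluations": res.n_evaluations,
               "history": [[v, lab] for v, lab in res.history]}
        log(f"critical {sc.parameter} = {res.value:.4g}")
        return out
    if sc.mode == "branch_limit":
        ratios = {t: (spec.k_lig[t] / spec.k_lig[spec.uniform_types[0]])
                  for t in spec.uniform_types}

        def spec_for(v):
            return spec.with_klig({t: r * v for t, r in ratios.items()})

        res = find_branch_limit(spec_for, sc.branch, bracket=sc.bracket,
                                tol=sc.tol, cfg=cfg.kinetics)
        out = {"branch": sc.branch, "branch_limit": res.value,
               "final_bracket": list(res.bracket),
               "history": [[v, lab] for v, lab in res.history],
               "k_lig_ratios": ratios}
        log(f"branch limit for {sc.branch}: {res.value:.4g}")
        return out
    # plain grid scan
    scan_fn = scan_klig if sc.parameter == "k_lig" else scan_concentration
    res = scan_fn(spec, sc.grid, protocol=sc.protocol, f_bias=cfg.f_bias,
                  cfg=cfg.kinetics)
    df = res.to_dataframe()
    df.to_csv(outdir / "scan.csv", index=False)
    log(f"scan: {len(df)} rows -> scan.csv")
    return {"parameter": sc.parameter, "n_points": len(sc.grid),
            "branches": sorted(res.branches),
            "all_converged": bool(df["converged"].all())}
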