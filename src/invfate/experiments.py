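"""Orchestration of the two experiment families and the validation suite.

``run_trajectory_experiment`` reproduces the deterministic fitness/frequency
panels (a grid of dominance values crossed with initial loads d);
``run_fixation_experiment`` estimates fixation probabilities over a grid of
inversion lengths, mutation rates, population sizes and inheritance modes;
``run_validation_suite`` executes the oracle-equivalence, fixed-point,
identity and neutral-drift checks and reports measured deviations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .autosomal import autosomal_trajectory, make_initial_autosomal_state
from .oracle import marginalize, oracle_from_slr_state, oracle_step
from .params import (
    ModelParams,
    effective_initial_frequency,
    expected_load,
    initial_relative_fitness_unloaded,
    prob_mutation_free,
)
from .slr import inversion_free_equilibrium, make_initial_slr_state, slr_step, slr_trajectory
from .wright_fisher import SimConfig, estimate_fixation_probability, estimate_to_record

__all__ = [
    "ExperimentSpec",
    "run_trajectory_experiment",
    "run_fixation_experiment",
    "run_validation_suite",
]

# deterministic-panel defaults: s=0.01, U=0.02, x=0.2, ntot=1e4 with
# h in {0.25, 0.1, 0.05} giving captured-load means Ux/(hs) of {1.6, 4, 8}
DEFAULT_H_GRID = (0.25, 0.1, 0.05)
DEFAULT_D_GRID = (0, 1, 2, 3)


@dataclass
class ExperimentSpec:
    """Parameter grid plus scale and output settings for one experiment."""

    kind: str  # "trajectory" | "fixation" | "validate"
    h_grid: Sequence[float] = DEFAULT_H_GRID
    d_grid: Sequence[int] = DEFAULT_D_GRID
    x_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.35, 0.5)
    U_grid: Sequence[float] = (0.02,)
    N_grid: Sequence[int] = (1000,)
    modes: Sequence[str] = ("slr", "autosomal")
    s: float = 0.01
    U: float = 0.02
    ntot: int = 10_000
    x: float = 0.2
    N: int = 10_000
    q0: float | None = None
    max_generations: int = 200_000
    replicate_multiplier: float = 1.0
    seed: int = 0
    include_autosomal: bool = False
    outdir: Path | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("h_grid", "d_grid", "x_grid", "U_grid", "N_grid", "modes"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.replicate_multiplier <= 0:
            raise ValueError("replicate_multiplier must be > 0")

    @classmethod
    def from_mapping(cls, kind: str, conf: dict[str, Any]) -> "ExperimentSpec":
        known = {k: v for k, v in conf.items() if k in cls.__dataclass_fields__}
        return cls(kind=kind, **known)


def run_trajectory_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Deterministic trajectories for each (h, d) cell, long-format.

    Columns carry full parameter provenance plus the analytic benchmarks
    (first-generation fitness 1 + Ux and asymptote q*).
    """
    frames = []
    for h in spec.h_grid:
        params = ModelParams.from_arm_rate(
            U=spec.U,
            s=spec.s,
            h=h,
            ntot=spec.ntot,
            x=spec.x,
            N=spec.N,
        )
        n = int(round(params.n_bar))
        q0 = spec.q0 if spec.q0 is not None else params.default_q0("slr")
        for d in spec.d_grid:
            init = make_initial_slr_state(params, d=d, n=n, q0=q0)
            traj = slr_trajectory(init, params, max_generations=spec.max_generations)
            df = traj.to_frame()[
                ["generation", "YI", "w_rel", "qYIW", "qXfW", "qXfD"]
            ].copy()
            df.insert(0, "model", "slr")
            if spec.include_autosomal:
                ainit = make_initial_autosomal_state(params, d=d, n=n, q0=q0)
                atraj = autosomal_trajectory(
                    ainit, params, max_generations=spec.max_generations
                )
                adf = atraj.to_frame()[["generation", "I", "w_rel"]].rename(
                    columns={"I": "YI"}
                )
                adf.insert(0, "model", "autosomal")
                df = pd.concat([df, adf], ignore_index=True)
            df["h"] = h
            df["d"] = d
            df["s"] = spec.s
            df["U"] = params.U
            df["x"] = spec.x
            df["ntot"] = spec.ntot
            df["q0"] = q0
            df["seed"] = spec.seed
            df["w_init_benchmark"] = initial_relative_fitness_unloaded(params)
            df["q_star_benchmark"] = effective_initial_frequency(params, q0)
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if spec.outdir is not None:
        spec.outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(spec.outdir / "trajectories.csv", index=False)
    return out


def run_fixation_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Fixation-probability grid over x, U, N and mode.

    One CSV row per cell with the Monte Carlo estimate, its exact binomial
    confidence interval, the d = 0-conditional estimate, the neutral baseline
    (2/N or 1/(2N)) and the analytic overlay f0*q*.
    """
    rows = []
    for N in spec.N_grid:
        for U in spec.U_grid:
            for mode in spec.modes:
                for x in spec.x_grid:
                    params = ModelParams.from_arm_rate(
                        U=U, s=spec.s, h=spec.h_grid[0], ntot=spec.ntot, x=x, N=N
                    )
                    reps = max(1, int(round(200 * N * spec.replicate_multiplier)))
                    config = SimConfig(
                        params=params,
                        mode=mode,
                        replicates=reps,
                        seed=spec.seed,
                        q0=spec.q0,
                    )
                    est = estimate_fixation_probability(config)
                    rows.append(
                        estimate_to_record(
                            est,
                            extra={
                                "x": x,
                                "U": U,
                                "N": N,
                                "h": spec.h_grid[0],
                                "s": spec.s,
                                "ntot": spec.ntot,
                                "seed": spec.seed,
                            },
                        )
                    )
    out = pd.DataFrame(rows)
    if spec.outdir is not None:
        spec.outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(spec.outdir / "fixation_grid.csv", index=False)
    return out


def run_validation_suite(spec: ExperimentSpec) -> dict[str, Any]:
    """Self-checks with measured deviations; returns a pass/fail JSON report."""
    report: dict[str, Any] = {"checks": {}}

    def add(name: str, deviation: float, tol: float) -> None:
        report["checks"][name] = {
            "deviation": deviation,
            "tolerance": tol,
            "passed": bool(deviation < tol),
        }

    # identity: f0 * q* == q0 exactly
    rng = np.random.default_rng(spec.seed)
    worst = 0.0
    checked = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while checked < 200:
            p = ModelParams(
                mu=10.0 ** rng.uniform(-8, -5),
                s=10.0 ** rng.uniform(-3, -0.5),
                h=rng.uniform(0.05, 0.5),
                ntot=int(rng.integers(100, 100_000)),
                x=rng.uniform(0.0, 1.0),
            )
            if expected_load(p) > 50:  # keep exp() finite; regime is absurd anyway
                continue
            checked += 1
            q0 = 10.0 ** rng.uniform(-6, -2)
            worst = max(
                worst,
                abs(prob_mutation_free(p) * effective_initial_frequency(p, q0) - q0)
                / q0,
            )
    add("identity_f0_qstar", worst, 1e-12)

    # inversion-free fixed point is invariant under the full step
    params = ModelParams.from_arm_rate(U=0.02, s=0.01, h=0.25, ntot=10_000, x=0.2, N=1000)
    q_eq = inversion_free_equilibrium(params)
    n = int(round(params.n_bar))
    st = make_initial_slr_state(params, d=0, n=n, q0=0.5, equilibrate=True)
    st = type(st)(
        YI=1e-300, qXfD=q_eq, qXmD=q_eq, qYD=q_eq,
        qXfW=q_eq, qXmW=q_eq, qYW=q_eq, qYIW=q_eq, d=0, n=n,
    )
    nxt = slr_step(st, params)
    dev = max(abs(a - b) for a, b in zip(nxt.freqs()[1:], st.freqs()[1:]))
    add("inversion_free_fixed_point", dev, 1e-12)

    # oracle equivalence, n = 1, d in {0, 1}, 200 generations
    worst = 0.0
    for d in (0, 1):
        state = make_initial_slr_state(params, d=d, n=1, q0=2e-4, equilibrate=True)
        table = oracle_from_slr_state(state)
        for _ in range(200):
            state = slr_step(state, params)
            table = oracle_step(table, params)
            mstate = marginalize(table)
            fields = (
                ["YI"]
                + (["qXfD", "qXmD", "qYD"] if d else [])
                + (["qXfW", "qXmW", "qYW", "qYIW"] if 1 - d else [])
            )
            worst = max(
                worst,
                max(abs(getattr(state, f) - getattr(mstate, f)) for f in fields),
            )
    add("oracle_equivalence_n1", worst, 1e-10)

    # neutral Wright-Fisher sanity at small scale
    nparams = ModelParams.from_arm_rate(U=0.0, s=0.01, h=0.25, ntot=100, x=0.2, N=200)
    est = estimate_fixation_probability(
        SimConfig(params=nparams, mode="slr", replicates=20_000, seed=spec.seed)
    )
    add(
        "neutral_slr_within_ci",
        0.0 if est.ci_low <= 2.0 / 200 <= est.ci_high else 1.0,
        0.5,
    )
    report["passed"] = all(c["passed"] for c in report["checks"].values())
    if spec.outdir is not None:
        spec.outdir.mkdir(parents=True, exist_ok=True)
        (spec.outdir / "validation.json").write_text(json.dumps(report, indent=2))
    return report
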