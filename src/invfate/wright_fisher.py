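"""Wright-Fisher fixation probabilities under time-dependent indirect selection.

Replicate simulations track only the inversion frequency; the indirect
selection it experiences is precomputed deterministically under the
pinned-background approximation: deleterious alleles on X and non-inverted
chromosomes are held at their mutation-selection equilibrium while the
inverted haplotype's W-locus frequency returns to equilibrium from 0 (or,
at D loci, stays fixed), yielding a relative-fitness sequence w_rel(t) that
decays from roughly 1 + Ux (for d = 0) to an asymptote: exactly 1 for
initially mutation-free inversions, below 1 for any d >= 1 (the permanent
load).

Each generation the expected inversion frequency is computed from these
fitnesses and the realized frequency is drawn binomially among the N/2 Y
chromosomes (SLR mode) or by multinomial sampling of the N adult karyotypes
(autosomal mode).  Fixation probabilities are estimated from 200 x N
replicates by default, with the captured load (n, d) of every replicate
drawn afresh, so estimates average over the distribution of initial loads.

Backgrounds are pinned at the numerically exact fixed point of the
single-class pinned recursion (equal to mu/(hs) to leading order) rather
than at mu/(hs) itself, so that d = 0 inversions are exactly neutral at the
asymptote and absorption is guaranteed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Any

import numpy as np
from scipy import stats

from ._selection import locus_mean_fitness, mutate, post_selection
from .params import ModelParams, sample_inversion_load, sample_inversion_loads

__all__ = [
    "SimConfig",
    "FixationEstimate",
    "ReplicateOutcome",
    "FitnessTrajectory",
    "fitness_trajectory",
    "simulate_slr_replicate",
    "simulate_autosomal_replicate",
    "estimate_fixation_probability",
]

FIXED, LOST, CENSORED = "FIXED", "LOST", "CENSORED"
_STATE_LABEL = {1: FIXED, 2: LOST, 3: CENSORED}


# ---------------------------------------------------------------------------
# pinned-background fitness terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _PinnedTerms:
    """Per-locus log-fitness terms shared by every (n, d) combination.

    All quantities are log-ratios relative to the non-inverted background
    factor, so a replicate's fitness ratio at generation t is
    ``exp(d*const + (n-d)*series[t])`` (SLR) and analogously per karyotype
    (autosomal).  ``series`` arrays are truncated once the inverted-haplotype
    frequency has converged; beyond them the terms are 0.
    """

    q_x: float
    q_pin: float
    slr_const: float
    slr_series: tuple[float, ...]
    auto_const_ii: float
    auto_const_in: float
    auto_series_ii: tuple[float, ...]
    auto_series_in: tuple[float, ...]


@lru_cache(maxsize=64)
def _pinned_terms(mu: float, s: float, h: float, tol: float) -> _PinnedTerms:
    q_x = mu / (h * s) if mu > 0 and h * s > 0 else 0.0

    # post-mutation fixed point of q <- select(mutate(q) | partner at q_x)
    q = q_x
    for _ in range(2_000_000):
        qn = post_selection(q_x, mutate(q, mu), s, h)[1]
        if abs(qn - q) < min(tol, 1e-15):
            break
        q = qn
    q_pin = mutate(q, mu)

    lN = math.log(locus_mean_fitness(q_x, q_pin, s, h))
    slr_const = math.log(locus_mean_fitness(q_x, 1.0, s, h)) - lN

    lNN = math.log(locus_mean_fitness(q_pin, q_pin, s, h))
    auto_const_ii = math.log(1.0 - s) - lNN
    auto_const_in = math.log(locus_mean_fitness(1.0, q_pin, s, h)) - lNN

    slr_series: list[float] = []
    auto_ii: list[float] = []
    auto_in: list[float] = []
    q = 0.0  # pre-mutation inverted-haplotype W frequency, generation 1
    for _ in range(1_000_000):
        qq = mutate(q, mu)
        slr_series.append(math.log(locus_mean_fitness(q_x, qq, s, h)) - lN)
        auto_ii.append(math.log(locus_mean_fitness(qq, qq, s, h)) - lNN)
        auto_in.append(math.log(locus_mean_fitness(qq, q_pin, s, h)) - lNN)
        if abs(qq - q_pin) < tol:
            break
        q = post_selection(q_x, qq, s, h)[1]
    return _PinnedTerms(
        q_x=q_x,
        q_pin=q_pin,
        slr_const=slr_const,
        slr_series=tuple(slr_series),
        auto_const_ii=auto_const_ii,
        auto_const_in=auto_const_in,
        auto_series_ii=tuple(auto_ii),
        auto_series_in=tuple(auto_in),
    )


def _terms(params: ModelParams, tol: float) -> _PinnedTerms:
    return _pinned_terms(params.mu, params.s, params.h, tol)


@dataclass(frozen=True)
class FitnessTrajectory:
    """Relative fitness sequence of a rare inversion with captured load (n, d).

    ``w_rel[t-1]`` is the fitness of inverted relative to non-inverted
    haplotypes in generation ``t`` (SLR: wYI/wY; autosomal: the
    heterokaryotype ratio wIN/wNN, the rare-inversion limit); after the
    recorded sequence it equals ``asymptote`` (1 iff d = 0).
    """

    mode: str
    d: int
    n: int
    w_rel: np.ndarray
    asymptote: float

    def __call__(self, t: int) -> float:
        if t < 1:
            raise ValueError("generations are counted from t = 1")
        return float(self.w_rel[t - 1]) if t <= len(self.w_rel) else self.asymptote

    def __len__(self) -> int:
        return len(self.w_rel)


def fitness_trajectory(
    params: ModelParams,
    d: int,
    n: int,
    horizon: int | None = None,
    mode: str = "slr",
    tol: float = 1e-12,
) -> FitnessTrajectory:
    """Precompute the pinned-background relative-fitness sequence for one (n, d)."""
    if not 0 <= d <= n:
        raise ValueError(f"need 0 <= d <= n, got d={d}, n={n}")
    tm = _terms(params, tol)
    if mode == "slr":
        series = np.asarray(tm.slr_series)
        logw = d * tm.slr_const + (n - d) * series
        asym = math.exp(d * tm.slr_const)
    elif mode == "autosomal":
        series = np.asarray(tm.auto_series_in)
        logw = d * tm.auto_const_in + (n - d) * series
        asym = math.exp(d * tm.auto_const_in)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    w = np.exp(logw)
    if horizon is not None:
        if len(w) >= horizon:
            w = w[:horizon]
        else:
            w = np.concatenate([w, np.full(horizon - len(w), asym)])
    return FitnessTrajectory(mode=mode, d=d, n=n, w_rel=w, asymptote=asym)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Configuration of a fixation-probability experiment."""

    params: ModelParams
    mode: str = "slr"
    replicates: int | None = None
    seed: int = 0
    max_generations: int | None = None
    traj_tol: float = 1e-12
    q0: float | None = None

    def __post_init__(self) -> None:
        if self.params.N is None:
            raise ValueError("SimConfig requires params with N set")
        if self.mode not in ("slr", "autosomal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.replicates is None:
            self.replicates = 200 * self.params.N
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_generations is None:
            self.max_generations = 20 * self.params.N

    @property
    def initial_frequency(self) -> float:
        return self.q0 if self.q0 is not None else self.params.default_q0(self.mode)


@dataclass(frozen=True)
class ReplicateOutcome:
    outcome: str            # FIXED | LOST | CENSORED
    generation: int         # absorption (or censoring) generation
    n: int                  # loci spanned
    d: int                  # deleterious alleles captured


@dataclass
class FixationEstimate:
    """Monte Carlo fixation-probability estimate with per-d breakdown."""

    mode: str
    replicates: int
    fixations: int
    losses: int
    censored: int
    estimate: float
    ci_low: float
    ci_high: float
    d0_replicates: int
    d0_fixations: int
    d0_estimate: float
    d0_ci_low: float
    d0_ci_high: float
    d_breakdown: dict[int, tuple[int, int]]  # d -> (replicates, fixations)
    mean_fixation_time: float
    analytic: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.fixations + self.losses + self.censored == self.replicates
        assert 0.0 <= self.estimate <= 1.0


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# replicate engines (vectorized across replicates)
# ---------------------------------------------------------------------------


def _run_slr_batch(
    params: ModelParams,
    n_arr: np.ndarray,
    d_arr: np.ndarray,
    N: int,
    p0: float,
    max_gen: int,
    rng: np.random.Generator,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial sampling of inverted-Y counts among the N/2 Y chromosomes."""
    tm = _terms(params, tol)
    series, const = np.asarray(tm.slr_series), tm.slr_const
    T = len(series)
    M = N // 2
    reps = len(n_arr)
    d = d_arr.astype(float)
    nmd = (n_arr - d_arr).astype(float)
    p = np.full(reps, p0)
    state = np.zeros(reps, dtype=np.int8)
    gen = np.zeros(reps, dtype=np.int64)
    idx = np.arange(reps)
    t = 1
    while idx.size:
        if t > max_gen:
            state[idx] = 3
            gen[idx] = max_gen
            break
        cbt = series[t - 1] if t - 1 < T else 0.0
        R = np.exp(d[idx] * const + nmd[idx] * cbt)
        pa = p[idx]
        pe = pa * R / (pa * R + (1.0 - pa))
        c = rng.binomial(M, pe)
        p[idx] = c / M
        fixed = c == M
        lost = c == 0
        done = fixed | lost
        if done.any():
            state[idx[fixed]] = 1
            state[idx[lost]] = 2
            gen[idx[done]] = t
            idx = idx[~done]
        t += 1
    return state, gen


def _run_autosomal_batch(
    params: ModelParams,
    n_arr: np.ndarray,
    d_arr: np.ndarray,
    N: int,
    p0: float,
    max_gen: int,
    rng: np.random.Generator,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial sampling of the N adult karyotypes (II, IN, NN)."""
    tm = _terms(params, tol)
    s_ii, s_in = np.asarray(tm.auto_series_ii), np.asarray(tm.auto_series_in)
    T = len(s_ii)
    reps = len(n_arr)
    d = d_arr.astype(float)
    nmd = (n_arr - d_arr).astype(float)
    p = np.full(reps, p0)
    state = np.zeros(reps, dtype=np.int8)
    gen = np.zeros(reps, dtype=np.int64)
    idx = np.arange(reps)
    t = 1
    while idx.size:
        if t > max_gen:
            state[idx] = 3
            gen[idx] = max_gen
            break
        b_ii = s_ii[t - 1] if t - 1 < T else 0.0
        b_in = s_in[t - 1] if t - 1 < T else 0.0
        rII = np.exp(d[idx] * tm.auto_const_ii + nmd[idx] * b_ii)
        rIN = np.exp(d[idx] * tm.auto_const_in + nmd[idx] * b_in)
        pa = p[idx]
        z = pa * pa * rII + 2.0 * pa * (1.0 - pa) * rIN + (1.0 - pa) ** 2
        pII = pa * pa * rII / z
        pIN = 2.0 * pa * (1.0 - pa) * rIN / z
        nII = rng.binomial(N, pII)
        frac = np.clip(pIN / np.maximum(1.0 - pII, 1e-300), 0.0, 1.0)
        nIN = rng.binomial(N - nII, frac)
        c = 2 * nII + nIN
        p[idx] = c / (2.0 * N)
        fixed = c == 2 * N
        lost = c == 0
        done = fixed | lost
        if done.any():
            state[idx[fixed]] = 1
            state[idx[lost]] = 2
            gen[idx[done]] = t
            idx = idx[~done]
        t += 1
    return state, gen


_BATCH = {"slr": _run_slr_batch, "autosomal": _run_autosomal_batch}


def _run_one(config: SimConfig, rng: np.random.Generator) -> ReplicateOutcome:
    n, d = sample_inversion_load(config.params, rng)
    state, gen = _BATCH[config.mode](
        config.params,
        np.array([n]),
        np.array([d]),
        config.params.N,
        config.initial_frequency,
        config.max_generations,
        rng,
        config.traj_tol,
    )
    return ReplicateOutcome(
        outcome=_STATE_LABEL[int(state[0])], generation=int(gen[0]), n=n, d=d
    )


def simulate_slr_replicate(config: SimConfig, rng: np.random.Generator) -> ReplicateOutcome:
    """One SLR replicate: draw (n, d), start at one copy among N/2 Y's, run to absorption."""
    if config.mode != "slr":
        raise ValueError("config.mode must be 'slr'")
    return _run_one(config, rng)


def simulate_autosomal_replicate(
    config: SimConfig, rng: np.random.Generator
) -> ReplicateOutcome:
    """One autosomal replicate: single copy among 2N homologs, multinomial sampling."""
    if config.mode != "autosomal":
        raise ValueError("config.mode must be 'autosomal'")
    return _run_one(config, rng)


def estimate_fixation_probability(config: SimConfig) -> FixationEstimate:
    """Run the full replicate batch and aggregate the fixation-probability estimate.

    Every replicate draws its own captured load (n, d); the estimate averages
    over that distribution.  Deterministic for a given config and seed.
    """
    params = config.params
    rng = np.random.default_rng(config.seed)
    reps = config.replicates
    n_arr, d_arr = sample_inversion_loads(params, reps, rng)
    state, gen = _BATCH[config.mode](
        params,
        n_arr,
        d_arr,
        params.N,
        config.initial_frequency,
        config.max_generations,
        rng,
        config.traj_tol,
    )
    fixed = state == 1
    k = int(fixed.sum())
    losses = int((state == 2).sum())
    censored = int((state == 3).sum())
    if censored > 0.01 * reps:
        warnings.warn(
            f"{censored}/{reps} replicates censored at the generation cap",
            stacklevel=2,
        )
    lo, hi = _clopper_pearson(k, reps)
    d0 = d_arr == 0
    n0, k0 = int(d0.sum()), int((fixed & d0).sum())
    lo0, hi0 = _clopper_pearson(k0, n0) if n0 else (0.0, 1.0)
    breakdown = {
        int(dv): (int((d_arr == dv).sum()), int((fixed & (d_arr == dv)).sum()))
        for dv in np.unique(d_arr)
    }
    q0 = config.initial_frequency
    load = params.U * params.x / (params.h * params.s) if params.h * params.s else 0.0
    analytic = {
        "q0": q0,
        "load": load,
        "f0": math.exp(-load),
        "q_star": q0 * math.exp(load),
        "f0_q_star": q0,
        "neutral": params.default_q0(config.mode),
    }
    return FixationEstimate(
        mode=config.mode,
        replicates=reps,
        fixations=k,
        losses=losses,
        censored=censored,
        estimate=k / reps,
        ci_low=lo,
        ci_high=hi,
        d0_replicates=n0,
        d0_fixations=k0,
        d0_estimate=k0 / n0 if n0 else float("nan"),
        d0_ci_low=lo0,
        d0_ci_high=hi0,
        d_breakdown=breakdown,
        mean_fixation_time=float(gen[fixed].mean()) if k else float("nan"),
        analytic=analytic,
    )


def estimate_to_record(est: FixationEstimate, extra: dict[str, Any] | None = None) -> dict:
    """Flatten a FixationEstimate into one CSV-friendly record."""
    rec: dict[str, Any] = {
        "mode": est.mode,
        "replicates": est.replicates,
        "fixations": est.fixations,
        "losses": est.losses,
        "censored": est.censored,
        "estimate": est.estimate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "d0_replicates": est.d0_replicates,
        "d0_fixations": est.d0_fixations,
        "d0_estimate": est.d0_estimate,
        "d0_ci_low": est.d0_ci_low,
        "d0_ci_high": est.d0_ci_high,
        "dge1_fixations": est.fixations - est.d0_fixations,
        "mean_fixation_time": est.mean_fixation_time,
    }
    rec.update({f"analytic_{k}": v for k, v in est.analytic.items()})
    if extra:
        rec.update(extra)
    return rec
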