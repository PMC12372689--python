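"""Deterministic recursions for an inversion expanding the sex-linked region.

An inversion on a Y chromosome captures the male-determining factor together
with ``n`` selected PAR loci, ``d`` of which carried a deleterious allele at
the moment of origin (D loci; the remaining ``n - d`` are W loci).  Because
inverted Y's occur only in X/Y-inverted males, the system is described by the
inversion frequency among Y chromosomes, ``YI``, plus deleterious-allele
frequencies in seven locus x chromosome classes: female- and male-transmitted
X's and non-inverted Y's at D and W loci, and the inverted Y at W loci
(``qYID = 1`` identically, and is not stored).

Census point: state frequencies are gametic, before mutation.  One generation
applies mutation (per allele copy, rate ``mu``), then viability selection
(multiplicative across loci; per-locus fitnesses 1, 1-hs, 1-s), then meiosis.
Within every sex x Y-arrangement class the joint distribution over loci stays
at linkage equilibrium (multiplicative fitness, independent per-locus
recombination), so marginal per-locus frequencies evolve autonomously within
classes; the inversion frequency update is driven by the whole-haplotype
fitness products ``wYI`` and ``wY``.

Recombination between the X and a *non-inverted* Y at PAR loci in males
occurs at rate ``r`` per locus (default 1/2, free recombination); there is no
exchange between X and inverted Y over the inverted region.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from ._selection import mutate, post_selection, symmetric_equilibrium
from .params import ModelParams
from .trajectory import (
    STOP_CONVERGED,
    STOP_EXTINCT,
    STOP_MAX_GENERATIONS,
    Trajectory,
)

__all__ = [
    "SLRState",
    "NumericalIntegrityError",
    "make_initial_slr_state",
    "mutate_slr_state",
    "slr_relative_fitness",
    "slr_step",
    "slr_trajectory",
    "inversion_free_equilibrium",
]

DEFAULT_EXTINCTION_THRESHOLD = 1e-5
DEFAULT_CONVERGENCE_TOL = 1e-14

_FREQ_FIELDS = ("YI", "qXfD", "qXmD", "qYD", "qXfW", "qXmW", "qYW", "qYIW")


class NumericalIntegrityError(RuntimeError):
    """A recursion produced a frequency outside [0, 1] (implementation bug)."""


@dataclass(frozen=True)
class SLRState:
    """Inversion frequency among Y's plus the seven class allele frequencies."""

    YI: float
    qXfD: float
    qXmD: float
    qYD: float
    qXfW: float
    qXmW: float
    qYW: float
    qYIW: float
    d: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.d <= self.n):
            raise ValueError(f"need 0 <= d <= n, got d={self.d}, n={self.n}")
        for name in _FREQ_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def freqs(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in _FREQ_FIELDS)


def inversion_free_equilibrium(
    params: ModelParams, tol: float = 1e-12, max_iter: int = 1_000_000
) -> float:
    """Numerically exact inversion-free fixed point of the class recursions.

    With no inversion and equal fitnesses in both sexes, all classes share a
    single equilibrium frequency (the equal-frequency manifold is invariant),
    equal to mu/(hs) to leading order.
    """
    return symmetric_equilibrium(params.mu, params.s, params.h, tol=tol, max_iter=max_iter)


def make_initial_slr_state(
    params: ModelParams,
    d: int,
    n: int,
    q0: float | None = None,
    equilibrate: bool = False,
) -> SLRState:
    """State at the moment a new inversion arises.

    All background classes sit at mutation-selection balance (the analytic
    q_hat, or the numerically iterated fixed point if ``equilibrate``); the
    inverted Y is fixed for deleterious alleles at its ``d`` D loci and free
    of them at its W loci (``qYIW = 0``); the inversion starts at ``q0``
    (default 2/N: a single copy among the N/2 Y chromosomes).
    """
    if q0 is None:
        q0 = params.default_q0("slr")
    if not (0 < q0 < 1):
        raise ValueError(f"q0 must be in (0, 1), got {q0}")
    q = (
        inversion_free_equilibrium(params)
        if equilibrate
        else (params.q_hat if params.mu > 0 else 0.0)
    )
    return SLRState(
        YI=q0, qXfD=q, qXmD=q, qYD=q, qXfW=q, qXmW=q, qYW=q, qYIW=0.0, d=d, n=n
    )


def mutate_slr_state(state: SLRState, params: ModelParams) -> SLRState:
    """Apply one round of per-copy mutation to every stored class frequency."""
    mu = params.mu
    return dataclasses.replace(
        state, **{f: mutate(getattr(state, f), mu) for f in _FREQ_FIELDS[1:]}
    )


def slr_relative_fitness(
    state: SLRState, params: ModelParams
) -> tuple[float, float, float]:
    """Whole-haplotype fitnesses (wYI, wY, wbar) of inverted and standard Y's.

    ``wYI`` multiplies, over the d D loci, the mean fitness of sons pairing a
    deleterious-fixed inverted Y with a maternal X at frequency ``qXfD``, and
    over the n-d W loci the analogous factor with the inverted-Y frequency
    ``qYIW``; ``wY`` is the non-inverted analogue; ``wbar`` is the Y-pool mean
    ``YI*wYI + (1-YI)*wY``.  Evaluated at the supplied state (no mutation is
    applied here).
    """
    s, h = params.s, params.h
    d, n = state.d, state.n
    fD_I = 1.0 - s * (h * (1.0 - state.qXfD) + state.qXfD)
    pXfW, qXfW = 1.0 - state.qXfW, state.qXfW
    pYIW, qYIW = 1.0 - state.qYIW, state.qYIW
    fW_I = 1.0 - s * (h * (pYIW * qXfW + qYIW * pXfW) + qYIW * qXfW)
    pXfD, qXfD = 1.0 - state.qXfD, state.qXfD
    pYD, qYD = 1.0 - state.qYD, state.qYD
    fD_N = 1.0 - s * (h * (pXfD * qYD + qXfD * pYD) + qXfD * qYD)
    pYW, qYW = 1.0 - state.qYW, state.qYW
    fW_N = 1.0 - s * (h * (pXfW * qYW + qXfW * pYW) + qXfW * qYW)
    wYI = fD_I**d * fW_I ** (n - d)
    wY = fD_N**d * fW_N ** (n - d)
    wbar = state.YI * wYI + (1.0 - state.YI) * wY
    return wYI, wY, wbar


def _guard(name: str, v: float) -> float:
    if not (-1e-12 <= v <= 1.0 + 1e-12):
        raise NumericalIntegrityError(f"{name} = {v} left [0, 1]")
    return min(max(v, 0.0), 1.0)


def slr_step(state: SLRState, params: ModelParams, r: float = 0.5) -> SLRState:
    """Advance one full generation: mutation, selection, meiosis.

    The inversion-frequency update equals direct evaluation of the
    whole-haplotype fitness ratio (``slr_relative_fitness``) at the
    post-mutation state; class frequencies follow the within-class marginal
    selection updates and the transmission rules (mothers transmit the
    average of their X's; fathers pass X to daughters and Y/YI to sons, with
    X <-> non-inverted-Y recombination at rate ``r`` per locus and none
    between X and the inverted region of YI).
    """
    s, h = params.s, params.h
    m = mutate_slr_state(state, params)

    wYI, wY, wbar = slr_relative_fitness(m, params)
    YI1 = m.YI * wYI / wbar if wbar > 0 else 0.0

    out: dict[str, float] = {}
    for cat in ("D", "W"):
        qXf = getattr(m, f"qXf{cat}")
        qXm = getattr(m, f"qXm{cat}")
        qY = getattr(m, f"qY{cat}")
        qYI = 1.0 if cat == "D" else m.qYIW

        # post-selection maternal/paternal marginals within each class
        f_m, f_p, _ = post_selection(qXf, qXm, s, h)        # females
        i_m, i_p, _ = post_selection(qXf, qYI, s, h)        # X/YI males
        n_m, n_p, _ = post_selection(qXf, qY, s, h)         # X/Y males

        out[f"qXf{cat}"] = 0.5 * (f_m + f_p)
        out[f"qXm{cat}"] = YI1 * i_m + (1.0 - YI1) * ((1.0 - r) * n_m + r * n_p)
        out[f"qY{cat}"] = (1.0 - r) * n_p + r * n_m
        if cat == "W":
            out["qYIW"] = i_p

    return SLRState(
        YI=_guard("YI", YI1),
        **{k: _guard(k, v) for k, v in out.items()},
        d=state.d,
        n=state.n,
    )


def slr_trajectory(
    initial: SLRState,
    params: ModelParams,
    max_generations: int,
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    convergence_tol: float = DEFAULT_CONVERGENCE_TOL,
    r: float = 0.5,
) -> Trajectory:
    """Iterate :func:`slr_step`, recording state and relative fitness each generation.

    Stops at ``max_generations``, at extinction (``YI`` below the threshold,
    1e-5 by default) or at numerical convergence (sup-norm state change below
    ``convergence_tol``).  The fitness columns recorded at generation ``t``
    are those that acted during the step from ``t`` to ``t+1`` (evaluated at
    the post-mutation state), so ``w_rel`` at ``t = 1`` is the inversion's
    first-generation relative fitness.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    cols: dict[str, list[float]] = {
        k: []
        for k in ("generation", *_FREQ_FIELDS, "wYI", "wY", "w_rel")
    }
    state = initial
    stop = STOP_MAX_GENERATIONS
    for t in range(1, max_generations + 1):
        m = mutate_slr_state(state, params)
        wYI, wY, wbar = slr_relative_fitness(m, params)
        cols["generation"].append(t)
        for f in _FREQ_FIELDS:
            cols[f].append(getattr(state, f))
        cols["wYI"].append(wYI)
        cols["wY"].append(wY)
        cols["w_rel"].append(wYI / wbar)
        nxt = slr_step(state, params, r=r)
        if nxt.YI < extinction_threshold:
            state = nxt
            stop = STOP_EXTINCT
            break
        delta = max(abs(a - b) for a, b in zip(nxt.freqs(), state.freqs()))
        state = nxt
        if delta < convergence_tol:
            stop = STOP_CONVERGED
            break
    meta = {
        "model": "slr",
        "params": params.to_dict(),
        "d": initial.d,
        "n": initial.n,
        "q0": initial.YI,
        "r": r,
        "extinction_threshold": extinction_threshold,
        "convergence_tol": convergence_tol,
        "final_YI": state.YI,
    }
    return Trajectory(columns=cols, stop_reason=stop, metadata=meta)
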