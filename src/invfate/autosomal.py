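"""Exact deterministic recursions for an autosomal inversion with captured load.

The partial-recessivity extension of the classical recursion system for an
autosomal inversion segregating with deleterious mutation-selection-balance
variation.  Three karyotypes exist (inverted homozygote II, heterokaryotype
IN, standard homozygote NN); the state is the inversion frequency ``I`` among
all homologs plus deleterious-allele frequencies on inverted (W loci only;
``QID = 1`` identically) and non-inverted (D and W loci) haplotypes.

Census and life cycle match the SLR engine: gametic state, then mutation,
viability selection (multiplicative across loci) and meiosis.  Non-inverted
haplotypes recombine freely among themselves, as do inverted ones;
heterokaryotypes exchange nothing over the inverted region.

The heterokaryotype fitness at a D locus is ``1 - s*(h*PND + QND)`` — the
genotype there is Aa with probability ``PND`` and aa with probability
``QND``.  Setting ``doubled_het_dominance=True`` instead applies ``2h`` in
that term (an alternative printed form of the mean fitness), applied
consistently to both the frequency update and the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._selection import locus_mean_fitness, mutate, post_selection, symmetric_equilibrium
from .params import ModelParams
from .slr import _guard
from .trajectory import (
    STOP_CONVERGED,
    STOP_EXTINCT,
    STOP_MAX_GENERATIONS,
    Trajectory,
)

__all__ = [
    "AutosomalState",
    "make_initial_autosomal_state",
    "mutate_autosomal_state",
    "autosomal_fitnesses",
    "autosomal_step",
    "autosomal_trajectory",
]

_FREQ_FIELDS = ("I", "QIW", "QND", "QNW")


@dataclass(frozen=True)
class AutosomalState:
    """Inversion frequency among homologs plus haplotype-class allele frequencies."""

    I: float
    QIW: float
    QND: float
    QNW: float
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


def make_initial_autosomal_state(
    params: ModelParams,
    d: int,
    n: int,
    q0: float | None = None,
    equilibrate: bool = False,
) -> AutosomalState:
    """Initial state: backgrounds at mutation-selection balance, QIW = 0, I = q0.

    ``q0`` defaults to 1/(2N), a single copy among the 2N homologs.
    """
    if q0 is None:
        q0 = params.default_q0("autosomal")
    if not (0 < q0 < 1):
        raise ValueError(f"q0 must be in (0, 1), got {q0}")
    q = (
        symmetric_equilibrium(params.mu, params.s, params.h)
        if equilibrate
        else (params.q_hat if params.mu > 0 else 0.0)
    )
    return AutosomalState(I=q0, QIW=0.0, QND=q, QNW=q, d=d, n=n)


def mutate_autosomal_state(state: AutosomalState, params: ModelParams) -> AutosomalState:
    mu = params.mu
    return AutosomalState(
        I=state.I,
        QIW=mutate(state.QIW, mu),
        QND=mutate(state.QND, mu),
        QNW=mutate(state.QNW, mu),
        d=state.d,
        n=state.n,
    )


def autosomal_fitnesses(
    state: AutosomalState,
    params: ModelParams,
    doubled_het_dominance: bool = False,
) -> tuple[float, float, float, float]:
    """Karyotype fitnesses (wII, wIN, wNN) and population mean fitness wbar.

    Evaluated at the supplied state.  ``wbar = I^2*wII + 2I(1-I)*wIN +
    (1-I)^2*wNN``.
    """
    s, h = params.s, params.h
    d, n = state.d, state.n
    h_het = 2.0 * h if doubled_het_dominance else h
    QIW, QND, QNW = state.QIW, state.QND, state.QNW
    wII = (1.0 - s) ** d * locus_mean_fitness(QIW, QIW, s, h) ** (n - d)
    fD_IN = 1.0 - s * (h_het * (1.0 - QND) + QND)
    wIN = fD_IN**d * locus_mean_fitness(QIW, QNW, s, h) ** (n - d)
    wNN = (
        locus_mean_fitness(QND, QND, s, h) ** d
        * locus_mean_fitness(QNW, QNW, s, h) ** (n - d)
    )
    i = state.I
    wbar = i * i * wII + 2.0 * i * (1.0 - i) * wIN + (1.0 - i) * (1.0 - i) * wNN
    return wII, wIN, wNN, wbar


def autosomal_step(
    state: AutosomalState,
    params: ModelParams,
    doubled_het_dominance: bool = False,
) -> AutosomalState:
    """Advance one generation: mutation, karyotype selection, meiosis."""
    s, h = params.s, params.h
    h_het = 2.0 * h if doubled_het_dominance else h
    m = mutate_autosomal_state(state, params)
    wII, wIN, wNN, wbar = autosomal_fitnesses(m, params, doubled_het_dominance)
    i = m.I
    fII = i * i * wII / wbar
    fIN = 2.0 * i * (1.0 - i) * wIN / wbar
    fNN = (1.0 - i) * (1.0 - i) * wNN / wbar
    I1 = fII + 0.5 * fIN

    # per-locus post-selection marginals within each karyotype
    qW_II = post_selection(m.QIW, m.QIW, s, h)[0]
    qW_IN_inv, qW_IN_non, _ = post_selection(m.QIW, m.QNW, s, h)
    qW_NN = post_selection(m.QNW, m.QNW, s, h)[0]
    qD_IN_non = post_selection(1.0, m.QND, s, h_het)[1]
    qD_NN = post_selection(m.QND, m.QND, s, h)[0]

    if I1 > 0.0:
        QIW1 = (fII * qW_II + 0.5 * fIN * qW_IN_inv) / I1
    else:  # no inverted gametes: carry the heterokaryotype-conditional limit
        QIW1 = qW_IN_inv
    if I1 < 1.0:
        QNW1 = (0.5 * fIN * qW_IN_non + fNN * qW_NN) / (1.0 - I1)
        QND1 = (0.5 * fIN * qD_IN_non + fNN * qD_NN) / (1.0 - I1)
    else:
        QNW1, QND1 = qW_IN_non, qD_IN_non

    return AutosomalState(
        I=_guard("I", I1),
        QIW=_guard("QIW", QIW1),
        QND=_guard("QND", QND1),
        QNW=_guard("QNW", QNW1),
        d=state.d,
        n=state.n,
    )


def autosomal_trajectory(
    initial: AutosomalState,
    params: ModelParams,
    max_generations: int,
    extinction_threshold: float = 1e-5,
    convergence_tol: float = 1e-14,
    doubled_het_dominance: bool = False,
) -> Trajectory:
    """Iterate :func:`autosomal_step`, recording karyotype fitnesses and
    the marginal relative fitness of inverted haplotypes,
    ``w_rel = (I*wII + (1-I)*wIN) / wbar``."""
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    cols: dict[str, list[float]] = {
        k: [] for k in ("generation", *_FREQ_FIELDS, "wII", "wIN", "wNN", "w_rel")
    }
    state = initial
    stop = STOP_MAX_GENERATIONS
    for t in range(1, max_generations + 1):
        m = mutate_autosomal_state(state, params)
        wII, wIN, wNN, wbar = autosomal_fitnesses(m, params, doubled_het_dominance)
        cols["generation"].append(t)
        for f in _FREQ_FIELDS:
            cols[f].append(getattr(state, f))
        cols["wII"].append(wII)
        cols["wIN"].append(wIN)
        cols["wNN"].append(wNN)
        cols["w_rel"].append((m.I * wII + (1.0 - m.I) * wIN) / wbar)
        nxt = autosomal_step(state, params, doubled_het_dominance)
        if nxt.I < extinction_threshold:
            state = nxt
            stop = STOP_EXTINCT
            break
        delta = max(abs(a - b) for a, b in zip(nxt.freqs(), state.freqs()))
        state = nxt
        if delta < convergence_tol:
            stop = STOP_CONVERGED
            break
    meta = {
        "model": "autosomal",
        "params": params.to_dict(),
        "d": initial.d,
        "n": initial.n,
        "q0": initial.I,
        "doubled_het_dominance": doubled_het_dominance,
        "extinction_threshold": extinction_threshold,
        "convergence_tol": convergence_tol,
        "final_I": state.I,
    }
    return Trajectory(columns=cols, stop_reason=stop, metadata=meta)
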