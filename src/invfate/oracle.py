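"""Exhaustive genotype-frequency iterator for tiny systems (n <= 2 loci).

Independent correctness oracle for both deterministic engines.  Instead of
tracking per-class marginal allele frequencies, it enumerates every haplotype
(arrangement x allele vector over the n loci) and iterates exact genotype
frequencies through the full life cycle — random union of gametes, per-copy
mutation, multiplicative viability selection, and gamete production with the
stated recombination rules — with no linkage-equilibrium or
class-marginalization assumptions.  Deliberately unoptimized and capped at
n = 2 (table growth is exponential in n).

Haplotype allele vectors are encoded as integers in [0, 2^n); bit ``i`` set
means the deleterious allele ``a`` at locus ``i``.  By the initializers'
convention, loci ``0 .. d-1`` are D loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autosomal import AutosomalState
from .params import ModelParams
from .slr import SLRState

__all__ = [
    "GenotypeTable",
    "oracle_from_slr_state",
    "oracle_from_autosomal_state",
    "oracle_step",
    "marginalize",
]

MAX_LOCI = 2


def _check_n(n: int) -> None:
    if n > MAX_LOCI:
        raise ValueError(f"oracle supports n <= {MAX_LOCI} loci, got n={n}")


def _bits(n: int) -> np.ndarray:
    """(2^n, n) matrix of allele indicators."""
    a = np.arange(2**n)
    return (a[:, None] >> np.arange(n)[None, :]) & 1


def _mutation_matrix(n: int, mu: float) -> np.ndarray:
    """M[a, b] = P(haplotype a mutates to b); A -> a at rate mu, irreversible."""
    bits = _bits(n)
    M = np.ones((2**n, 2**n))
    for i in range(n):
        ai = bits[:, i][:, None]
        bi = bits[:, i][None, :]
        per = np.where(
            ai == 1,
            np.where(bi == 1, 1.0, 0.0),
            np.where(bi == 1, mu, 1.0 - mu),
        )
        M *= per
    return M


def _fitness_matrix(n: int, s: float, h: float) -> np.ndarray:
    """w[a, b] = multiplicative fitness of the diploid with haplotypes a, b."""
    bits = _bits(n)
    counts = bits[:, None, :] + bits[None, :, :]
    per = np.choose(counts, [1.0, 1.0 - h * s, 1.0 - s])
    return per.prod(axis=-1)


def _transmission_matrix(n: int, r: float) -> np.ndarray:
    """T[a, b, e] = P(gamete e | parent haplotypes a 'kept', b 'other').

    Independently at each locus the gamete inherits the kept haplotype's
    allele with probability 1 - r and the other's with probability r.
    r = 1/2 is free recombination; r = 0 transmits haplotype a intact.
    """
    bits = _bits(n)
    T = np.ones((2**n, 2**n, 2**n))
    for i in range(n):
        ai = bits[:, i][:, None, None]
        bi = bits[:, i][None, :, None]
        ei = bits[:, i][None, None, :]
        T *= (1.0 - r) * (ei == ai) + r * (ei == bi)
    return T


@dataclass
class GenotypeTable:
    """Exact gamete-pool frequencies for the oracle.

    SLR mode: ``egg_x`` and ``sperm_x`` are distributions over X haplotypes;
    ``sperm_y`` is a (2, 2^n) distribution over (arrangement, haplotype) for
    Y-bearing sperm, arrangement 0 = standard Y, 1 = inverted Y.  Autosomal
    mode: ``gametes`` is a (2, 2^n) distribution, arrangement 0 = standard,
    1 = inverted.  Each pool sums to one.
    """

    mode: str
    n: int
    d: int
    egg_x: np.ndarray | None = None
    sperm_x: np.ndarray | None = None
    sperm_y: np.ndarray | None = None
    gametes: np.ndarray | None = None

    def check_conservation(self, tol: float = 1e-14) -> None:
        if self.mode == "slr":
            for name, pool in (
                ("egg_x", self.egg_x),
                ("sperm_x", self.sperm_x),
                ("sperm_y", self.sperm_y),
            ):
                if abs(pool.sum() - 1.0) > tol or (pool < -tol).any():
                    raise AssertionError(f"pool {name} not a distribution")
        else:
            if abs(self.gametes.sum() - 1.0) > tol or (self.gametes < -tol).any():
                raise AssertionError("gamete pool not a distribution")


def _haplotype_dist(n: int, qs: list[float]) -> np.ndarray:
    """Product distribution over 2^n haplotypes from per-locus frequencies."""
    bits = _bits(n)
    out = np.ones(2**n)
    for i, q in enumerate(qs):
        out *= np.where(bits[:, i] == 1, q, 1.0 - q)
    return out


def oracle_from_slr_state(state: SLRState) -> GenotypeTable:
    """Linkage-equilibrium gamete pools matching an :class:`SLRState`."""
    n, d = state.n, state.d
    _check_n(n)
    per = lambda qd, qw: [qd] * d + [qw] * (n - d)  # noqa: E731
    egg = _haplotype_dist(n, per(state.qXfD, state.qXfW))
    spx = _haplotype_dist(n, per(state.qXmD, state.qXmW))
    spy = np.zeros((2, 2**n))
    spy[0] = (1.0 - state.YI) * _haplotype_dist(n, per(state.qYD, state.qYW))
    spy[1] = state.YI * _haplotype_dist(n, per(1.0, state.qYIW))
    return GenotypeTable(mode="slr", n=n, d=d, egg_x=egg, sperm_x=spx, sperm_y=spy)


def oracle_from_autosomal_state(state: AutosomalState) -> GenotypeTable:
    n, d = state.n, state.d
    _check_n(n)
    per = lambda qd, qw: [qd] * d + [qw] * (n - d)  # noqa: E731
    g = np.zeros((2, 2**n))
    g[0] = (1.0 - state.I) * _haplotype_dist(n, per(state.QND, state.QNW))
    g[1] = state.I * _haplotype_dist(n, per(1.0, state.QIW))
    return GenotypeTable(mode="autosomal", n=n, d=d, gametes=g)


def oracle_step(
    table: GenotypeTable, params: ModelParams, r: float = 0.5
) -> GenotypeTable:
    """Exact next-generation gamete pools.

    Life cycle: random union of gametes, mutation at rate mu per allele copy,
    multiplicative viability selection within each sex, then meiosis.  In SLR
    mode X and non-inverted Y exchange at rate ``r`` per locus in males and X
    and inverted Y exchange nothing; in autosomal mode like arrangements
    recombine freely and unlike arrangements exchange nothing.
    """
    n = table.n
    _check_n(n)
    M = _mutation_matrix(n, params.mu)
    W = _fitness_matrix(n, params.s, params.h)
    Tfree = _transmission_matrix(n, 0.5)

    if table.mode == "slr":
        Tr = _transmission_matrix(n, r)
        # zygotes: females (egg X x sperm X), males (egg X x Y-bearing sperm)
        F = np.einsum("a,b->ab", table.egg_x, table.sperm_x)
        Mz = np.einsum("a,yb->yab", table.egg_x, table.sperm_y)
        # mutation on each haplotype copy
        F = np.einsum("ab,ac,bd->cd", F, M, M)
        Mz = np.einsum("yab,ac,bd->ycd", Mz, M, M)
        # selection within each sex
        F *= W
        F /= F.sum()
        Mz *= W[None, :, :]
        Mz /= Mz.sum()
        # meiosis
        egg = np.einsum("ab,abe->e", F, Tfree)
        # X-bearing sperm: from X/Y males recombined at rate r; from X/YI intact X
        spx = np.einsum("ab,abe->e", Mz[0], Tr) + Mz[1].sum(axis=1)
        spy = np.zeros((2, 2**n))
        spy[0] = np.einsum("ab,bae->e", Mz[0], Tr)  # Y kept, X other
        spy[1] = Mz[1].sum(axis=0)                   # YI transmitted intact
        return GenotypeTable(
            mode="slr", n=n, d=table.d, egg_x=egg, sperm_x=spx, sperm_y=spy
        )

    # autosomal mode
    g = table.gametes
    Z = np.einsum("ya,zb->yazb", g, g)
    Z = np.einsum("yazb,ac,bd->yczd", Z, M, M)
    Z *= W[None, :, None, :]
    Z /= Z.sum()
    out = np.zeros_like(g)
    for y in range(2):
        for z in range(2):
            block = Z[y, :, z, :]
            if y == z:  # like arrangements recombine freely
                out[y] += np.einsum("ab,abe->e", block, Tfree)
            else:       # heterokaryotype: transmit either haplotype intact
                out[y] += 0.5 * block.sum(axis=1)
                out[z] += 0.5 * block.sum(axis=0)
    return GenotypeTable(mode="autosomal", n=n, d=table.d, gametes=out)


def _class_locus_freqs(pool: np.ndarray, n: int) -> np.ndarray:
    """Per-locus deleterious-allele frequencies of a (possibly unnormalized) pool."""
    tot = pool.sum()
    if tot <= 0:
        return np.zeros(n)
    return (pool @ _bits(n)) / tot


def _category_mean(freqs: np.ndarray, idx: slice) -> float:
    vals = freqs[idx]
    return float(vals.mean()) if vals.size else 0.0


def marginalize(table: GenotypeTable) -> SLRState | AutosomalState:
    """Extract class allele frequencies and the inversion frequency (exact sums).

    D-category (loci 0..d-1) and W-category (loci d..n-1) frequencies are
    averaged within category; with symmetric initial conditions they are
    identical across loci of a category.  Empty categories report 0.
    """
    n, d = table.n, table.d
    D, Wsl = slice(0, d), slice(d, n)
    if table.mode == "slr":
        YI = float(table.sperm_y[1].sum())
        qxf = _class_locus_freqs(table.egg_x, n)
        qxm = _class_locus_freqs(table.sperm_x, n)
        qy = _class_locus_freqs(table.sperm_y[0], n)
        qyi = _class_locus_freqs(table.sperm_y[1], n)
        return SLRState(
            YI=YI,
            qXfD=_category_mean(qxf, D),
            qXmD=_category_mean(qxm, D),
            qYD=_category_mean(qy, D),
            qXfW=_category_mean(qxf, Wsl),
            qXmW=_category_mean(qxm, Wsl),
            qYW=_category_mean(qy, Wsl),
            qYIW=_category_mean(qyi, Wsl),
            d=d,
            n=n,
        )
    I = float(table.gametes[1].sum())
    qn = _class_locus_freqs(table.gametes[0], n)
    qi = _class_locus_freqs(table.gametes[1], n)
    return AutosomalState(
        I=I,
        QIW=_category_mean(qi, Wsl),
        QND=_category_mean(qn, D),
        QNW=_category_mean(qn, Wsl),
        d=d,
        n=n,
    )
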