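"""Per-locus viability-selection primitives shared by all engines.

Fitness is multiplicative across loci, so within any (sex x arrangement)
class the post-selection joint genotype distribution factorizes over loci and
marginal per-locus frequencies can be updated one locus at a time; factors
contributed by other loci cancel from the within-class normalization.
"""

from __future__ import annotations

__all__ = [
    "mutate",
    "locus_mean_fitness",
    "post_selection",
    "pinned_class_equilibrium",
    "symmetric_equilibrium",
]


def mutate(q: float, mu: float) -> float:
    """One round of irreversible A -> a mutation at per-copy rate mu."""
    return q + mu * (1.0 - q)


def locus_mean_fitness(qm: float, qp: float, s: float, h: float) -> float:
    """Mean fitness factor of one locus for maternal/paternal allele freqs qm, qp.

    Allele copies are independent within a class (random union + linkage
    equilibrium), so P(aa) = qm*qp, P(Aa) = qm*(1-qp) + (1-qm)*qp.
    """
    pm, pp = 1.0 - qm, 1.0 - qp
    return 1.0 - s * (h * (qm * pp + pm * qp) + qm * qp)


def post_selection(qm: float, qp: float, s: float, h: float) -> tuple[float, float, float]:
    """Post-selection maternal- and paternal-copy frequencies at one locus.

    Returns ``(qm', qp', wbar)`` where ``wbar`` is the locus mean-fitness
    factor within the class.
    """
    pm, pp = 1.0 - qm, 1.0 - qp
    wbar = 1.0 - s * (h * (qm * pp + pm * qp) + qm * qp)
    qm2 = (qm * qp * (1.0 - s) + qm * pp * (1.0 - h * s)) / wbar
    qp2 = (qm * qp * (1.0 - s) + pm * qp * (1.0 - h * s)) / wbar
    return qm2, qp2, wbar


def pinned_class_equilibrium(
    mu: float, s: float, h: float, partner_q: float, q0: float,
    tol: float = 1e-14, max_iter: int = 2_000_000,
) -> float:
    """Fixed point of the single-class recursion q <- sel(mut(q) | partner pinned).

    Models one haplotype class whose pairing partner's allele frequency is
    held constant at ``partner_q`` (the pinned-background approximation used
    by the Wright-Fisher fitness trajectories).
    """
    q = q0
    for _ in range(max_iter):
        qn = post_selection(partner_q, mutate(q, mu), s, h)[1]
        if abs(qn - q) < tol:
            return qn
        q = qn
    return q


def symmetric_equilibrium(
    mu: float, s: float, h: float, q0: float | None = None,
    tol: float = 1e-14, max_iter: int = 2_000_000,
) -> float:
    """Inversion-free population equilibrium of q <- sel(mut(q) | partner = self).

    With no inversion segregating and identical fitnesses in both sexes, the
    equal-frequency manifold (all chromosome classes at the same q) is
    invariant, so the population fixed point is this scalar one.  Equals
    mu/(hs) to leading order.
    """
    if q0 is None:
        q0 = mu / (h * s) if h * s > 0 else 0.0
        q0 = min(q0, 0.5)
    q = q0
    for _ in range(max_iter):
        qq = mutate(q, mu)
        qn = post_selection(qq, qq, s, h)[0]
        if abs(qn - q) < tol:
            return qn
        q = qn
    return q
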