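"""Model parameters and closed-form quantities at mutation-selection balance.

The model considers ``ntot`` diallelic selected loci in the pseudoautosomal
region (PAR) of a proto sex chromosome (or on an autosomal arm).  Wild-type
alleles ``A`` mutate irreversibly to deleterious alleles ``a`` at rate ``mu``
per copy per generation; genotypic fitnesses at each locus are ``1``,
``1 - h*s`` and ``1 - s`` for AA, Aa and aa, multiplicative across loci.
Deleterious alleles segregate at the mutation-selection balance frequency
``q_hat = mu / (h*s)``.

A new inversion of length ``x`` (fraction of the PAR) spans ``n ~ Poisson(ntot*x)``
selected loci and captures ``d`` deleterious alleles, where ``d`` is binomial
given ``n`` and marginally ``Poisson(U*x/(h*s))`` with ``U = mu*ntot`` the
arm-wide deleterious mutation rate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "AnalyticQuantities",
    "RegimeWarning",
    "DegenerateParameterError",
    "equilibrium_frequency",
    "expected_load",
    "prob_mutation_free",
    "effective_initial_frequency",
    "approx_fixation_probability",
    "initial_relative_fitness_unloaded",
    "sample_inversion_load",
    "sample_inversion_loads",
    "analytic_quantities",
]


class RegimeWarning(UserWarning):
    """The parameters leave the regime where q_hat = mu/(hs) is a good equilibrium.

    The closed-form results assume strong selection relative to mutation
    (``s >> mu``) and partial recessivity (``h > mu/s``).  Outside this regime
    the analytic benchmarks degrade (deliberately explorable, hence a warning).
    """


class DegenerateParameterError(ValueError):
    """Raised when a quantity is undefined for the supplied parameters (e.g. h*s = 0)."""


@dataclass(frozen=True)
class ModelParams:
    """Mutation, selection and genome parameters shared by every module.

    Exactly one of ``mu`` and ``U`` may be supplied to the constructor
    helpers; both are stored and kept consistent (``U = mu * ntot``).

    Parameters
    ----------
    mu : float
        Per-locus, per-generation A -> a mutation probability.
    s : float
        Selection coefficient against the aa homozygote.
    h : float
        Dominance coefficient of the deleterious allele.
    ntot : int
        Number of selected loci in the PAR on the focal chromosome arm.
    x : float
        Inversion length as a fraction of the PAR, in [0, 1].
    N : int, optional
        Total diploid population size (even; N/2 Y chromosomes).  Only
        required for finite-population quantities and default initial
        frequencies.
    """

    mu: float
    s: float
    h: float
    ntot: int
    x: float
    N: int | None = None
    U: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "U", float(self.mu) * int(self.ntot))
        if not (0 < self.s <= 1):
            raise ValueError(f"s must be in (0, 1], got {self.s}")
        if not (0 <= self.h <= 1):
            raise ValueError(f"h must be in [0, 1], got {self.h}")
        if not (0 <= self.x <= 1):
            raise ValueError(f"x must be in [0, 1], got {self.x}")
        if self.mu < 0:
            raise ValueError(f"mu must be nonnegative, got {self.mu}")
        if int(self.ntot) < 1:
            raise ValueError(f"ntot must be >= 1, got {self.ntot}")
        if self.N is not None:
            if self.N < 2 or self.N % 2:
                raise ValueError(f"N must be even and >= 2, got {self.N}")
        self._regime_check()

    def _regime_check(self) -> None:
        if self.mu == 0:
            return
        msgs = []
        if self.s <= 10 * self.mu:
            msgs.append(f"s={self.s} is not >> mu={self.mu}")
        if self.h * self.s > 0 and self.h <= self.mu / self.s:
            msgs.append(f"h={self.h} <= mu/s={self.mu / self.s}")
        if self.h * self.s > 0 and self.mu / (self.h * self.s) >= 0.1:
            msgs.append(f"q_hat={self.mu / (self.h * self.s)} >= 0.1")
        if msgs:
            warnings.warn(
                "mutation-selection balance assumptions strained: " + "; ".join(msgs),
                RegimeWarning,
                stacklevel=3,
            )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_arm_rate(
        cls, U: float, s: float, h: float, ntot: int, x: float, N: int | None = None
    ) -> "ModelParams":
        """Build from the chromosome-arm mutation rate ``U`` (mu = U/ntot)."""
        return cls(mu=U / ntot, s=s, h=h, ntot=ntot, x=x, N=N)

    @classmethod
    def from_mapping(cls, conf: Mapping[str, Any]) -> "ModelParams":
        """Build from a flat key-value mapping (parsed config file or CLI)."""
        keys = {k.lower(): v for k, v in conf.items()}
        ntot = int(keys["ntot"])
        has_mu, has_u = "mu" in keys, "u" in keys
        if has_mu and has_u:
            if not math.isclose(float(keys["u"]), float(keys["mu"]) * ntot, rel_tol=1e-9):
                raise ValueError("inconsistent mu and U supplied (U must equal mu*ntot)")
        if not has_mu and not has_u:
            raise ValueError("one of 'mu' or 'U' is required")
        mu = float(keys["mu"]) if has_mu else float(keys["u"]) / ntot
        N = keys.get("n")
        return cls(
            mu=mu,
            s=float(keys["s"]),
            h=float(keys["h"]),
            ntot=ntot,
            x=float(keys["x"]),
            N=int(N) if N is not None else None,
        )

    # -- derived quantities ------------------------------------------------

    @property
    def q_hat(self) -> float:
        """Mutation-selection balance frequency mu/(h s)."""
        return equilibrium_frequency(self)

    @property
    def n_bar(self) -> float:
        """Expected number of selected loci spanned by the inversion, ntot*x."""
        return self.ntot * self.x

    def default_q0(self, mode: str = "slr") -> float:
        """Single-copy initial frequency: 2/N among Y's (SLR), 1/(2N) autosomal."""
        if self.N is None:
            raise ValueError("N is required for the default initial frequency")
        if mode == "slr":
            return 2.0 / self.N
        if mode == "autosomal":
            return 1.0 / (2.0 * self.N)
        raise ValueError(f"unknown mode {mode!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "mu": self.mu,
            "s": self.s,
            "h": self.h,
            "ntot": self.ntot,
            "x": self.x,
            "U": self.U,
            "N": self.N,
        }


def equilibrium_frequency(params: ModelParams) -> float:
    """Per-locus deleterious-allele frequency at mutation-selection balance, mu/(hs)."""
    if params.mu == 0:
        return 0.0
    hs = params.h * params.s
    if hs == 0:
        raise DegenerateParameterError(
            "equilibrium frequency mu/(hs) undefined for h*s = 0 with mu > 0"
        )
    q = params.mu / hs
    if not (0 < q < 1):
        raise DegenerateParameterError(
            f"equilibrium frequency mu/(hs) = {q} outside (0, 1); "
            "parameters violate the mutation-selection balance assumptions"
        )
    return q


def expected_load(params: ModelParams) -> float:
    """Poisson mean of the captured-mutation count d: U*x/(h*s)."""
    if params.mu == 0 or params.x == 0:
        return 0.0
    return params.U * params.x / (params.h * params.s) if params.h * params.s else _degenerate()


def _degenerate() -> float:
    raise DegenerateParameterError("expected load U*x/(hs) undefined for h*s = 0")


def prob_mutation_free(params: ModelParams) -> float:
    """Probability f0 = exp(-Ux/(hs)) that a new inversion captures no deleterious allele."""
    return math.exp(-expected_load(params))


def effective_initial_frequency(params: ModelParams, q0: float) -> float:
    """Effective initial frequency q* = q0 * exp(Ux/(hs)).

    The deterministic asymptote an initially mutation-free inversion converges
    to once its transient advantage has eroded.  A warning is emitted when the
    leading-order formula exceeds 1 (it is a rare-inversion approximation).
    """
    if not (0 < q0 <= 1):
        raise ValueError(f"q0 must be in (0, 1], got {q0}")
    q_star = q0 * math.exp(expected_load(params))
    if q_star > 1:
        warnings.warn(
            f"q* = {q_star} > 1: the rare-inversion approximation does not apply",
            RegimeWarning,
            stacklevel=2,
        )
    return q_star


def approx_fixation_probability(params: ModelParams, q0: float | None = None) -> float:
    """Closed-form overall fixation probability Pr(fix | x) ~= f0 * q*.

    Algebraically equal to ``q0`` (``f0 * q* = q0`` exactly): length-dependent
    benefits and costs cancel, leaving the neutral single-copy expectation.
    """
    if q0 is None:
        q0 = params.default_q0("slr")
    return prob_mutation_free(params) * effective_initial_frequency(params, q0)


def initial_relative_fitness_unloaded(params: ModelParams) -> float:
    """Leading-order first-generation relative fitness of a mutation-free inversion, 1 + Ux."""
    return 1.0 + params.U * params.x


def sample_inversion_load(
    params: ModelParams, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (n, d) for one new inversion.

    n ~ Poisson(ntot*x) spanned loci; d ~ Binomial(n, q_hat) captured
    deleterious alleles (marginally Poisson(Ux/(hs)) by Poisson thinning).
    """
    n = int(rng.poisson(params.n_bar))
    q = params.q_hat if params.mu > 0 else 0.0
    d = int(rng.binomial(n, q)) if n > 0 else 0
    return n, d


def sample_inversion_loads(
    params: ModelParams, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`sample_inversion_load`; returns arrays (n, d) of length ``size``."""
    n = rng.poisson(params.n_bar, size=size)
    q = params.q_hat if params.mu > 0 else 0.0
    d = rng.binomial(n, q)
    return n, d


@dataclass(frozen=True)
class AnalyticQuantities:
    """Bundle of the closed-form quantities for one parameter set."""

    q_hat: float
    n_bar: float
    load: float
    f0: float
    q0: float
    q_star: float
    w_init: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def analytic_quantities(params: ModelParams, q0: float | None = None) -> AnalyticQuantities:
    """Evaluate every closed-form quantity at once (single JSON-able record)."""
    if q0 is None:
        q0 = params.default_q0("slr")
    return AnalyticQuantities(
        q_hat=params.q_hat if params.mu > 0 else 0.0,
        n_bar=params.n_bar,
        load=expected_load(params),
        f0=prob_mutation_free(params),
        q0=q0,
        q_star=effective_initial_frequency(params, q0),
        w_init=initial_relative_fitness_unloaded(params),
    )
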