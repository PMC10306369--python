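"""Selfing-rescaling mathematics and piecewise-constant demographic models.

A population of ``N`` diploids producing offspring by self-fertilization with
probability ``sigma`` (and by outcrossing otherwise) behaves, at equilibrium,
like a neutral population with inbreeding coefficient ``F = sigma/(2-sigma)``:
the effective size is reduced to ``N/(1+F)`` and the effective per-site
recombination rate to ``r*(1-F)``.  Time-varying models are expressed as an
ordered list of epochs, each holding a census size, a selfing rate and a raw
recombination rate; all rate functions are piecewise constant and
right-continuous in time-before-present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "Epoch",
    "DemographicModel",
    "TransitionScenario",
    "inbreeding_coefficient",
    "selfing_rescalings",
    "recomb_prob_given_tmrca",
    "scenario_to_epochs",
]


def inbreeding_coefficient(sigma: float) -> float:
    """Equilibrium inbreeding coefficient ``F = sigma/(2-sigma)`` for partial selfing."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"selfing rate must lie in [0, 1], got {sigma}")
    return sigma / (2.0 - sigma)


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant epoch of a demographic model.

    Parameters
    ----------
    start_time:
        Epoch start in generations before present (the epoch covers
        ``[start_time, next_start)``).
    N:
        Census diploid population size.
    sigma:
        Selfing rate in ``[0, 1]``.
    rec_rate:
        Raw per-site per-generation recombination rate.
    """

    start_time: float
    N: float
    sigma: float
    rec_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError("epoch start_time must be non-negative")
        if self.N <= 0:
            raise ValueError("population size must be positive")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("selfing rate must lie in [0, 1]")
        if self.rec_rate < 0:
            raise ValueError("recombination rate must be non-negative")

    @property
    def F(self) -> float:
        return inbreeding_coefficient(self.sigma)

    @property
    def N_sigma(self) -> float:
        """Selfing-effective population size ``N/(1+F)``."""
        return self.N / (1.0 + self.F)

    @property
    def rec_rate_effective(self) -> float:
        """Effective recombination rate ``r*(1-F)``."""
        return self.rec_rate * (1.0 - self.F)

    @property
    def coal_rate(self) -> float:
        """Pairwise coalescence rate per generation, ``(1+F)/(2N)``."""
        return (1.0 + self.F) / (2.0 * self.N)


@dataclass(frozen=True)
class DemographicModel:
    """Ordered epochs covering ``[0, inf)`` in time-before-present."""

    epochs: tuple[Epoch, ...]

    def __init__(self, epochs: Sequence[Epoch]):
        epochs = tuple(epochs)
        if not epochs:
            raise ValueError("a demographic model needs at least one epoch")
        if epochs[0].start_time != 0:
            raise ValueError("first epoch must start at time 0")
        starts = [e.start_time for e in epochs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        object.__setattr__(self, "epochs", epochs)

    def epoch_at(self, t: float) -> Epoch:
        """The unique epoch whose interval contains time ``t >= 0``."""
        if t < 0:
            raise ValueError("time must be non-negative")
        for epoch in reversed(self.epochs):
            if t >= epoch.start_time:
                return epoch
        raise AssertionError("unreachable: epochs cover [0, inf)")

    def boundaries(self) -> list[float]:
        return [e.start_time for e in self.epochs]

    @property
    def max_sigma(self) -> float:
        return max(e.sigma for e in self.epochs)

    def constant_rec_rate(self) -> float:
        """The common raw recombination rate, if it is epoch-invariant."""
        rates = {e.rec_rate for e in self.epochs}
        if len(rates) != 1:
            raise ValueError("model has epoch-dependent recombination rates")
        return rates.pop()


@dataclass(frozen=True)
class TransitionScenario:
    """A single stepwise change in selfing rate and one in population size.

    ``sigma`` changes from ``sigma_anc`` to ``sigma_pres`` at ``t_sigma``
    generations before present; ``N`` changes from ``N_anc`` to ``N_pres`` at
    ``t_N``.  Both changes are instantaneous; the two breakpoints may
    coincide.
    """

    N_pres: float
    N_anc: float
    t_N: float
    sigma_pres: float
    sigma_anc: float
    t_sigma: float
    rec_rate: float
    mut_rate: float

    def __post_init__(self) -> None:
        if self.N_pres <= 0 or self.N_anc <= 0:
            raise ValueError("population sizes must be positive")
        if self.t_N < 0 or self.t_sigma < 0:
            raise ValueError("change times must be non-negative")
        for s in (self.sigma_pres, self.sigma_anc):
            if not 0.0 <= s <= 1.0:
                raise ValueError("selfing rates must lie in [0, 1]")
        if self.rec_rate < 0 or self.mut_rate < 0:
            raise ValueError("rates must be non-negative")

    def to_dict(self) -> dict:
        return {
            "N_pres": self.N_pres,
            "N_anc": self.N_anc,
            "t_N": self.t_N,
            "sigma_pres": self.sigma_pres,
            "sigma_anc": self.sigma_anc,
            "t_sigma": self.t_sigma,
            "rec_rate": self.rec_rate,
            "mut_rate": self.mut_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionScenario":
        return cls(**{k: float(d[k]) for k in (
            "N_pres", "N_anc", "t_N", "sigma_pres", "sigma_anc",
            "t_sigma", "rec_rate", "mut_rate")})


def selfing_rescalings(N: float, r: float, mu: float, sigma: float) -> dict:
    """Effective-parameter rescalings implied by a selfing rate.

    Returns a dict with

    - ``F``: inbreeding coefficient ``sigma/(2-sigma)``;
    - ``N_sigma``: effective size ``N/(1+F)``;
    - ``r_sigma``: effective recombination rate ``r*(1-F)``;
    - ``rho_sigma``: population recombination rate ``4*N*r*(1-F)/(1+F)``;
    - ``theta_sigma``: population mutation rate ``4*N*mu/(1+F)``.
    """
    if N <= 0:
        raise ValueError("population size must be positive")
    if r < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    F = inbreeding_coefficient(sigma)
    return {
        "F": F,
        "N_sigma": N / (1.0 + F),
        "r_sigma": r * (1.0 - F),
        "rho_sigma": 4.0 * N * r * (1.0 - F) / (1.0 + F),
        "theta_sigma": 4.0 * N * mu / (1.0 + F),
    }


def recomb_prob_given_tmrca(model: DemographicModel, s: float) -> float:
    """Probability of an effective recombination event for a pair with tmrca ``s``.

    Closed form of ``1 - exp(-∫_0^s 2 (1-σ_k) (2-σ_k)^{-2} r_k dk)`` where
    ``σ_k`` and ``r_k`` are the piecewise-constant selfing and recombination
    rates at time ``k``; the integral is a finite sum over the epochs
    intersecting ``[0, s]``.
    """
    if s < 0:
        raise ValueError("tmrca must be non-negative")
    integral = 0.0
    epochs = model.epochs
    for j, epoch in enumerate(epochs):
        lo = epoch.start_time
        hi = epochs[j + 1].start_time if j + 1 < len(epochs) else math.inf
        if lo >= s:
            break
        span = min(hi, s) - lo
        sig = epoch.sigma
        integral += 2.0 * (1.0 - sig) / (2.0 - sig) ** 2 * epoch.rec_rate * span
    return -math.expm1(-integral)


def scenario_to_epochs(sc: TransitionScenario) -> DemographicModel:
    """Expand a :class:`TransitionScenario` into an explicit epoch model.

    Produces two epochs when ``t_N == t_sigma`` and three otherwise; for
    ``t < min(t_N, t_sigma)`` the present-day values apply.
    """

    def n_at(t: float) -> float:
        return sc.N_pres if t < sc.t_N else sc.N_anc

    def sigma_at(t: float) -> float:
        return sc.sigma_pres if t < sc.t_sigma else sc.sigma_anc

    breaks = sorted({0.0, sc.t_N, sc.t_sigma})
    # coincident or zero-time breakpoints collapse
    epochs = [
        Epoch(start_time=t, N=n_at(t), sigma=sigma_at(t), rec_rate=sc.rec_rate)
        for t in breaks
    ]
    # drop epochs made redundant by a breakpoint at 0 duplicating values
    deduped: list[Epoch] = []
    for e in epochs:
        if deduped and (e.N, e.sigma, e.rec_rate) == (
            deduped[-1].N, deduped[-1].sigma, deduped[-1].rec_rate
        ):
            continue
        deduped.append(e)
    return DemographicModel(deduped)
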