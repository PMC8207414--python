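"""Gaussian stabilizing selection and Ricker density-dependent fecundity.

The degree of adaptation w (fitness proxy) declines with the squared
mismatch between phenotype and optimum,

    w_i = exp(-(z_i - theta_t)^2 / (2 * gamma^2)),

with gamma the width of the fitness function (larger gamma = weaker
selection).  Fecundity scales w by Ricker density regulation,

    w'_i = w_i * exp(psi * (1 - N / K_t)),

where psi is the density-compensation strength distinguishing life-history
strategies: low psi ~ slow, low-fecundity species (e.g. large vertebrates),
high psi ~ fast boom-bust life histories.  A reproductive couple (i, j)
produces Poisson(lambda) offspring with lambda = w'_i + w'_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionParams",
    "LifeHistory",
    "degree_of_adaptation",
    "scaled_fecundity",
    "couple_offspring",
    "ricker_map",
]


@dataclass(frozen=True)
class SelectionParams:
    """gamma: width of the Gaussian fitness function (phenotypic units)."""

    gamma: float = 2.2

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class LifeHistory:
    """psi: density-compensation strength; K: mean carrying capacity."""

    psi: float = 1.0
    K: float = 1000.0

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError(f"psi must be >= 0, got {self.psi}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")


def degree_of_adaptation(
    z: np.ndarray | float, theta: float, params: SelectionParams
) -> np.ndarray | float:
    """Gaussian fitness proxy in (0, 1]; equals 1 iff z == theta."""
    z = np.asarray(z, dtype=float)
    w = np.exp(-((z - theta) ** 2) / (2.0 * params.gamma**2))
    return w if w.ndim else float(w)


def scaled_fecundity(
    w: np.ndarray | float, N: float, lh: LifeHistory, Kt: float | None = None
) -> np.ndarray | float:
    """Ricker-scaled fecundity w' = w * exp(psi * (1 - N / K_t)).

    ``Kt`` is the realized carrying capacity of the current generation
    (defaults to the mean K); ``N`` is the adult count before reproduction.
    """
    if N < 0:
        raise ValueError(f"population size must be >= 0, got {N}")
    K = lh.K if Kt is None else Kt
    if K <= 0:
        raise ValueError(f"carrying capacity must be > 0, got {K}")
    w = np.asarray(w, dtype=float)
    wp = w * np.exp(lh.psi * (1.0 - N / K))
    return wp if wp.ndim else float(wp)


def couple_offspring(
    wprime_i: float, wprime_j: float, rng: np.random.Generator
) -> int:
    """Poisson(lambda) offspring draw for one couple, lambda = w'_i + w'_j."""
    lam = wprime_i + wprime_j
    if lam < 0:
        raise ValueError(f"fecundities must be >= 0, got lambda = {lam}")
    return int(rng.poisson(lam))


def ricker_map(N: float, lh: LifeHistory, w: float = 1.0) -> float:
    """Deterministic skeleton of the expected population dynamics.

    With every female breeding and lambda = w'_i + w'_j, the expected next
    population size is N * mean(w').  For a perfectly adapted population
    (w = 1) this is the classic Ricker map N' = N * exp(psi * (1 - N/K)):
    monotone approach to K for small psi, overshoot and oscillation around
    K for large psi.
    """
    return N * float(scaled_fecundity(w, N, lh))
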