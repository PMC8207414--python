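"""Moving phenotypic optimum with colored (AR(1)) stochasticity.

The environment imposes a phenotypic optimum theta_t that drifts
deterministically at rate ``eta`` per generation and fluctuates around the
trend with first-order autoregressive noise,

    theta_t  = theta*_t + phi_t,      theta*_t = theta0 + eta * t
    phi_t    = alpha * phi_{t-1} + beta * xi_t,   xi_t ~ N(0, 1)

with beta = sigma * sqrt(1 - alpha^2) so that the stationary variance of
phi equals sigma^2 for every admissible autocorrelation alpha (blue noise
alpha < 0, white alpha = 0, red alpha > 0).  The carrying capacity may
additionally fluctuate from generation to generation, drawn from
Normal(K, (sd_pct * K)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnvParams",
    "EnvState",
    "noise_scale",
    "deterministic_optimum",
    "initial_environment",
    "advance_environment",
    "sample_capacity",
    "simulate_noise",
]

#: floor applied to stochastic carrying-capacity draws; K enters the Ricker
#: exponent as a divisor, so K_t must stay positive.
K_FLOOR = 1.0


def noise_scale(alpha: float, sigma2: float) -> float:
    """Noise scale beta = sigma * sqrt(1 - alpha^2).

    Scaling the innovations this way makes the stationary variance of the
    AR(1) deviation process equal to ``sigma2`` regardless of ``alpha``.

    Raises
    ------
    ValueError
        If |alpha| >= 1 (non-stationary process) or sigma2 < 0.
    """
    if not -1.0 < alpha < 1.0:
        raise ValueError(f"autocorrelation must satisfy -1 < alpha < 1, got {alpha}")
    if sigma2 < 0:
        raise ValueError(f"environmental variance must be >= 0, got {sigma2}")
    return math.sqrt(sigma2) * math.sqrt(1.0 - alpha * alpha)


@dataclass(frozen=True)
class EnvParams:
    """Parameters of the stochastic moving-optimum environment.

    Attributes
    ----------
    theta0 : initial optimum (phenotypic units).
    eta : rate of directional change per generation.
    alpha : noise autocorrelation, -1 < alpha < 1.
    sigma2 : stationary environmental variance sigma^2.
    K : mean carrying capacity (individuals).
    sd_pct : stochastic-K standard deviation as a fraction of K (0 = fixed K).
    """

    theta0: float = 0.0
    eta: float = 0.0
    alpha: float = 0.0
    sigma2: float = 1.0
    K: float = 1000.0
    sd_pct: float = 0.0

    def __post_init__(self) -> None:
        noise_scale(self.alpha, self.sigma2)  # validates alpha, sigma2
        if self.K <= 0:
            raise ValueError(f"carrying capacity must be > 0, got {self.K}")
        if self.sd_pct < 0:
            raise ValueError(f"sd_pct must be >= 0, got {self.sd_pct}")

    @property
    def beta(self) -> float:
        """Adjusted innovation scale; always recomputed, never stored."""
        return noise_scale(self.alpha, self.sigma2)


@dataclass(frozen=True)
class EnvState:
    """Realized environment of one generation.

    ``theta = theta_star + phi`` holds by construction; ``Kt`` is the
    carrying capacity in force this generation.
    """

    t: int
    phi: float
    theta_star: float
    theta: float
    Kt: float


def deterministic_optimum(t: float, params: EnvParams) -> float:
    """Trend component theta*_t = theta0 + eta * t (t >= 0)."""
    if t < 0:
        raise ValueError(f"generation index must be >= 0, got {t}")
    return params.theta0 + params.eta * t


def sample_capacity(params: EnvParams, rng: np.random.Generator) -> float:
    """Carrying capacity draw: Normal(K, (sd_pct*K)^2), floored at K_FLOOR.

    Returns K exactly when sd_pct == 0 (no draw is consumed).
    """
    if params.sd_pct == 0:
        return float(params.K)
    draw = rng.normal(params.K, params.sd_pct * params.K)
    return max(float(draw), K_FLOOR)


def initial_environment(params: EnvParams, rng: np.random.Generator) -> EnvState:
    """Environment at t = 0.

    phi_0 is a single scaled innovation beta * xi_0, so generation 0
    already carries stochasticity and the process starts at stationarity
    in distribution.
    """
    phi0 = params.beta * rng.standard_normal() if params.sigma2 > 0 else 0.0
    theta_star = deterministic_optimum(0, params)
    return EnvState(
        t=0,
        phi=phi0,
        theta_star=theta_star,
        theta=theta_star + phi0,
        Kt=sample_capacity(params, rng),
    )


def advance_environment(
    state: EnvState, params: EnvParams, rng: np.random.Generator
) -> EnvState:
    """Step the environment from generation t to t + 1.

    phi' = alpha * phi + beta * xi with xi ~ N(0,1); the innovation is
    consumed even when sigma2 == 0 would make it irrelevant only if
    sigma2 > 0 (a deterministic environment consumes no randomness, so
    seeded runs with and without noise share population draws).
    """
    if params.sigma2 > 0:
        phi = params.alpha * state.phi + params.beta * rng.standard_normal()
    else:
        phi = 0.0
    t = state.t + 1
    theta_star = deterministic_optimum(t, params)
    return EnvState(
        t=t,
        phi=phi,
        theta_star=theta_star,
        theta=theta_star + phi,
        Kt=sample_capacity(params, rng),
    )


def simulate_noise(n_steps: int, params: EnvParams, rng: np.random.Generator) -> np.ndarray:
    """Trajectory of the deviation phi over ``n_steps`` generations.

    Steps the environment one generation at a time (the same code path the
    simulator uses) and returns the phi series including phi_0; intended
    for stationarity and autocorrelation diagnostics.
    """
    state = initial_environment(params, rng)
    out = np.empty(n_steps + 1)
    out[0] = state.phi
    for i in range(1, n_steps + 1):
        state = advance_environment(state, params, rng)
        out[i] = state.phi
    return out


def trajectory_frame(states: list[EnvState]):
    """Tidy export of an environment trajectory (t, theta_star, phi, theta, Kt)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t": [s.t for s in states],
            "theta_star": [s.theta_star for s in states],
            "phi": [s.phi for s in states],
            "theta": [s.theta for s in states],
            "Kt": [s.Kt for s in states],
        }
    )
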