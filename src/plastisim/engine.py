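"""Generation loop and whole-replicate simulation.

One generation proceeds in a fixed order: develop phenotypes of all adults
from the cue optimum, evaluate the degree of adaptation against the
current optimum, scale fecundity by Ricker density dependence, record the
cohort statistics, mate (lottery polygyny) and draw Poisson offspring with
inheritance and mutation, kill all adults (non-overlapping generations),
and advance the environment.

Two development-cue schedules are supported:

- ``current``  labile traits: development sees the optimum of the
  generation being lived (plastic response follows the change);
- ``previous`` constant characters: the sensitive period closed in the
  previous environment, so development uses the previous generation's
  realized optimum while selection acts on the current one (the first
  generation develops on theta0).

Generation ``g`` (1-based) experiences the environment at time t = g - 1,
so under a deterministic trend the optimum of generation g is
theta0 + eta * (g - 1); with eta = 0.02 the saturation threshold pi/2 is
first exceeded at generation 80 (0.02 * 79 = 1.58).

Each replicate owns a single RNG stream seeded as base_seed +
replicate_index; the environment and the population consume it in the
fixed order written here, making whole replicates bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import (
    EnvParams,
    EnvState,
    advance_environment,
    initial_environment,
)
from .genetics import MutationModel, Population, inherit, init_population, mutate, pair_mates
from .plasticity import PlasticitySpec, develop_phenotype
from .selection import LifeHistory, SelectionParams, degree_of_adaptation, scaled_fecundity

__all__ = [
    "SimulationConfig",
    "ReplicateRecord",
    "run_generation",
    "run_replicate",
    "check_extinction",
]

SERIES_COLUMNS = ["t", "N", "theta", "mean_w", "var_a", "var_z", "mean_a", "mean_z"]


@dataclass(frozen=True)
class SimulationConfig:
    """Full scenario: environment, selection, life history, plasticity,
    mutation, genetic initialization and run controls."""

    env: EnvParams = EnvParams()
    selection: SelectionParams = SelectionParams()
    lh: LifeHistory = LifeHistory()
    plasticity: PlasticitySpec = PlasticitySpec()
    mutation: MutationModel = MutationModel()
    VG: float = 0.2
    L: int = 1
    t_max: int = 250
    development_cue: str = "current"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        if self.development_cue not in ("current", "previous"):
            raise ValueError(
                f"development_cue must be 'current' or 'previous', got {self.development_cue!r}"
            )
        if self.lh.K != self.env.K:
            raise ValueError(
                f"carrying capacity disagrees between environment ({self.env.K}) "
                f"and life history ({self.lh.K})"
            )
        if self.VG < 0 or self.L < 1:
            raise ValueError("need VG >= 0 and L >= 1")

    @classmethod
    def from_values(
        cls,
        *,
        K: float = 1000.0,
        gamma: float = 2.2,
        sigma2: float = 1.0,
        theta0: float = 0.0,
        eta: float = 0.0,
        alpha: float = 0.0,
        psi: float = 1.0,
        plasticity: str = "none",
        b: float = 0.5,
        VE: float = 1.0,
        VG: float = 0.2,
        L: int = 1,
        mu: float = 1e-3,
        MV: float = 0.2,
        t_max: int = 250,
        sd_pct: float = 0.0,
        development_cue: str = "current",
        seed: int = 0,
    ) -> "SimulationConfig":
        """Build a consistent config from flat parameter values."""
        return cls(
            env=EnvParams(theta0=theta0, eta=eta, alpha=alpha, sigma2=sigma2, K=K, sd_pct=sd_pct),
            selection=SelectionParams(gamma=gamma),
            lh=LifeHistory(psi=psi, K=K),
            plasticity=PlasticitySpec(mode=plasticity, b=b, VE=VE),
            mutation=MutationModel(mu=mu, MV=MV),
            VG=VG,
            L=L,
            t_max=t_max,
            development_cue=development_cue,
            seed=seed,
        )


@dataclass
class ReplicateRecord:
    """Outcome of one replicate.

    ``series`` holds one row per completed generation (recorded on the
    adult cohort before reproduction); ``extinction_generation`` is the
    first generation that could not be run, or None if the replicate
    reached t_max.
    """

    persisted: bool
    extinction_generation: int | None
    series: pd.DataFrame


def check_extinction(pop: Population) -> bool:
    """True when no breeding pair can form: empty or single-sex cohort."""
    if pop.size == 0:
        return True
    n_female = int(pop.is_female.sum())
    return n_female == 0 or n_female == pop.size


def _cohort_stats(pop: Population, env: EnvState) -> dict:
    a = pop.a
    n = pop.size
    ddof_ok = n >= 2
    return {
        "t": env.t,
        "N": n,
        "theta": env.theta,
        "mean_w": float(np.mean(pop.w)),
        "var_a": float(np.var(a, ddof=1)) if ddof_ok else float("nan"),
        "var_z": float(np.var(pop.z, ddof=1)) if ddof_ok else float("nan"),
        "mean_a": float(np.mean(a)),
        "mean_z": float(np.mean(pop.z)),
    }


def run_generation(
    pop: Population,
    env: EnvState,
    config: SimulationConfig,
    rng: np.random.Generator,
    cue_theta: float | None = None,
) -> tuple[Population, EnvState, dict]:
    """Advance one generation; returns (offspring cohort, next env, stats row).

    ``cue_theta`` is the optimum development responds to; defaults to the
    current optimum (labile traits).  An empty offspring cohort is a legal
    outcome and means extinction.
    """
    if pop.size == 0:
        raise ValueError("cannot run a generation on an empty population")
    if cue_theta is None:
        cue_theta = env.theta

    # 1. development
    dev = develop_phenotype(pop.a, cue_theta, config.plasticity, rng)
    pop.e, pop.z = dev.e, dev.z

    # 2. degree of adaptation against the *current* optimum
    pop.w = np.asarray(degree_of_adaptation(pop.z, env.theta, config.selection))

    # 3. density-dependent fecundity with this generation's realized K_t
    pop.wprime = np.asarray(scaled_fecundity(pop.w, pop.size, config.lh, env.Kt))

    # 4. cohort statistics (pre-reproduction adults)
    row = _cohort_stats(pop, env)

    # 5. reproduction: lottery polygyny, Poisson offspring, inheritance, mutation
    females, males = pair_mates(pop, rng)
    if females.size:
        lam = pop.wprime[females] + pop.wprime[males]
        counts = rng.poisson(lam)
        mothers = np.repeat(females, counts)
        fathers = np.repeat(males, counts)
        child_alleles = inherit(pop.alleles[mothers], pop.alleles[fathers], rng)
        child_alleles = mutate(child_alleles, config.mutation, rng)
        offspring = Population(
            alleles=child_alleles,
            is_female=rng.random(child_alleles.shape[0]) < 0.5,
        )
    else:
        offspring = Population(
            alleles=np.empty((0, config.L, 2)), is_female=np.empty(0, dtype=bool)
        )

    # 6. adults die; environment advances
    next_env = advance_environment(env, config.env, rng)
    return offspring, next_env, row


def run_replicate(config: SimulationConfig, replicate_index: int = 0) -> ReplicateRecord:
    """Run one replicate to t_max generations or extinction.

    Deterministic given (config.seed, replicate_index): the replicate's RNG
    is seeded with their sum and consumed in a fixed order (environment
    initialization, population initialization, then per-generation draws).
    """
    rng = np.random.default_rng(config.seed + replicate_index)
    env = initial_environment(config.env, rng)
    pop = init_population(
        K=int(config.env.K), theta0=config.env.theta0, VG=config.VG, L=config.L, rng=rng
    )

    rows: list[dict] = []
    extinction_generation: int | None = None
    prev_theta = config.env.theta0  # cue of generation 1 under 'previous'
    for g in range(1, config.t_max + 1):
        if check_extinction(pop):
            extinction_generation = g
            break
        cue = env.theta if config.development_cue == "current" else prev_theta
        prev_theta = env.theta
        pop, env, row = run_generation(pop, env, config, rng, cue_theta=cue)
        rows.append(row)

    series = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    return ReplicateRecord(
        persisted=extinction_generation is None,
        extinction_generation=extinction_generation,
        series=series,
    )
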