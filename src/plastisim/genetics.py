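"""Diploid genetics: population state, mating, inheritance, mutation.

Each individual carries L diploid loci with additive allelic values; the
genetic component of the phenotype is a = sum of all allelic values.  The
population starts locally adapted: alleles drawn from Normal(theta0, VG/2)
so that Var(a) = 2L * (VG/2) equals the initial genetic variance VG (for
the default single locus).  Mating is lottery polygyny — every female
samples one male uniformly with replacement — and each haplotype mutates
independently per locus with probability mu, adding a Normal(0, MV) effect
to the allelic value (continuum of alleles).

The population is stored as a struct-of-arrays (`Population`) so that
development, selection and reproduction vectorize over the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

__all__ = [
    "MutationModel",
    "Population",
    "init_population",
    "pair_mates",
    "inherit",
    "mutate",
]


@dataclass(frozen=True)
class MutationModel:
    """mu: per-haplotype per-locus mutation probability; MV: effect variance."""

    mu: float = 1e-3
    MV: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.mu}")
        if self.MV < 0:
            raise ValueError(f"mutation effect variance must be >= 0, got {self.MV}")


@dataclass
class Population:
    """Cohort of adults as aligned arrays.

    alleles has shape (N, L, 2); is_female is boolean.  e, z, w, wprime are
    filled by the engine during development and selection and are NaN for
    an undeveloped cohort.
    """

    alleles: np.ndarray
    is_female: np.ndarray
    e: np.ndarray = field(default=None)  # type: ignore[assignment]
    z: np.ndarray = field(default=None)  # type: ignore[assignment]
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    wprime: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError(f"alleles must have shape (N, L, 2), got {self.alleles.shape}")
        if self.is_female.shape[0] != self.alleles.shape[0]:
            raise ValueError("sex array and allele array disagree on N")
        n = self.size
        for name in ("e", "z", "w", "wprime"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(n, np.nan))

    @property
    def size(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def a(self) -> np.ndarray:
        """Genetic component: additive sum over loci and haplotypes."""
        return self.alleles.sum(axis=(1, 2))

    def snapshot_frame(self):
        """Per-individual export (id, sex, a, e, z, w) for debugging/fixtures."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.size),
                "sex": np.where(self.is_female, "female", "male"),
                "a": self.a,
                "e": self.e,
                "z": self.z,
                "w": self.w,
            }
        )


def init_population(
    K: int,
    theta0: float,
    VG: float,
    L: int,
    rng: np.random.Generator,
) -> Population:
    """Locally adapted founding population of N = K adults.

    Every allele ~ Normal(theta0, VG/2); sexes i.i.d. Bernoulli(1/2).
    Phenotypes remain undeveloped until the first engine step.

    Note: the mean of a is L * 2 * theta0, i.e. theta0 only for the default
    theta0 = 0; a nonzero theta0 with this literal allele-mean rule shifts
    the population mean genotype to 2 L theta0.
    """
    K = int(K)
    if K < 2:
        raise ValueError(f"need K >= 2 to ever form a breeding pair, got {K}")
    if VG < 0:
        raise ValueError(f"initial genetic variance must be >= 0, got {VG}")
    if L < 1:
        raise ValueError(f"need at least one locus, got {L}")
    if theta0 != 0.0:
        import warnings

        warnings.warn(
            "allele mean theta0 != 0 makes the mean genetic component 2*L*theta0",
            stacklevel=2,
        )
    alleles = rng.normal(theta0, math.sqrt(VG / 2.0), size=(K, L, 2))
    is_female = rng.random(K) < 0.5
    return Population(alleles=alleles, is_female=is_female)


def pair_mates(
    pop: Population, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Lottery polygyny: each female draws one male uniformly, with replacement.

    Returns (female_indices, male_indices) of equal length; both empty when
    either sex is absent (reproduction then fails, signalling extinction).
    """
    females = np.flatnonzero(pop.is_female)
    males = np.flatnonzero(~pop.is_female)
    if females.size == 0 or males.size == 0:
        empty = np.empty(0, dtype=int)
        return empty, empty
    chosen = males[rng.integers(0, males.size, size=females.size)]
    return females, chosen


def inherit(
    mother_alleles: np.ndarray,
    father_alleles: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mendelian transmission for a batch of offspring.

    Parameters are (n, L, 2) arrays of the parental genotypes, one row per
    offspring.  Per locus, one of the mother's two alleles and one of the
    father's two are picked uniformly and independently; only the genetic
    component is transmitted (the environmental component e is not
    heritable).  Returns the (n, L, 2) offspring genotypes with the
    maternal haplotype in slot 0.
    """
    mother_alleles = np.asarray(mother_alleles, dtype=float)
    father_alleles = np.asarray(father_alleles, dtype=float)
    if mother_alleles.shape != father_alleles.shape:
        raise ValueError(
            f"parental genotype shapes disagree: {mother_alleles.shape} vs {father_alleles.shape}"
        )
    n, L, _ = mother_alleles.shape
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    from_mother = mother_alleles[rows, cols, rng.integers(0, 2, size=(n, L))]
    from_father = father_alleles[rows, cols, rng.integers(0, 2, size=(n, L))]
    return np.stack([from_mother, from_father], axis=2)


def mutate(
    alleles: np.ndarray, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Continuum-of-alleles mutation.

    Independently per haplotype per locus, with probability mu the allelic
    value is incremented by a Normal(0, MV) draw.  Returns a new array;
    with mu = 0 the input is returned unchanged (bit-identical).
    """
    if model.mu == 0.0:
        return alleles
    hit = rng.random(alleles.shape) < model.mu
    n_hit = int(hit.sum())
    if n_hit == 0:
        return alleles
    out = alleles.copy()
    out[hit] += rng.normal(0.0, math.sqrt(model.MV), size=n_hit)
    return out
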