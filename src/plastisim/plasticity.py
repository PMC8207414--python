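"""Phenotype development: reaction norms with and without limits.

The ecological phenotype decomposes as z = a + e, with a the additive
genetic component and e the environmental (plastic) component.  Five
development rules are supported:

- ``none``        genetic determinism, e = 0 (narrow-sense h^2 = 1);
- ``random``      nonadaptive noise, e ~ Normal(0, VE), redrawn each
                  generation (labile);
- ``linear``      classic linear reaction norm e = b * theta (no limit;
                  b = 1 is "perfect plasticity");
- ``saturating``  flexible response toward the optimum that saturates:
                  e = sin(|dE|) * dE for |dE| <= pi/2, and e = pi/2 in
                  magnitude beyond (dE = theta - a is the required shift);
- ``sinusoidal``  flexible response that decays past pi/2 and fails
                  entirely beyond |dE| > pi (e = 0: development fails).

The two limited rules map phenotypic units 1:1 onto radians inside the
sine, so the saturation point sits at a mismatch of pi/2 ~ 1.5708
phenotypic units.  Because many distinct genotypes a develop to the same
z near the optimum, these rules realise a many-to-one genotype-phenotype
map: developmental canalization at the population level and cryptic
genetic variation once the limit is exceeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PlasticitySpec", "DevelopmentResult", "develop_phenotype", "MODES"]

MODES = ("none", "random", "linear", "saturating", "sinusoidal")

HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class PlasticitySpec:
    """Development rule and its parameters.

    b is consulted only in ``linear`` mode, VE only in ``random`` mode.
    """

    mode: str = "none"
    b: float = 0.5
    VE: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown plasticity mode {self.mode!r}; expected one of {MODES}")
        if self.VE < 0:
            raise ValueError(f"VE must be >= 0, got {self.VE}")


@dataclass(frozen=True)
class DevelopmentResult:
    """Outcome of development for a cohort (arrays are aligned per individual).

    delta_e and omega are populated for the limited (saturating/sinusoidal)
    rules and None otherwise.
    """

    e: np.ndarray
    z: np.ndarray
    delta_e: np.ndarray | None = None
    omega: np.ndarray | None = None


def develop_phenotype(
    a: np.ndarray,
    theta_cue: float,
    spec: PlasticitySpec,
    rng: np.random.Generator | None = None,
) -> DevelopmentResult:
    """Develop phenotypes z = a + e for a cohort of genetic values ``a``.

    Parameters
    ----------
    a : array of genetic components.
    theta_cue : the optimum used as developmental cue.  The engine passes
        the current generation's optimum for labile traits, or the previous
        generation's for constant characters whose sensitive period closed
        before the environment changed.
    spec : development rule.
    rng : required for ``random`` mode only.
    """
    a = np.asarray(a, dtype=float)
    mode = spec.mode

    if mode == "none":
        e = np.zeros_like(a)
        return DevelopmentResult(e=e, z=a + e)

    if mode == "random":
        if rng is None:
            raise ValueError("random plasticity requires an rng")
        e = rng.normal(0.0, math.sqrt(spec.VE), size=a.shape)
        return DevelopmentResult(e=e, z=a + e)

    if mode == "linear":
        e = np.full_like(a, spec.b * theta_cue)
        return DevelopmentResult(e=e, z=a + e)

    # limited, developmentally flexible rules
    delta_e = theta_cue - a
    abs_de = np.abs(delta_e)
    omega = np.sin(np.minimum(abs_de, math.pi))  # sin(|dE|), kept in [0, 1] domain-wise

    if mode == "saturating":
        # beyond |dE| > pi/2 the response saturates: dE clamped to +/- pi/2,
        # where sin(pi/2) = 1, so |e| caps at pi/2
        clamped = np.clip(delta_e, -HALF_PI, HALF_PI)
        e = np.where(abs_de > HALF_PI, clamped, np.sin(abs_de) * delta_e)
        omega = np.where(abs_de > HALF_PI, 1.0, omega)
    elif mode == "sinusoidal":
        # past |dE| > pi the organism fails to develop any response
        e = np.where(abs_de > math.pi, 0.0, np.sin(abs_de) * delta_e)
    else:  # pragma: no cover - guarded by PlasticitySpec
        raise ValueError(f"unknown plasticity mode {mode!r}")

    return DevelopmentResult(e=e, z=a + e, delta_e=delta_e, omega=omega)
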