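"""Model parameters for the five-species Min reaction-diffusion network.

The model tracks three cytoplasmic species (MinD:ADP, MinD:ATP, MinE, in
proteins/um^3) and two membrane-bound species (MinD:ATP and the MinD:MinE:ATP
complex, in proteins/um^2).  The rate constants below are the widely used
Huang parameter set for wild-type E. coli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class RateParameters:
    """Diffusion and reaction rate constants.

    Attributes
    ----------
    D_D, D_E:
        Cytoplasmic diffusion constants for MinD and MinE (um^2/s).
    k_exchange:
        MinD:ADP -> MinD:ATP nucleotide exchange rate (1/s).
    k_D:
        Spontaneous MinD:ATP membrane attachment rate (um/s).
    k_dD:
        Cooperative recruitment of MinD:ATP by membrane-bound MinD (um^3/s).
    k_de:
        ATP hydrolysis / complex breakup rate on the membrane (1/s).
    k_E:
        Binding of cytoplasmic MinE to membrane-bound MinD:ATP (um^3/s).
    """

    D_D: float = 2.5
    D_E: float = 2.5
    k_exchange: float = 1.0
    k_D: float = 0.025
    k_dD: float = 0.0015
    k_de: float = 0.7
    k_E: float = 0.093

    def __post_init__(self) -> None:
        for name in ("D_D", "D_E", "k_exchange", "k_D", "k_dD", "k_de", "k_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be nonnegative")

    @property
    def D_max(self) -> float:
        return max(self.D_D, self.D_E)


HUANG_RATES = RateParameters()

#: Default bulk concentrations (proteins/um^3), the cylindrical-cell lineal
#: densities 1000/um (MinD) and 350/um (MinE) divided by pi * (0.5 um)^2.
MIND_CONCENTRATION = 1000.0 / (math.pi * 0.5**2)
MINE_CONCENTRATION = 350.0 / (math.pi * 0.5**2)


def concentrations_from_linear_density(
    lineal_mind: float, lineal_mine: float, radius: float
) -> tuple[float, float]:
    """Convert per-unit-length protein numbers in a cylinder to volume densities.

    Parameters
    ----------
    lineal_mind, lineal_mine:
        Total MinD and MinE per unit cell length (proteins/um).
    radius:
        Cylinder radius (um).

    Returns
    -------
    (MinD, MinE) concentrations in proteins/um^3.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    area = math.pi * radius * radius
    return lineal_mind / area, lineal_mine / area


@dataclass(frozen=True)
class InitialCondition:
    """How a simulation is seeded.

    ``mind`` and ``mine`` are bulk concentrations (proteins/um^3).  The
    homogeneous state is a fixed point of the dynamics, so a perturbation is
    required to start the oscillation: either a seeded random multiplicative
    perturbation of the MinD:ADP field (``mode="random"``) or a deterministic
    gradient along the long axis (``mode="polar-gradient"``).
    """

    mind: float = MIND_CONCENTRATION
    mine: float = MINE_CONCENTRATION
    mode: str = "random"
    amplitude: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mind < 0 or self.mine < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.mode not in ("random", "polar-gradient"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if not 0 <= self.amplitude < 1:
            raise ValueError("perturbation amplitude must be in [0, 1)")
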