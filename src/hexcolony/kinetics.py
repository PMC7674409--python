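"""Monod growth kinetics, yields and stoichiometry.

Three trophic roles are modelled, mirroring the denitrification pathway of
*Pseudomonas stutzeri*:

* **complete reducer** — grows on nitrate (whole pathway, used pairwise in
  the competition scenario; no nitrite is released),
* **producer** — grows on nitrate and excretes one mole of nitrite per
  mole of nitrate reduced,
* **consumer** — grows on the nitrite supplied by the producer.

Growth rate is Monod in the role's substrate, ``mu = mu_max * C / (C +
K)``.  Nitrite toxicity (strong mutualism, low ambient pH) acts purely on
the biomass yield of *both* strains, interpolating between ``y_max`` at
zero nitrite and ``y_min`` at saturating nitrite; growth rate is never
affected by toxicity.  Biomass integrates explicitly,
``m(t+dt) = m(t) * (1 + mu*dt)``, and substrate consumption follows the
yield: ``moles = mu * m * dt / Y``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StrainRole",
    "Strain",
    "KineticParams",
    "GrowthResult",
    "growth_rate",
    "yield_coefficient",
    "biomass_step",
    "consumption",
    "step_growth",
]


class StrainRole(enum.Enum):
    COMPLETE_REDUCER = "complete_reducer"
    PRODUCER = "producer"
    CONSUMER = "consumer"


@dataclass(frozen=True)
class Strain:
    """A strain is a trophic role plus a label (e.g. fluorescent tag)."""

    role: StrainRole
    label: str


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and yield parameters.

    Defaults are the anaerobic denitrification values used throughout:
    ``mu_max = 5.4e-6 s⁻¹`` (doubling time ≈ 36 h), half-saturation
    constants of 0.04 mM for both substrates (nitrite deliberately equal
    to nitrate to avoid a parameterisation bias), nitrite inhibition
    constant 0.02 mM, and yields 0.06 / 0.006 kgDW mol⁻¹ (minimum yield
    10% of the maximum).  ``toxicity_on`` selects the strong-mutualism
    condition (ambient pH 6.5) in which accumulated nitrite lowers the
    yield of both strains.
    """

    mu_max: float = 5.4e-6
    k_no3: float = 0.04
    k_no2: float = 0.04
    k_inh: float = 0.02
    y_max: float = 0.06
    y_min: float = 0.006
    toxicity_on: bool = False

    def validate(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if min(self.k_no3, self.k_no2, self.k_inh) <= 0:
            raise ValueError("half-saturation/inhibition constants must be positive")
        if not 0 < self.y_min <= self.y_max:
            raise ValueError("require 0 < y_min <= y_max")


@dataclass(frozen=True)
class GrowthResult:
    """Nominal (pre-clipping) outcome of one growth step at one node."""

    mu: float
    new_mass: float
    no3_consumed: float
    no2_consumed: float
    no2_produced: float


def growth_rate(
    role: StrainRole,
    c_no3: np.ndarray | float,
    c_no2: np.ndarray | float,
    params: KineticParams,
) -> np.ndarray | float:
    """Monod growth rate (s⁻¹) of a role at the given concentrations (mM).

    Complete reducers and producers saturate on nitrate, consumers on
    nitrite.  Result lies in ``[0, mu_max]`` and is monotone
    non-decreasing in the substrate concentration.
    """
    c_no3 = np.asarray(c_no3, dtype=float)
    c_no2 = np.asarray(c_no2, dtype=float)
    if np.any(c_no3 < 0) or np.any(c_no2 < 0):
        raise ValueError("concentrations must be non-negative")
    if role is StrainRole.CONSUMER:
        mu = params.mu_max * c_no2 / (c_no2 + params.k_no2)
    else:
        mu = params.mu_max * c_no3 / (c_no3 + params.k_no3)
    return mu if mu.ndim else float(mu)


def yield_coefficient(
    c_no2: np.ndarray | float, params: KineticParams
) -> np.ndarray | float:
    """Biomass yield (kgDW mol⁻¹) at the local nitrite concentration.

    Without toxicity the yield is constantly ``y_max``.  With toxicity it
    decreases monotonically from ``y_max`` (no nitrite) towards ``y_min``
    (saturating nitrite): ``(y_max - y_min) * k_inh / (k_inh + C) + y_min``.
    The same yield applies to both strains of the consortium.
    """
    c_no2 = np.asarray(c_no2, dtype=float)
    if not params.toxicity_on:
        out = np.full_like(c_no2, params.y_max)
        return out if out.ndim else float(out)
    y = (params.y_max - params.y_min) * params.k_inh / (params.k_inh + c_no2) + params.y_min
    return y if y.ndim else float(y)


def biomass_step(
    mass: np.ndarray | float, mu: np.ndarray | float, dt: float
) -> np.ndarray | float:
    """Explicit biomass update ``m * (1 + mu * dt)``."""
    return mass * (1.0 + np.asarray(mu) * dt) if np.ndim(mass) or np.ndim(mu) else mass * (1.0 + mu * dt)


def consumption(
    mass: np.ndarray | float,
    mu: np.ndarray | float,
    yield_coef: np.ndarray | float,
    dt: float,
) -> np.ndarray | float:
    """Moles of substrate consumed over ``dt``: ``mu * m * dt / Y``."""
    y = np.asarray(yield_coef, dtype=float)
    if np.any(y <= 0):
        raise ValueError("yield coefficient must be positive")
    out = np.asarray(mu) * np.asarray(mass) * dt / y
    return out if out.ndim else float(out)


def step_growth(
    role: StrainRole,
    mass: float,
    c_no3: float,
    c_no2: float,
    params: KineticParams,
    dt: float,
) -> GrowthResult:
    """Convenience: one nominal growth step for a single agent.

    Producers report nitrite production equal to their nitrate
    consumption (1:1 stoichiometry of the first denitrification step).
    The simulator applies the same arithmetic in vectorised form and clips
    consumption against locally available substrate.
    """
    params.validate()
    if mass <= 0:
        raise ValueError("mass must be positive")
    mu = float(growth_rate(role, c_no3, c_no2, params))
    y = float(yield_coefficient(c_no2, params))
    moles = float(consumption(mass, mu, y, dt))
    new_mass = float(biomass_step(mass, mu, dt))
    if role is StrainRole.CONSUMER:
        return GrowthResult(mu, new_mass, 0.0, moles, 0.0)
    produced = moles if role is StrainRole.PRODUCER else 0.0
    return GrowthResult(mu, new_mass, moles, 0.0, produced)
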