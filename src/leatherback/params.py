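"""Parameter containers for the leatherback bioenergetics model.

All containers are frozen dataclasses validated on construction. Units follow
the field conventions used throughout the package: mass in kg, length in cm
(straight carapace length), age in years, energy densities in kJ per gram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class GrowthParams:
    """von Bertalanffy growth (mass form) plus the length-mass allometry.

    Parameters
    ----------
    w_inf : float
        Asymptotic mass W_inf (kg) that adults approach.
    k : float
        VBGF growth parameter (yr^-1). A curvature constant, not a growth rate.
    t0 : float
        Theoretical age (yr) at which mass is zero. Anchored to a positive
        hatchling mass it is negative.
    b : float
        Exponent of the length-mass relationship W = a * L**b.
    a : float
        Multiplier of the length-mass relationship (kg * cm**-b).
    """

    w_inf: float = 319.0
    k: float = 0.299
    t0: float = 0.0
    b: float = 2.86
    a: float = 2.14e-4

    def __post_init__(self) -> None:
        if not self.w_inf > 0:
            raise ValueError(f"w_inf must be positive, got {self.w_inf}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not 2.0 < self.b < 4.0:
            raise ValueError(f"b must lie in (2, 4), got {self.b}")
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")

    @property
    def asymptotic_length(self) -> float:
        """SCL (cm) at which the length-mass curve reaches w_inf."""
        return (self.w_inf / self.a) ** (1.0 / self.b)

    def with_t0(self, t0: float) -> "GrowthParams":
        return replace(self, t0=t0)


@dataclass(frozen=True)
class ConversionParams:
    """Food-conversion allometry and diet energetics.

    beta is the single constant of the gross conversion-efficiency allometry
    K1 = 1 - (W / W_inf)**beta. The captive gelatin diet carries ~2.016 kJ/g
    wet mass versus ~0.2 kJ/g for wild gelatinous prey, hence a tenfold
    wet-mass factor when expressing intake as jellyfish equivalents.
    """

    beta: float = 0.0328
    diet_energy_wm: float = 2.016  # kJ per g wet mass of the gelatin diet
    jelly_energy_wm: float = 0.2   # kJ per g wet mass of jellyfish
    jelly_factor: float = 10.0     # gelatin->jellyfish wet-mass multiplier

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must lie in (0, 1), got {self.beta}")
        for name in ("diet_energy_wm", "jelly_energy_wm", "jelly_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        implied = self.diet_energy_wm / self.jelly_energy_wm
        if abs(implied - self.jelly_factor) / self.jelly_factor > 0.01:
            raise ValueError(
                "jelly_factor must equal diet_energy_wm / jelly_energy_wm "
                f"within 1% (got {self.jelly_factor} vs implied {implied:.3f})"
            )

    @property
    def jelly_energy_per_tonne(self) -> float:
        """Energy content of jellyfish in MJ per metric tonne wet mass."""
        # kJ/g * 1e6 g/t / 1e3 kJ/MJ
        return self.jelly_energy_wm * 1000.0


@dataclass(frozen=True)
class MetabolicParams:
    """Usable-energy fractions for the metabolic-rate derivation.

    ``total_available`` is the combined digestible-and-assimilable fraction of
    ingested energy; the default 0.63 is the rounded product of 80% digestive
    and 80% assimilation efficiency and is used as given rather than recomputed
    (0.8 * 0.8 = 0.64; both are exposed so either convention can be selected).
    """

    digestive_efficiency: float = 0.8
    assimilation_efficiency: float = 0.8
    total_available: float = 0.63

    def __post_init__(self) -> None:
        for name in ("digestive_efficiency", "assimilation_efficiency",
                     "total_available"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


#: Seconds in a Julian year; fixes the kJ/yr -> W conversion used everywhere.
SECONDS_PER_YEAR = 31_557_600.0

#: Default hatchling mass (kg) used to anchor t0.
HATCHLING_MASS_KG = 0.046


def default_growth_params(
    w_inf: float = 319.0,
    k: float = 0.299,
    b: float = 2.86,
    a: float = 2.14e-4,
    hatchling_mass: float = HATCHLING_MASS_KG,
) -> GrowthParams:
    """Central growth parameters with t0 anchored to the hatchling mass.

    The anchoring solves W(0) = hatchling_mass in closed form:
    t0 = ln(1 - (W_hatch / W_inf)**(1/b)) / k.
    """
    if not 0 < hatchling_mass < w_inf:
        raise ValueError("hatchling mass must lie in (0, w_inf)")
    t0 = math.log(1.0 - (hatchling_mass / w_inf) ** (1.0 / b)) / k
    return GrowthParams(w_inf=w_inf, k=k, t0=t0, b=b, a=a)
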