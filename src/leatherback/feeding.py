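"""Food conversion, individual consumption, and metabolic-rate derivation.

Gross food-conversion efficiency follows the Pauly allometry

    K1(W) = 1 - (W / W_inf)**beta,

which has the required property that K1 -> 0 as W -> W_inf. Individual intake
at age t is growth rate divided by conversion efficiency,

    F(t) = (dW/dt) / K1(W(t)),

in units of the experimental gelatin diet; multiplying wet mass by the factor
10 expresses it as the energy-equivalent wet mass of jellyfish. The 0/0 limit
at W = W_inf resolves analytically to k * W_inf / beta (diet units), the
maintenance ration of a non-growing adult.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .growth import growth_rate, mass_at_age
from .params import ConversionParams, GrowthParams, MetabolicParams, SECONDS_PER_YEAR

FEEDING_RECORD_COLUMNS = [
    "animal_id", "age_start_yr", "age_end_yr",
    "mass_start_kg", "mass_end_kg", "food_wet_kg",
]
ASSAY_COLUMNS = ["sample_id", "dry_fraction", "energy_kj_per_g_dm"]

#: Below this conversion efficiency the analytic adult limit replaces the
#: 0/0-prone ratio; at K1 = 1e-12 the two agree to ~1e-12 relative.
_K1_FLOOR = 1e-12

__all__ = [
    "k1_at_mass",
    "fit_beta",
    "BetaFit",
    "consumption_rate",
    "cumulative_consumption",
    "metabolic_rate",
    "body_energy",
    "consumption_from_energy_budget",
    "assay_summary",
    "AssaySummary",
    "validate_feeding_records",
]


def k1_at_mass(W, gp: GrowthParams, cp: ConversionParams):
    """Gross food-conversion efficiency K1 = 1 - (W / W_inf)**beta."""
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("mass must be positive")
    if np.any(W > gp.w_inf * (1 + 1e-12)):
        raise ValueError("mass must not exceed w_inf")
    out = 1.0 - (np.minimum(W, gp.w_inf) / gp.w_inf) ** cp.beta
    return float(out) if out.ndim == 0 else out


def validate_feeding_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEEDING_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"feeding records missing columns {missing}")
    if (records["age_end_yr"] <= records["age_start_yr"]).any():
        raise ValueError("interval end must exceed start")
    if (records[["mass_start_kg", "mass_end_kg"]] <= 0).any().any():
        raise ValueError("masses must be positive")
    if (records["food_wet_kg"] < 0).any():
        raise ValueError("food consumed must be non-negative")
    return records


@dataclass(frozen=True)
class BetaFit:
    """Through-origin log-log regression of conversion efficiency on mass."""

    beta: float
    se: float
    n_used: int
    n_excluded: int
    rss: float
    noise_var: float  # estimated variance of the multiplicative food noise
    residuals: np.ndarray = field(repr=False)


def fit_beta(records: pd.DataFrame, gp: GrowthParams) -> BetaFit:
    """Estimate beta from feeding records.

    Per record the observed conversion efficiency is
    K1 = (mass_end - mass_start) / food, assigned to the interval's mean mass
    (W_i + W_j) / 2, and log(1 - K1) is regressed on log(W / W_inf) through
    the origin; the slope is beta. Records with zero food or K1 >= 1 are
    excluded with a warning.

    Multiplicative noise on weighed food enters log(1 - K1) nonlinearly and
    shifts its expectation by -sigma^2/2 * K1 / (1 - K1)^2 to second order
    (sigma the SD of log food error). The fit therefore iterates a
    retransformation correction, adding that term back with sigma^2 estimated
    from the scaled residuals; with no noise the correction vanishes and the
    regression is exact. The reported SE is heteroscedasticity-robust, since
    the residual scale grows as K1 / (1 - K1) toward small masses.
    """
    validate_feeding_records(records)
    if len(records) < 10:
        raise ValueError("need at least 10 feeding records")

    dW = records["mass_end_kg"].to_numpy() - records["mass_start_kg"].to_numpy()
    food = records["food_wet_kg"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = np.where(food > 0, dW / food, np.nan)
    bad = ~np.isfinite(k1) | (k1 >= 1.0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} feeding record(s) with zero food or "
            "K1 >= 1", stacklevel=2)
    k1 = k1[~bad]
    w_mid = 0.5 * (records["mass_start_kg"].to_numpy()
                   + records["mass_end_kg"].to_numpy())[~bad]

    x = np.log(w_mid / gp.w_inf)
    y = np.log(1.0 - k1)
    sxx = float(x @ x)
    beta = float(x @ y) / sxx
    sig2 = 0.0
    y_corr = y
    for _ in range(3):
        k1_fit = 1.0 - np.exp(beta * x)  # model K1 at each record's mass
        gain = np.maximum(k1_fit / (1.0 - k1_fit), 1e-8)
        resid = y - beta * x
        sig2 = float(np.mean((resid / gain) ** 2))
        y_corr = y + 0.5 * sig2 * k1_fit / (1.0 - k1_fit) ** 2
        beta = float(x @ y_corr) / sxx
    resid = y_corr - beta * x
    rss = float(resid @ resid)
    se = float(np.sqrt(np.sum(x * x * resid * resid)) / sxx)
    return BetaFit(beta=beta, se=se, n_used=len(x), n_excluded=int(bad.sum()),
                   rss=rss, noise_var=sig2, residuals=resid)


def consumption_rate(t, gp: GrowthParams, cp: ConversionParams,
                     units: str = "jellyfish"):
    """Individual food intake (kg wet mass yr^-1) at age ``t``.

    ``units="diet"`` returns intake of the gelatin experimental diet;
    ``units="jellyfish"`` (default) multiplies by the wet-mass factor 10.
    Finite and positive at every age: the indeterminate ratio at W = W_inf is
    replaced by its analytic limit k * W_inf / beta.
    """
    if units not in ("diet", "jellyfish"):
        raise ValueError(f"units must be 'diet' or 'jellyfish', got {units!r}")
    scalar = np.isscalar(t)
    W = np.atleast_1d(mass_at_age(t, gp))
    dW = np.atleast_1d(growth_rate(t, gp))
    k1 = np.atleast_1d(k1_at_mass(W, gp, cp))
    limit = gp.k * gp.w_inf / cp.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(k1 > _K1_FLOOR, dW / np.maximum(k1, _K1_FLOOR), limit)
    if units == "jellyfish":
        out = out * cp.jelly_factor
    return float(out[0]) if scalar else out


def cumulative_consumption(t1: float, t2: float, gp: GrowthParams,
                           cp: ConversionParams) -> float:
    """Total jellyfish intake (metric tonnes) over ages [t1, t2] by quadrature."""
    if not 0 <= t1 <= t2:
        raise ValueError("need 0 <= t1 <= t2")
    if t1 == t2:
        return 0.0
    total, _ = quad(lambda u: consumption_rate(u, gp, cp, units="jellyfish"),
                    t1, t2, epsrel=1e-9, limit=200)
    return total / 1000.0


def metabolic_rate(t, gp: GrowthParams, cp: ConversionParams,
                   mp: MetabolicParams | None = None):
    """Mass-specific metabolic rate (W kg^-1) implied by food consumption.

    The energy flux available for metabolism is intake (diet units) times the
    diet's wet-mass energy density, the usable-energy fraction, and the share
    (1 - K1) not allocated to growth; dividing by body mass and converting
    kJ yr^-1 to watts gives the mass-specific rate.
    """
    mp = mp or MetabolicParams()
    scalar = np.isscalar(t)
    W = np.atleast_1d(mass_at_age(t, gp))
    f_diet = np.atleast_1d(consumption_rate(t, gp, cp, units="diet"))
    k1 = np.atleast_1d(k1_at_mass(W, gp, cp))
    kj_per_yr = f_diet * (cp.diet_energy_wm * 1000.0) * mp.total_available * (1.0 - k1)
    watts_per_kg = kj_per_yr * 1000.0 / SECONDS_PER_YEAR / W
    return float(watts_per_kg[0]) if scalar else watts_per_kg


def body_energy(mass_kg: float, water_fraction: float,
                tissue_energy_dm: float) -> float:
    """Whole-body energy content (MJ).

    mass (kg) x dry fraction x tissue energy (kJ/g dry mass); the unit product
    kg * kJ/g is numerically MJ.
    """
    if not 0.0 < water_fraction < 1.0:
        raise ValueError("water fraction must lie in (0, 1)")
    if mass_kg <= 0 or tissue_energy_dm <= 0:
        raise ValueError("mass and tissue energy must be positive")
    return mass_kg * (1.0 - water_fraction) * tissue_energy_dm


def consumption_from_energy_budget(body_energy_mj: float, mean_beta: float,
                                   jelly_energy_wm: float = 0.2) -> float:
    """Jellyfish tonnage implied by the whole-body energy budget.

    Dividing body energy by the mean gross conversion constant and the energy
    per tonne of jellyfish (0.2 kJ/g wet mass = 200 MJ/t) cross-checks the
    integrated consumption to maturity.
    """
    if body_energy_mj <= 0 or jelly_energy_wm <= 0:
        raise ValueError("inputs must be positive")
    if mean_beta <= 0:
        raise ValueError("mean_beta must be positive")
    mj_per_tonne = jelly_energy_wm * 1000.0
    return body_energy_mj / (mean_beta * mj_per_tonne)


@dataclass(frozen=True)
class AssaySummary:
    n: int
    mean_dry_fraction: float
    mean_energy: float
    sd_energy: float  # nan when a single assay leaves the SD undefined


def assay_summary(assays: pd.DataFrame) -> AssaySummary:
    """Arithmetic mean dry fraction and mean +/- SD energy density."""
    missing = [c for c in ASSAY_COLUMNS if c not in assays.columns]
    if missing:
        raise ValueError(f"assay table missing columns {missing}")
    if len(assays) == 0:
        raise ValueError("need at least one assay")
    energy = assays["energy_kj_per_g_dm"].to_numpy(dtype=float)
    sd = float(np.std(energy, ddof=1)) if len(energy) > 1 else float("nan")
    if len(energy) == 1:
        warnings.warn("single assay: SD undefined", stacklevel=2)
    return AssaySummary(
        n=len(assays),
        mean_dry_fraction=float(assays["dry_fraction"].mean()),
        mean_energy=float(energy.mean()),
        sd_energy=sd,
    )
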