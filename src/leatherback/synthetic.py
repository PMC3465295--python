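"""Synthetic captive-cohort data for parameter-recovery testing.

Emulates the feeding experiment the analysis assumes: a cohort of hatchlings
raised on a gelatin diet, weighed weekly, with all food weighed before (and
residue after) each feeding, plus bomb-calorimetry assays of diet samples.

Each animal grows along a VBGF with its own growth constant k_i (lognormal
individual variation around the shared k, the simplest identifiable
structure; b and W_inf are shared). Weekly interval food is the true mass
gain divided by the conversion efficiency at the true interval mean mass,
perturbed by multiplicative lognormal observation noise. The weighed mass
series carries its own multiplicative observation noise, while feeding
records keep the internally consistent pre-noise masses (interval end mass
equals the next interval's start mass).

What this generator does not emulate: satiation dynamics, temperature
effects, tank conditions, or any covariance between food and mass errors —
recovery tests therefore certify the fitters under iid measurement noise,
not under every failure mode of real husbandry data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feeding import k1_at_mass
from .growth import mass_at_age
from .params import ConversionParams, GrowthParams, default_growth_params

__all__ = [
    "CohortSimSpec",
    "simulate_cohort",
    "simulate_energy_assays",
    "make_fixture_set",
]


@dataclass(frozen=True)
class CohortSimSpec:
    """Configuration of the simulated feeding experiment.

    Defaults follow the captive study: 20 hatchlings measured weekly for two
    years, 2% multiplicative observation noise on mass, 5% on food, and 5%
    lognormal individual variation on k.
    """

    n_animals: int = 20
    duration_yr: float = 2.0
    cadence_yr: float = 1.0 / 52.0
    growth: GrowthParams = field(default_factory=default_growth_params)
    conversion: ConversionParams = field(default_factory=ConversionParams)
    k_individual_sd: float = 0.05   # lognormal SD of k_i around the shared k
    mass_obs_sd: float = 0.02       # multiplicative SD on weighed masses
    food_obs_sd: float = 0.05       # multiplicative SD on weighed food
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need at least one animal")
        if self.duration_yr <= 0 or self.cadence_yr <= 0:
            raise ValueError("duration and cadence must be positive")
        for name in ("k_individual_sd", "mass_obs_sd", "food_obs_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate weekly masses and interval feeding records for a cohort.

    Returns
    -------
    (mass_series, feeding_records) : DataFrames in the schemas used by
    :func:`leatherback.growth.fit_growth` and
    :func:`leatherback.feeding.fit_beta`.
    """
    rng = np.random.default_rng(spec.seed)
    gp, cp = spec.growth, spec.conversion
    times = np.arange(0.0, spec.duration_yr + spec.cadence_yr / 2, spec.cadence_yr)

    mass_rows = []
    feed_rows = []
    for i in range(spec.n_animals):
        animal = f"LB{i:02d}"
        if spec.k_individual_sd > 0:
            k_i = gp.k * rng.lognormal(0.0, spec.k_individual_sd)
        else:
            k_i = gp.k
        gp_i = GrowthParams(w_inf=gp.w_inf, k=k_i, t0=gp.t0 * gp.k / k_i,
                            b=gp.b, a=gp.a)
        true_mass = mass_at_age(times, gp_i)
        if np.any(true_mass <= 0):
            raise ValueError("simulation produced non-positive masses")
        obs_mass = true_mass * rng.lognormal(0.0, spec.mass_obs_sd, len(times)) \
            if spec.mass_obs_sd > 0 else true_mass.copy()

        mass_rows.append(pd.DataFrame({
            "animal_id": animal, "age_yr": times, "mass_kg": obs_mass}))

        w_i, w_j = true_mass[:-1], true_mass[1:]
        k1_true = k1_at_mass(0.5 * (w_i + w_j), gp, cp)
        food = (w_j - w_i) / k1_true
        if spec.food_obs_sd > 0:
            food = food * rng.lognormal(0.0, spec.food_obs_sd, len(food))
        feed_rows.append(pd.DataFrame({
            "animal_id": animal,
            "age_start_yr": times[:-1], "age_end_yr": times[1:],
            "mass_start_kg": w_i, "mass_end_kg": w_j,
            "food_wet_kg": food}))

    return (pd.concat(mass_rows, ignore_index=True),
            pd.concat(feed_rows, ignore_index=True))


def simulate_energy_assays(n: int, dry_fraction: float = 0.10,
                           energy_kj_per_g_dm: float = 20.16,
                           energy_sd: float = 0.58,
                           dry_fraction_sd: float = 0.01,
                           seed: int = 0) -> pd.DataFrame:
    """Simulated bomb-calorimetry assays of the gelatin diet.

    Normal draws around the true dry fraction and energy density, redrawn
    while non-positive (the energy SD 0.58 kJ/g makes negatives practically
    impossible but the truncation is enforced).
    """
    if n < 1:
        raise ValueError("need at least one assay")
    rng = np.random.default_rng(seed)

    def trunc_normal(mean, sd, size):
        out = rng.normal(mean, sd, size) if sd > 0 else np.full(size, mean)
        while np.any(out <= 0):
            bad = out <= 0
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
        return out

    return pd.DataFrame({
        "sample_id": [f"A{i:04d}" for i in range(n)],
        "dry_fraction": np.clip(trunc_normal(dry_fraction, dry_fraction_sd, n),
                                None, 0.999),
        "energy_kj_per_g_dm": trunc_normal(energy_kj_per_g_dm, energy_sd, n),
    })


def make_fixture_set(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write the default fixture files: nesting config, cohort CSVs, assays.

    Deterministic for a fixed seed (byte-identical files on repeated calls).
    Returns the paths written, keyed by fixture name.
    """
    from .io import write_nesting_config
    from .demography import pacific_nesting_params

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mass, feeding = simulate_cohort(CohortSimSpec(seed=seed))
    assays = simulate_energy_assays(30, seed=seed)

    paths = {
        "nesting": out / "nesting.toml",
        "mass_series": out / "cohort_mass.csv",
        "feeding_records": out / "cohort_feeding.csv",
        "assays": out / "diet_assays.csv",
    }
    write_nesting_config(pacific_nesting_params(), paths["nesting"])
    fmt = "%.10g"
    mass.to_csv(paths["mass_series"], index=False, float_format=fmt)
    feeding.to_csv(paths["feeding_records"], index=False, float_format=fmt)
    assays.to_csv(paths["assays"], index=False, float_format=fmt)
    return paths
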