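"""Stage-structured demography of the Pacific leatherback population.

Hatchling production is the product of seven nesting-ecology factors per
rookery (nesters/yr x nests/female x eggs/nest x hatching success x emergence
x first-day beach survival x first-day water survival), summed over the
eastern (EP) and western (WP) Pacific. Within each life stage cohort abundance
decays exponentially,

    N(t) = R * exp(-Z * (t - t_R)),

with R recruits entering at age t_R and instantaneous mortality Z (yr^-1);
ln 2 / Z is the half-life, S = exp(-Z) the annual survival and A = 1 - S the
annual mortality. Population totals use discrete annual age classes (the one
convention that reproduces the printed 294,088 / 6,199 family of counts):
the annual hatchling pulse, plus juvenile cohorts at integer ages 1-15, plus
adult cohorts at integer ages 16 onward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NestingRow",
    "NestingParams",
    "Stage",
    "StageSchedule",
    "hatchling_production",
    "recruits_to_adults",
    "mortality_coefficient",
    "abundance_at_age",
    "stage_summary",
    "total_population",
    "TotalPopulation",
    "pacific_nesting_params",
    "pacific_schedule",
    "PACIFIC_STAGE_COUNTS",
    "PACIFIC_Z",
]

LEVELS = ("low", "mean", "high")


@dataclass(frozen=True)
class NestingRow:
    """One rookery's nesting-ecology factors at one level (low/mean/high)."""

    nesters_per_yr: float
    nests_per_female: float
    eggs_per_nest: float
    hatching_success: float
    emergence_rate: float
    beach_survival: float
    water_survival: float

    def __post_init__(self) -> None:
        for name in ("hatching_success", "emergence_rate",
                     "beach_survival", "water_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("nesters_per_yr", "nests_per_female", "eggs_per_nest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def product(self) -> float:
        return (self.nesters_per_yr * self.nests_per_female
                * self.eggs_per_nest * self.hatching_success
                * self.emergence_rate * self.beach_survival
                * self.water_survival)


@dataclass(frozen=True)
class NestingParams:
    """Nesting-ecology rows per population and level.

    ``rows`` maps population code (e.g. "EP", "WP") to a dict with keys
    "low", "mean", "high". Low <= mean <= high is enforced factor-wise.
    """

    rows: dict[str, dict[str, NestingRow]]

    def __post_init__(self) -> None:
        for pop, levels in self.rows.items():
            missing = [lv for lv in LEVELS if lv not in levels]
            if missing:
                raise ValueError(f"population {pop!r} missing levels {missing}")
            lo, me, hi = (levels[lv] for lv in LEVELS)
            for fld in NestingRow.__dataclass_fields__:
                a, b, c = (getattr(r, fld) for r in (lo, me, hi))
                if not a <= b <= c:
                    raise ValueError(
                        f"{pop}.{fld}: low <= mean <= high violated ({a}, {b}, {c})")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def total_nesters(self) -> float:
        return sum(levels["mean"].nesters_per_yr for levels in self.rows.values())


def pacific_nesting_params() -> NestingParams:
    """Published nesting-ecology table for the eastern and western Pacific."""
    shared = dict(
        nests_per_female=(4.3, 6.1, 7.9),
        hatching_success=(0.39, 0.47, 0.55),
        emergence_rate=(0.51, 0.76, 1.0),
        beach_survival=(0.78, 0.83, 0.87),
        water_survival=(0.64, 0.69, 0.74),
    )
    spec = {
        "EP": dict(nesters_per_yr=(248, 248, 248),
                   eggs_per_nest=(61.3, 64.1, 66.9), **shared),
        "WP": dict(nesters_per_yr=(1113, 1113, 1113),
                   eggs_per_nest=(73.2, 77.9, 82.6), **shared),
    }
    rows = {
        pop: {lv: NestingRow(**{f: v[i] for f, v in fields.items()})
              for i, lv in enumerate(LEVELS)}
        for pop, fields in spec.items()
    }
    return NestingParams(rows=rows)


def hatchling_production(np_: NestingParams, level: str = "mean",
                         by_population: bool = False):
    """Hatchlings entering the ocean per year: seven-factor product per
    rookery, summed over rookeries. Rounding happens only at reporting."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    per_pop = {pop: levels[level].product() for pop, levels in np_.rows.items()}
    return per_pop if by_population else sum(per_pop.values())


def recruits_to_adults(np_: NestingParams,
                       first_timer_fraction: float = 0.5,
                       sex_multiplier: dict[str, float] | None = None,
                       level: str = "mean") -> float:
    """Annual recruits to the adult population.

    nesters x fraction of first-time nesters x a per-population multiplier
    converting first-time nesting females to total new adults (1.25 for the
    EP's 4:1 female:male ratio, 2 for the WP's 1:1), summed over rookeries.
    """
    if not 0.0 < first_timer_fraction <= 1.0:
        raise ValueError("first_timer_fraction must lie in (0, 1]")
    sex_multiplier = sex_multiplier or {"EP": 1.25, "WP": 2.0}
    total = 0.0
    for pop, levels in np_.rows.items():
        mult = sex_multiplier.get(pop, 1.0)
        if mult < 1.0:
            raise ValueError(f"sex multiplier for {pop!r} must be >= 1")
        total += levels[level].nesters_per_yr * first_timer_fraction * mult
    return total


def mortality_coefficient(n_start: float, n_end: float, duration: float,
                          allow_negative: bool = False) -> float:
    """Instantaneous mortality Z = -ln(N_end / N_start) / duration (yr^-1)."""
    if n_end <= 0 or n_start <= 0:
        raise ValueError("counts must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_end > n_start and not allow_negative:
        raise ValueError("N_end > N_start implies negative Z; "
                         "pass allow_negative=True to permit it")
    return -math.log(n_end / n_start) / duration


@dataclass(frozen=True)
class Stage:
    """One life stage: recruits R entering at t_R, decaying at rate Z until t_end."""

    name: str
    t_recruit: float
    recruits: float
    z: float
    t_end: float

    def __post_init__(self) -> None:
        if self.recruits <= 0:
            raise ValueError("recruits must be positive")
        if self.z < 0:
            raise ValueError("Z must be non-negative")
        if self.t_end <= self.t_recruit:
            raise ValueError("stage end must exceed recruitment age")

    def abundance(self, t):
        return self.recruits * np.exp(-self.z * (np.asarray(t, float) - self.t_recruit))


@dataclass(frozen=True)
class StageSchedule:
    """Ordered life stages with strictly increasing recruitment ages."""

    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        ts = [s.t_recruit for s in self.stages]
        if not all(a < b for a, b in zip(ts, ts[1:])):
            raise ValueError("recruitment ages must be strictly increasing")
        for a, b in zip(self.stages, self.stages[1:]):
            if not math.isclose(a.t_end, b.t_recruit, rel_tol=1e-9):
                raise ValueError(
                    f"stage {a.name!r} ends at {a.t_end}, next starts at {b.t_recruit}")

    @property
    def t_start(self) -> float:
        return self.stages[0].t_recruit

    @property
    def t_end(self) -> float:
        return self.stages[-1].t_end

    def stage_at(self, t: float) -> Stage:
        if t < self.t_start:
            raise ValueError(f"age {t} precedes first recruitment ({self.t_start})")
        for s in self.stages:
            if t < s.t_end:
                return s
        return self.stages[-1]


def abundance_at_age(t, sched: StageSchedule):
    """N(t): piecewise-exponential cohort abundance across stages."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < sched.t_start):
        raise ValueError("age precedes first recruitment")
    out = np.empty_like(t_arr, dtype=float)
    remaining = np.ones_like(t_arr, dtype=bool)
    for s in sched.stages:
        mask = remaining & (t_arr < s.t_end)
        out[mask] = s.abundance(t_arr[mask])
        remaining &= ~mask
    if remaining.any():  # beyond the last stage boundary: extend the last stage
        out[remaining] = sched.stages[-1].abundance(t_arr[remaining])
    return float(out) if np.isscalar(t) else out


def stage_summary(sched: StageSchedule) -> pd.DataFrame:
    """Per-stage annual survival S = e^-Z, mortality A = 1 - S, half-life ln2/Z."""
    rows = []
    for s in sched.stages:
        surv = math.exp(-s.z)
        half = math.inf if s.z == 0 else math.log(2) / s.z
        rows.append({"stage": s.name, "t_recruit": s.t_recruit,
                     "recruits": s.recruits, "z": s.z,
                     "annual_survival": surv, "annual_mortality": 1.0 - surv,
                     "half_life_yr": half})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TotalPopulation:
    by_stage: dict[str, float]
    total: float
    nesting_fraction: float | None  # annual nesters / total, when nesters given


def total_population(sched: StageSchedule,
                     annual_nesters: float | None = None) -> TotalPopulation:
    """Population size by discrete annual age classes.

    The first stage contributes its annual recruit pulse once; each later
    stage contributes the sum of cohort sizes at integer ages within
    [t_recruit, t_end).
    """
    by_stage: dict[str, float] = {}
    first = sched.stages[0]
    by_stage[first.name] = first.recruits
    for s in sched.stages[1:]:
        ages = np.arange(math.ceil(s.t_recruit), math.ceil(s.t_end))
        by_stage[s.name] = float(s.abundance(ages).sum())
    total = sum(by_stage.values())
    frac = annual_nesters / total if annual_nesters is not None else None
    return TotalPopulation(by_stage=by_stage, total=total, nesting_fraction=frac)


#: Printed stage counts per scenario level: hatchlings, yearlings, adult recruits.
PACIFIC_STAGE_COUNTS = {
    "low": (41_275.0, 10_425.0, 1_217.0),
    "mean": (128_031.0, 32_338.0, 1_268.0),
    "high": (303_578.0, 76_679.0, 1_318.0),
}

#: Printed instantaneous mortality coefficients (hatchling, juvenile, adult).
PACIFIC_Z = {
    "low": (1.38, 0.143, 0.333),
    "mean": (1.38, 0.216, 0.229),
    "high": (1.38, 0.271, 0.177),
}

#: Hatchling recruitment is at ~1 day; maturity at 16 yr; 31 adult years.
T_HATCH = 0.0027
T_MATURITY = 16.0
ADULT_SPAN = 31.0


def pacific_schedule(level: str = "mean", coefficients: str = "printed",
                     maturity: float = T_MATURITY,
                     adult_span: float = ADULT_SPAN) -> StageSchedule:
    """Stage schedule for the Pacific population at one scenario level.

    ``coefficients="printed"`` uses the published rounded stage counts and
    mortality coefficients (the reproduction setting). ``"derived"``
    recomputes: yearlings as 25% of hatchlings, Z from the boundary
    conditions via :func:`mortality_coefficient` (the continuity setting);
    the low/high adult coefficients have no stated derivation and keep their
    printed values either way.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if coefficients not in ("printed", "derived"):
        raise ValueError("coefficients must be 'printed' or 'derived'")

    hatchlings, yearlings, recruits = PACIFIC_STAGE_COUNTS[level]
    z_h, z_j, z_a = PACIFIC_Z[level]
    if coefficients == "derived":
        yearlings = 0.25 * hatchlings
        z_h = mortality_coefficient(hatchlings, yearlings, 1.0 - T_HATCH)
        z_j = mortality_coefficient(yearlings, recruits, maturity - 1.0)
        if level == "mean":
            z_a = mortality_coefficient(recruits, 1.0, adult_span)
        else:
            warnings.warn(
                f"{level} adult mortality has no stated derivation; "
                "keeping the printed value", stacklevel=2)

    return StageSchedule(stages=(
        Stage("hatchling", T_HATCH, hatchlings, z_h, 1.0),
        Stage("juvenile", 1.0, yearlings, z_j, maturity),
        Stage("adult", maturity, recruits, z_a, maturity + adult_span),
    ))
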