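"""Individual growth: von Bertalanffy mass curve, derivative, length-mass
interconversion, t0 anchoring, and nonlinear least-squares fitting.

The mass-form VBGF used throughout is

    W(t) = W_inf * (1 - exp(-k * (t - t0)))**b

with the growth rate given by its analytic derivative

    dW/dt = W_inf * b * k * s**(b-1) * (1 - s),   s = 1 - exp(-k * (t - t0)).

Mass-at-age data live in plain pandas DataFrames with columns
``animal_id, age_yr, mass_kg`` (see :func:`validate_mass_series`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import GrowthParams, default_growth_params

MASS_SERIES_COLUMNS = ["animal_id", "age_yr", "mass_kg"]

__all__ = [
    "mass_at_age",
    "growth_rate",
    "mass_from_length",
    "length_from_mass",
    "solve_t0",
    "fit_growth",
    "GrowthFit",
    "validate_mass_series",
]


def _saturation(t, p: GrowthParams):
    t = np.asarray(t, dtype=float)
    if np.any(t < p.t0):
        raise ValueError(f"age must be >= t0 ({p.t0:.4f} yr)")
    return 1.0 - np.exp(-p.k * (t - p.t0))


def mass_at_age(t, p: GrowthParams):
    """Predicted mass (kg) at age ``t`` (yr). Accepts scalars or arrays."""
    s = _saturation(t, p)
    out = p.w_inf * s**p.b
    return float(out) if np.isscalar(t) else out


def growth_rate(t, p: GrowthParams):
    """Analytic dW/dt (kg yr^-1); declines to zero as mass approaches W_inf."""
    s = _saturation(t, p)
    out = p.w_inf * p.b * p.k * s ** (p.b - 1.0) * (1.0 - s)
    return float(out) if np.isscalar(t) else out


def mass_from_length(L, p: GrowthParams):
    """Mass (kg) from straight carapace length (cm): W = a * L**b."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    out = p.a * L**p.b
    return float(out) if out.ndim == 0 else out


def length_from_mass(W, p: GrowthParams):
    """SCL (cm) from mass (kg): L = (W / a)**(1/b)."""
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("mass must be positive")
    out = (W / p.a) ** (1.0 / p.b)
    return float(out) if out.ndim == 0 else out


def solve_t0(hatchling_mass: float, p: GrowthParams) -> float:
    """t0 (yr) such that mass_at_age(0) equals ``hatchling_mass`` exactly.

    Closed form: t0 = ln(1 - (W_hatch / W_inf)**(1/b)) / k; negative for any
    positive hatchling mass, approaching 0 as the hatchling mass does.
    """
    if not 0.0 < hatchling_mass < p.w_inf:
        raise ValueError("hatchling mass must lie in (0, w_inf)")
    return math.log(1.0 - (hatchling_mass / p.w_inf) ** (1.0 / p.b)) / p.k


def validate_mass_series(data: pd.DataFrame) -> pd.DataFrame:
    """Check the mass-at-age schema and per-animal ordering; return the frame.

    Requires columns ``animal_id, age_yr, mass_kg``; non-negative ages,
    positive masses, and strictly increasing ages within each animal.
    """
    missing = [c for c in MASS_SERIES_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"mass series missing columns {missing}")
    if (data["age_yr"] < 0).any():
        raise ValueError("ages must be non-negative")
    if (data["mass_kg"] <= 0).any():
        raise ValueError("masses must be positive")
    for animal, grp in data.groupby("animal_id"):
        if not grp["age_yr"].is_monotonic_increasing or grp["age_yr"].duplicated().any():
            raise ValueError(f"ages for animal {animal!r} must be strictly increasing")
    return data


@dataclass(frozen=True)
class GrowthFit:
    """Result of a VBGF fit: point estimates, standard errors, diagnostics."""

    params: GrowthParams
    se: dict[str, float]
    free: tuple[str, ...]
    n_obs: int
    rss: float
    residuals: np.ndarray = field(repr=False)
    log_mass: bool = False


def fit_growth(
    data: pd.DataFrame,
    fixed: dict[str, float] | None = None,
    log_mass: bool = False,
    p0: GrowthParams | None = None,
) -> GrowthFit:
    """Fit the mass-form VBGF to mass-at-age data by nonlinear least squares.

    Parameters
    ----------
    data : DataFrame
        Columns ``animal_id, age_yr, mass_kg``.
    fixed : dict, optional
        Any of ``b`` and/or ``w_inf`` to hold fixed; ``k`` and ``t0`` are
        always estimated. By default both ``b`` and ``w_inf`` are fixed at
        their central values (the identifiable setting for a juvenile-only
        cohort far from the asymptote).
    log_mass : bool
        Fit on log-mass (appropriate for multiplicative observation noise).

    Returns
    -------
    GrowthFit with standard errors from the local curvature of the
    least-squares surface.
    """
    validate_mass_series(data)
    if data["age_yr"].nunique() < 6:
        raise ValueError("need at least 6 distinct ages to fit the VBGF")

    base = p0 or default_growth_params()
    if fixed is None:
        fixed = {"b": base.b, "w_inf": base.w_inf}
    free = ["k", "t0"] + [name for name in ("b", "w_inf") if name not in fixed]

    t = data["age_yr"].to_numpy(dtype=float)
    y = data["mass_kg"].to_numpy(dtype=float)
    if log_mass:
        y = np.log(y)

    defaults = {"k": base.k, "t0": base.t0, "b": base.b, "w_inf": base.w_inf}
    defaults.update(fixed)

    def model(tt, *theta):
        vals = dict(defaults)
        vals.update(zip(free, theta))
        gp = GrowthParams(w_inf=vals["w_inf"], k=vals["k"], t0=vals["t0"],
                          b=vals["b"], a=base.a)
        w = mass_at_age(tt, gp)
        return np.log(w) if log_mass else w

    start = [defaults[name] for name in free]
    # keep k, w_inf positive and b inside its admissible band during search
    lower = [1e-6 if name in ("k", "w_inf") else (2.0 + 1e-9 if name == "b" else -np.inf)
             for name in free]
    upper = [4.0 - 1e-9 if name == "b" else np.inf for name in free]
    popt, pcov = curve_fit(model, t, y, p0=start, bounds=(lower, upper),
                           maxfev=20000)

    vals = dict(defaults)
    vals.update(zip(free, popt))
    fitted = GrowthParams(w_inf=vals["w_inf"], k=vals["k"], t0=vals["t0"],
                          b=vals["b"], a=base.a)
    resid = y - model(t, *popt)
    se = {name: float(np.sqrt(pcov[i, i])) for i, name in enumerate(free)}
    return GrowthFit(params=fitted, se=se, free=tuple(free), n_obs=len(t),
                     rss=float(resid @ resid), residuals=resid,
                     log_mass=log_mass)
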