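"""File formats: CSV schemas for measurement tables and grids, TOML configs
for parameter sets.

CSV schemas
-----------
- mass series:      ``animal_id,age_yr,mass_kg``
- feeding records:  ``animal_id,age_start_yr,age_end_yr,mass_start_kg,mass_end_kg,food_wet_kg``
- energy assays:    ``sample_id,dry_fraction,energy_kj_per_g_dm``
- population grid:  ``age_yr,N,mass_kg,F_t_per_yr,Q_t_per_yr,B_t``
- envelope:         ``age_yr,mean,lo95,hi95``

Config format
-------------
TOML with a ``[growth]`` section (keys ``w_inf_kg, k_per_yr, t0_yr, b, a``),
an optional ``[conversion]`` section, and ``[nesting.<POP>]`` sections whose
keys each hold three values ``[low, mean, high]``.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import pandas as pd

from .demography import LEVELS, NestingParams, NestingRow
from .feeding import ASSAY_COLUMNS, FEEDING_RECORD_COLUMNS, validate_feeding_records
from .growth import MASS_SERIES_COLUMNS, validate_mass_series
from .params import ConversionParams, GrowthParams

__all__ = [
    "read_mass_series", "write_mass_series",
    "read_feeding_records", "write_feeding_records",
    "read_assays", "write_assays",
    "read_config", "write_growth_config", "write_nesting_config",
    "write_grid", "write_envelope", "write_summary_json",
]

_NESTING_KEYS = [
    "nesters_per_yr", "nests_per_female", "eggs_per_nest", "hatching_success",
    "emergence_rate", "beach_survival", "water_survival",
]


def read_mass_series(path: str | Path) -> pd.DataFrame:
    return validate_mass_series(pd.read_csv(path))


def write_mass_series(data: pd.DataFrame, path: str | Path) -> None:
    validate_mass_series(data)[MASS_SERIES_COLUMNS].to_csv(path, index=False)


def read_feeding_records(path: str | Path) -> pd.DataFrame:
    return validate_feeding_records(pd.read_csv(path))


def write_feeding_records(data: pd.DataFrame, path: str | Path) -> None:
    validate_feeding_records(data)[FEEDING_RECORD_COLUMNS].to_csv(path, index=False)


def read_assays(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay file missing columns {missing}")
    return df


def write_assays(data: pd.DataFrame, path: str | Path) -> None:
    data[ASSAY_COLUMNS].to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    """Read a TOML config; returns parsed sections as python objects.

    Recognised sections: ``growth`` -> :class:`GrowthParams`, ``conversion``
    -> :class:`ConversionParams`, ``nesting`` -> :class:`NestingParams`.
    Unrecognised sections pass through untouched.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out: dict = {}
    if "growth" in raw:
        g = raw["growth"]
        out["growth"] = GrowthParams(w_inf=g["w_inf_kg"], k=g["k_per_yr"],
                                     t0=g["t0_yr"], b=g["b"], a=g["a"])
    if "conversion" in raw:
        out["conversion"] = ConversionParams(**raw["conversion"])
    if "nesting" in raw:
        rows = {}
        for pop, keys in raw["nesting"].items():
            rows[pop] = {
                lv: NestingRow(**{key: keys[key][i] for key in _NESTING_KEYS})
                for i, lv in enumerate(LEVELS)
            }
        out["nesting"] = NestingParams(rows=rows)
    for section, val in raw.items():
        out.setdefault(section, val)
    return out


def write_growth_config(gp: GrowthParams, path: str | Path,
                        cp: ConversionParams | None = None) -> None:
    lines = [
        "[growth]",
        f"w_inf_kg = {gp.w_inf!r}",
        f"k_per_yr = {gp.k!r}",
        f"t0_yr = {gp.t0!r}",
        f"b = {gp.b!r}",
        f"a = {gp.a!r}",
    ]
    if cp is not None:
        lines += [
            "",
            "[conversion]",
            f"beta = {cp.beta!r}",
            f"diet_energy_wm = {cp.diet_energy_wm!r}",
            f"jelly_energy_wm = {cp.jelly_energy_wm!r}",
            f"jelly_factor = {cp.jelly_factor!r}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_nesting_config(np_: NestingParams, path: str | Path) -> None:
    lines = []
    for pop, levels in np_.rows.items():
        lines.append(f"[nesting.{pop}]")
        for key in _NESTING_KEYS:
            vals = [getattr(levels[lv], key) for lv in LEVELS]
            lines.append(f"{key} = [{', '.join(repr(float(v)) for v in vals)}]")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_grid(grid, path: str | Path) -> None:
    grid.to_frame().rename(columns={"age_yr": "age_yr"}).to_csv(
        path, index=False, float_format="%.10g")


def write_envelope(env, path: str | Path) -> None:
    pd.DataFrame({"age_yr": env.ages, "mean": env.mean,
                  "lo95": env.lo95, "hi95": env.hi95}).to_csv(
        path, index=False, float_format="%.8g")


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
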