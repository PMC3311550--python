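"""Stand-height classifications and per-hectare aggregates.

A *stand* is any per-stem inventory table (simulated or measured) with at
least a height and a DBH column.  Five ways of summarising the height of
the community are provided:

``h_max``
    height of the tallest tree.
``h_mean``
    arithmetic mean height, optionally after removing stems shorter than
    a cutoff (2 m is the conventional choice).
``h_100``
    mean height of the 100 largest-DBH trees per hectare (a "top height");
    on plots other than 1 ha the count scales proportionally.
``h_lorey``
    basal-area-weighted mean height, sum(H_i * A_i) / sum(A_i).
``mod_lorey``
    an index combining H_max with the ratio of current to optimum basal
    area per hectare; unlike the others it is not a mean of stem heights.

All metrics operate on plain :class:`pandas.DataFrame` objects using the
canonical stem-table schema written by the simulator (``height_m``,
``dbh_m``, ...); bare ``height``/``dbh`` column names are also accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STEM_COLUMNS", "SUMMARY_COLUMNS", "as_stem_table",
    "h_max", "h_mean", "h_100", "h_lorey", "mod_lorey", "ModLorey",
    "basal_area", "stand_summary",
]

#: canonical per-stem schema (the simulator writes these columns)
STEM_COLUMNS = [
    "year", "tree_id", "species", "x_m", "y_m", "age_yr", "dbh_m",
    "height_m", "stem_mass_kg", "canopy_mass_kg", "canopy_area_m2",
    "stem_volume_m3", "phase", "alive",
]

#: canonical per-stand summary schema
SUMMARY_COLUMNS = [
    "year", "area_ha", "light", "stems_per_ha", "volume_m3_per_ha",
    "biomass_t_per_ha", "basal_area_m2_per_ha", "h_max_m", "h_mean_m",
    "h100_m", "h_lorey_m", "mod_lorey_m",
]

_ALIASES = {"height": "height_m", "dbh": "dbh_m", "basal_area": "basal_area_m2",
            "stem_volume": "stem_volume_m3", "stem_mass": "stem_mass_kg"}

# DBH is measured at 1.37 m; shorter stems have no breast-height diameter
BREAST_HEIGHT_M = 1.37


def as_stem_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise column names and check the basic stem-table invariants."""
    df = table.rename(columns={k: v for k, v in _ALIASES.items()
                               if k in table.columns and v not in table.columns})
    if "height_m" not in df.columns:
        raise ValueError("stem table needs a 'height_m' (or 'height') column")
    for col in ("height_m", "dbh_m", "basal_area_m2", "stem_volume_m3",
                "stem_mass_kg"):
        if col in df.columns and (df[col].to_numpy(dtype=float) < 0).any():
            raise ValueError(f"stem table column {col!r} contains negative values")
    return df


def basal_area(table: pd.DataFrame) -> np.ndarray:
    """Per-stem basal area A_i = pi * DBH^2 / 4 (m^2)."""
    df = as_stem_table(table)
    if "basal_area_m2" in df.columns:
        return df["basal_area_m2"].to_numpy(dtype=float)
    if "dbh_m" not in df.columns:
        raise ValueError("stem table needs 'dbh_m' or 'basal_area_m2'")
    d = df["dbh_m"].to_numpy(dtype=float)
    return np.pi * d * d / 4.0


def _require_stems(df: pd.DataFrame, what: str) -> None:
    if len(df) == 0:
        raise ValueError(f"{what}: stem table is empty")


def h_max(table: pd.DataFrame) -> float:
    """Height of the tallest tree."""
    df = as_stem_table(table)
    _require_stems(df, "h_max")
    return float(df["height_m"].max())


def h_mean(table: pd.DataFrame, min_height_filter: float = 0.0) -> float:
    """Arithmetic mean height of stems at least ``min_height_filter`` tall.

    The default includes every stem; a 2 m cutoff is the conventional
    inventory option (it tightens height-volume correlations at the cost
    of macroecological completeness).
    """
    df = as_stem_table(table)
    _require_stems(df, "h_mean")
    h = df["height_m"].to_numpy(dtype=float)
    if min_height_filter > 0:
        h = h[h >= min_height_filter]
        if h.size == 0:
            raise ValueError(
                f"h_mean: min_height_filter={min_height_filter} m removed all stems")
    return float(h.mean())


def h_100(table: pd.DataFrame, area_ha: float = 1.0) -> float:
    """Mean height of the 100 largest-DBH trees per hectare.

    On plots of other sizes the count is scaled proportionally,
    k = round(100 * area_ha), floored at one stem.  Tables with fewer
    than k stems use every stem.  DBH ties are broken by height
    (descending) and then stem id so the selection is deterministic.
    """
    df = as_stem_table(table)
    _require_stems(df, "h_100")
    if area_ha <= 0:
        raise ValueError("h_100: area_ha must be positive")
    if "dbh_m" not in df.columns:
        raise ValueError("h_100: stem table needs a 'dbh_m' column")
    k = max(1, int(round(100 * area_ha)))
    tid = df["tree_id"] if "tree_id" in df.columns else pd.Series(
        np.arange(len(df)), index=df.index)
    order = df.assign(_tid=tid.to_numpy()).sort_values(
        ["dbh_m", "height_m", "_tid"], ascending=[False, False, True],
        kind="mergesort")
    return float(order["height_m"].head(k).mean())


def h_lorey(table: pd.DataFrame) -> float:
    """Basal-area-weighted mean height, sum(H_i A_i) / sum(A_i)."""
    df = as_stem_table(table)
    _require_stems(df, "h_lorey")
    a = basal_area(df)
    total = a.sum()
    if total <= 0:
        raise ValueError("h_lorey: total basal area is zero")
    h = df["height_m"].to_numpy(dtype=float)
    return float((h * a).sum() / total)


@dataclass(frozen=True)
class ModLorey:
    """Mod Lorey height plus the basal-area capability fraction behind it."""

    height_m: float
    capability_fraction: float
    relative_ba_m2_per_ha: float


def mod_lorey(h_max: float, ba_absolute: float, occupied_area_fraction: float,
              ba_optimum_per_ha: float) -> ModLorey:
    """Constrain H_max by the stand's basal-area capability.

    ``relative BA = ba_absolute / occupied_area_fraction`` expresses the
    current absolute basal area on a per-occupied-hectare basis; dividing
    by the optimum stocking ``ba_optimum_per_ha`` gives the *capability
    fraction* (e.g. 3 m^2/ha of a 30 m^2/ha-capable stand is 10% of
    capability).  The index is the product

        ModLorey = H_max * (relative BA / optimum BA)

    which rises monotonically with both H_max and relative basal area and
    equals H_max exactly at full capability.  Values above H_max are
    possible for overstocked stands and are reported as computed.
    """
    if h_max <= 0 or ba_absolute <= 0:
        raise ValueError("mod_lorey: h_max and ba_absolute must be positive")
    if not 0 < occupied_area_fraction <= 1:
        raise ValueError("mod_lorey: occupied_area_fraction must be in (0, 1]")
    if ba_optimum_per_ha <= 0:
        raise ValueError("mod_lorey: ba_optimum_per_ha must be positive")
    rel = ba_absolute / occupied_area_fraction
    cap = rel / ba_optimum_per_ha
    return ModLorey(height_m=h_max * cap, capability_fraction=cap,
                    relative_ba_m2_per_ha=rel)


def stand_summary(table: pd.DataFrame, area_ha: float, light: float = 1.0,
                  species_params=None, min_height_filter: float = 0.0,
                  ba_optimum_per_ha: float | None = None,
                  occupied_area_fraction: float = 1.0,
                  year: float = np.nan) -> pd.Series:
    """Aggregate a stem table into per-hectare stocking and height metrics.

    Biomass is taken from ``stem_mass_kg`` when present, otherwise from
    stem volume and per-species wood density (``species_params`` mapping
    name -> :class:`~serasim.params.SpeciesParams`).  ``mod_lorey_m`` is
    reported only when an optimum basal area is supplied.
    """
    if area_ha <= 0:
        raise ValueError("stand_summary: area_ha must be positive")
    df = as_stem_table(table)
    out = {c: np.nan for c in SUMMARY_COLUMNS}
    out["year"] = year
    out["area_ha"] = area_ha
    out["light"] = light
    out["stems_per_ha"] = len(df) / area_ha
    if len(df) == 0:
        out["volume_m3_per_ha"] = 0.0
        out["biomass_t_per_ha"] = 0.0
        out["basal_area_m2_per_ha"] = 0.0
        return pd.Series(out)[SUMMARY_COLUMNS]

    ba = basal_area(df)
    out["basal_area_m2_per_ha"] = ba.sum() / area_ha

    if "stem_volume_m3" in df.columns:
        vol = df["stem_volume_m3"].to_numpy(dtype=float)
    elif "stem_mass_kg" in df.columns and species_params is not None:
        rho = df["species"].map(lambda s: species_params[s].wood_density)
        vol = df["stem_mass_kg"].to_numpy(dtype=float) / rho.to_numpy(dtype=float)
    else:
        raise ValueError("stand_summary: need stem_volume_m3, or stem_mass_kg "
                         "plus species_params, to compute volume")
    out["volume_m3_per_ha"] = vol.sum() / area_ha

    if "stem_mass_kg" in df.columns:
        mass = df["stem_mass_kg"].to_numpy(dtype=float)
    elif species_params is not None:
        rho = df["species"].map(lambda s: species_params[s].wood_density)
        mass = vol * rho.to_numpy(dtype=float)
    else:
        mass = np.full(len(df), np.nan)
    out["biomass_t_per_ha"] = mass.sum() / 1000.0 / area_ha

    out["h_max_m"] = h_max(df)
    out["h_mean_m"] = h_mean(df, min_height_filter=min_height_filter)
    out["h100_m"] = h_100(df, area_ha=area_ha)
    out["h_lorey_m"] = h_lorey(df) if ba.sum() > 0 else np.nan
    if ba_optimum_per_ha is not None and ba.sum() > 0:
        out["mod_lorey_m"] = mod_lorey(
            out["h_max_m"], float(ba.sum()), occupied_area_fraction,
            ba_optimum_per_ha).height_m
    return pd.Series(out)[SUMMARY_COLUMNS]
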