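"""Canonical study protocols: the simulation experiments and statistics
that the analysis scripts, the test suite and the acceptance script all
share.

The study design is a default-resource factorial (five forest
compositions x five planting densities, 1 ha, full light, 100 years)
plus targeted light-reduction and density-convergence experiments, with
three statistics families on top:

* pooled individual-tree allometric exponents (log-log OLS of stem mass
  on DBH, and of height on DBH, over every living stem of every year),
* the "all data" cubic fits of each stand-height classification against
  stand volume, with their coefficients of determination,
* stem-count convergence across planting densities on a volume axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analysis
from .experiments import MIXED, SweepSpec, run_sweep
from .sera_engine import SimConfig, run

__all__ = [
    "DENSITIES", "COMPOSITIONS", "HEIGHT_CLASSES",
    "default_resource_sweep", "alldata_cubic_r2", "pooled_allometry",
    "species_allometry_slopes", "abies_density_profiles",
    "density_convergence", "light_response",
]

#: the planting-density ladder of the density experiments (stems per ha)
DENSITIES = [1, 100, 1000, 10_000, 25_000]

#: forest compositions of the default-resource study
COMPOSITIONS = ["abies_alba", "cryptomeria", "generic_gymnosperm",
                "generic_angiosperm", MIXED]

#: stand-height classifications compared against volume
HEIGHT_CLASSES = ["h_max_m", "h_mean_m", "h100_m", "h_lorey_m"]


def default_resource_sweep(base_seed: int, species=None, densities=None,
                           years: int = 100, replicates: int = 1,
                           progress: bool = False) -> pd.DataFrame:
    """Long-format per-year summaries of the default-resource factorial."""
    spec = SweepSpec(species=list(species or COMPOSITIONS),
                     densities=list(densities or DENSITIES),
                     lights=[1.0], areas=[1.0], years=years,
                     replicates=replicates, base_seed=base_seed)
    archive = run_sweep(spec, progress=progress)
    if not archive.complete:
        raise RuntimeError(f"sweep failed for cells: {archive.failures}")
    return archive.summary_frame()


def alldata_cubic_r2(summaries: pd.DataFrame) -> dict[str, analysis.FitResult]:
    """One best-fitting cubic per height class over the pooled summaries."""
    out = {}
    for metric in HEIGHT_CLASSES:
        out[metric] = analysis.fit_cubic_height_volume(
            (summaries["volume_m3_per_ha"], summaries[metric]))
    return out


def pooled_allometry(base_seed: int, species: str, densities=None,
                     years: int = 100, replicates: int = 3) -> dict:
    """Pooled individual-tree allometric exponents for one species.

    Runs the species' density sweep, pools every living stem of every
    year across runs, and fits both candidate allometric pairs by
    log-log OLS: stem mass against DBH (the whole-tree AGB slope) and
    height against DBH.  Returns both fits plus the closed-form slope
    implied by the species constants (1 / e_dm).
    """
    densities = list(densities or DENSITIES)
    spec = SweepSpec(species=[species], densities=densities, lights=[1.0],
                     areas=[1.0], years=years, replicates=replicates,
                     base_seed=base_seed)
    dbh_parts, mass_parts, height_parts = [], [], []
    archive = run_sweep(spec, record_stems=True)
    if not archive.complete:
        raise RuntimeError(f"sweep failed for cells: {archive.failures}")
    for res in archive.results.values():
        stems = res.stems
        ok = stems["dbh_m"] > 0
        dbh_parts.append(stems.loc[ok, "dbh_m"].to_numpy())
        mass_parts.append(stems.loc[ok, "stem_mass_kg"].to_numpy())
        height_parts.append(stems.loc[ok, "height_m"].to_numpy())
        res.stems = None  # free the per-stem records as we go
    dbh = np.concatenate(dbh_parts)
    mass = np.concatenate(mass_parts)
    height = np.concatenate(height_parts)
    from .params import default_species
    return {
        "mass_dbh": analysis.fit_loglog_exponent(dbh, mass),
        "height_dbh": analysis.fit_loglog_exponent(dbh, height),
        "closed_form": default_species()[species].mass_diameter_slope,
        "n_stem_years": int(dbh.size),
    }


def species_allometry_slopes(base_seed: int, replicates: int = 3,
                             densities=None) -> dict[str, dict]:
    """Pooled mass-DBH slopes for the three calibrated reference species."""
    return {name: pooled_allometry(base_seed, name, replicates=replicates,
                                   densities=densities)
            for name in ("abies_alba", "generic_gymnosperm",
                         "generic_angiosperm")}


def abies_density_profiles(base_seed: int, replicates: int = 3,
                           years: int = 100) -> list[pd.DataFrame]:
    """Per-density summary series of the Abies alba density experiment."""
    df = default_resource_sweep(base_seed, species=["abies_alba"],
                                years=years, replicates=replicates)
    return [df[df.density == d] for d in DENSITIES]


def density_convergence(base_seed: int, replicates: int = 3,
                        cv_threshold: float | None = None) -> float | None:
    """Volume at which Abies alba stem counts converge across densities."""
    runs = abies_density_profiles(base_seed, replicates=replicates)
    kwargs = {} if cv_threshold is None else {"cv_threshold": cv_threshold}
    return analysis.convergence_volume(runs, **kwargs)


def light_response(base_seed: int, species=("abies_alba",
                                            "generic_angiosperm"),
                   lights=(1.0, 0.75, 0.5), density: float = 10_000,
                   years: int = 100) -> pd.DataFrame:
    """Per-year summaries of the light-reduction experiment."""
    frames = []
    for sp in species:
        for li in lights:
            res = run(SimConfig(species=sp, planting_density=density,
                                light_intensity=li, years=years,
                                rng_seed=(base_seed * 131 + int(li * 100))
                                % (2 ** 31)))
            df = res.summaries.copy()
            df.insert(0, "species", sp)
            df.insert(1, "light_level", li)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def regrowth_surge(summaries: pd.DataFrame, after_year: int = 20) -> float:
    """Cumulative regrowth pulses after early self-thinning (stems/ha).

    Sums the positive year-over-year stem-count increments from
    ``after_year`` on: years in which establishment outpaced mortality.
    Stands that only thin monotonically score ~0; stands with post-
    mortality recruitment waves score by the total size of those waves.
    """
    sub = summaries[summaries["year"] >= after_year]
    dn = np.diff(sub["stems_per_ha"].to_numpy())
    return float(dn[dn > 0].sum())
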