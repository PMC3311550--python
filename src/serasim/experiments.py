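"""Factorial sweeps over species, planting density, light and plot area.

A sweep runs one simulation per cell of the factor grid (times
replicates), with per-cell seeds derived deterministically from a base
seed, and collects the per-year summaries — and optionally per-stem
records — into an archive that the figure-assembly and statistics
stages consume.  Archives can be held in memory or written to disk as
one directory per cell (``summary.csv`` [, ``stems.csv``],
``manifest.json`` with the seed and content hashes).

Area-variation cells keep the *planted stem count* fixed while the
plot shrinks (10 000 stems/ha on 0.25 ha means 10 000 stems planted on
the quarter plot), which is how constrained-area experiments are set
up; per-hectare densities rise accordingly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .params import SpeciesParams
from .sera_engine import RunResult, SimConfig, run

__all__ = ["SweepSpec", "CellKey", "SweepArchive", "cell_seed", "run_sweep",
           "assemble_figure_data", "MIXED", "FIGURES"]

#: sentinel species entry meaning an equal-proportion four-species mix
MIXED = "mixed_species"

_DEFAULT_MIX = {"abies_alba": 0.25, "cryptomeria": 0.25,
                "generic_gymnosperm": 0.25, "generic_angiosperm": 0.25}


@dataclass(frozen=True)
class CellKey:
    species: str
    density: float
    light: float
    area_ha: float
    replicate: int

    def label(self) -> str:
        return (f"{self.species}_d{self.density:g}_l{self.light:g}"
                f"_a{self.area_ha:g}_r{self.replicate}")


@dataclass
class SweepSpec:
    """Factor grid of one experiment."""

    species: list[str] = field(default_factory=lambda: ["abies_alba"])
    densities: list[float] = field(
        default_factory=lambda: [1, 100, 1000, 10_000, 25_000])
    lights: list[float] = field(default_factory=lambda: [1.0])
    areas: list[float] = field(default_factory=lambda: [1.0])
    years: int = 100
    replicates: int = 1
    base_seed: int = 0
    maintain_planted_count: bool = True
    species_params: Mapping[str, SpeciesParams] | None = None

    def __post_init__(self) -> None:
        for name, vals in (("species", self.species),
                           ("densities", self.densities),
                           ("lights", self.lights), ("areas", self.areas)):
            if not vals:
                raise ValueError(f"sweep {name} list must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self) -> list[CellKey]:
        return [CellKey(s, d, l, a, r)
                for s in self.species for d in self.densities
                for l in self.lights for a in self.areas
                for r in range(self.replicates)]


def cell_seed(base_seed: int, key: CellKey) -> int:
    """Deterministic per-cell seed, stable across runs and platforms."""
    text = f"{base_seed}|{key.species}|{key.density:g}|{key.light:g}|" \
           f"{key.area_ha:g}|{key.replicate}"
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _cell_config(spec: SweepSpec, key: CellKey) -> SimConfig:
    species = _DEFAULT_MIX if key.species == MIXED else key.species
    density = key.density
    if spec.maintain_planted_count and key.area_ha != 1.0:
        # constant planted count: density is defined on the 1 ha reference
        density = key.density / key.area_ha
    return SimConfig(species=species, planting_density=density,
                     area_ha=key.area_ha, light_intensity=key.light,
                     years=spec.years, rng_seed=cell_seed(spec.base_seed, key),
                     species_params=spec.species_params)


@dataclass
class SweepArchive:
    """Results of a sweep: one RunResult per cell, plus a manifest."""

    spec: SweepSpec
    results: dict[CellKey, RunResult]
    failures: dict[CellKey, str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.failures

    def manifest(self) -> dict:
        cells = {}
        for key, res in self.results.items():
            cells[key.label()] = {
                "seed": cell_seed(self.spec.base_seed, key),
                "summary_sha256": hashlib.sha256(
                    res.summaries.to_csv(index=False).encode()).hexdigest(),
            }
        spec_dict = asdict(self.spec)
        spec_dict.pop("species_params", None)
        return {"spec": spec_dict, "cells": cells,
                "failures": {k.label(): v for k, v in self.failures.items()},
                "complete": self.complete}

    def summary_frame(self) -> pd.DataFrame:
        """All per-year summaries in long format with scenario columns."""
        frames = []
        for key, res in self.results.items():
            df = res.summaries.copy()
            df.insert(0, "species", key.species)
            df.insert(1, "density", key.density)
            df.insert(2, "light_level", key.light)
            df.insert(3, "area", key.area_ha)
            df.insert(4, "replicate", key.replicate)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, res in self.results.items():
            cell_dir = out / key.label()
            cell_dir.mkdir(exist_ok=True)
            res.summaries.to_csv(cell_dir / "summary.csv", index=False)
            if res.stems is not None:
                res.stems.to_csv(cell_dir / "stems.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=1))


def run_sweep(spec: SweepSpec, record_stems: bool = False,
              out_dir=None, progress: bool = False) -> SweepArchive:
    """Execute every cell of the grid; partial failures are collected.

    Cells that raise are recorded under ``failures`` and the archive is
    marked incomplete rather than aborting the whole sweep.
    """
    results: dict[CellKey, RunResult] = {}
    failures: dict[CellKey, str] = {}
    for key in spec.cells():
        cfg = _cell_config(spec, key)
        try:
            if progress:
                print(f"[sweep] {key.label()} (seed {cfg.rng_seed})")
            results[key] = run(cfg, record_stems=record_stems)
        except Exception as exc:  # noqa: BLE001 - logged and reported
            failures[key] = f"{type(exc).__name__}: {exc}"
    archive = SweepArchive(spec=spec, results=results, failures=failures)
    if out_dir is not None:
        archive.write(out_dir)
    return archive


# ----------------------------------------------------------------------
# figure datasets
# ----------------------------------------------------------------------

#: which scenario cells and value columns each figure dataset draws on
FIGURES = {
    # height-volume trajectories across planting densities (one species)
    "fig1": {"metric": "h_max_m", "species": ["abies_alba"],
             "densities": None, "lights": [1.0], "areas": [1.0]},
    "fig2": {"metric": "h_mean_m", "species": ["abies_alba"],
             "densities": None, "lights": [1.0], "areas": [1.0]},
    "fig3": {"metric": "h_lorey_m", "species": ["abies_alba"],
             "densities": None, "lights": [1.0], "areas": [1.0]},
    # species comparison at one density
    "fig4": {"metric": ["h_max_m", "h_mean_m"], "species": None,
             "densities": [10_000], "lights": [1.0], "areas": [1.0]},
    "fig5": {"metric": "h_lorey_m", "species": None,
             "densities": [10_000], "lights": [1.0], "areas": [1.0]},
    "fig6": {"metric": "h_mean_m", "species": None,
             "densities": [10_000], "lights": [1.0], "areas": [1.0]},
    "fig7": {"metric": "h_lorey_m", "species": None,
             "densities": [10_000], "lights": [1.0], "areas": [1.0],
             "against": "biomass_t_per_ha"},
    # every species x density under default resources, all height classes
    "fig8": {"metric": ["h_max_m", "h_mean_m", "h100_m", "h_lorey_m"],
             "species": None, "densities": None, "lights": [1.0],
             "areas": [1.0]},
    # thinning curves under light variation
    "fig9": {"metric": "stems_per_ha",
             "species": ["abies_alba", "generic_angiosperm"],
             "densities": [10_000], "lights": None, "areas": [1.0]},
    "fig10": {"metric": ["h_max_m", "h100_m", "h_lorey_m", "h_mean_m"],
              "species": ["abies_alba"], "densities": [10_000],
              "lights": None, "areas": [1.0]},
}


def assemble_figure_data(archive: SweepArchive, figure: str) -> pd.DataFrame:
    """Long-format table of the scenarios and metrics one figure plots.

    Raises with an explicit list of absent cells when the archive does
    not cover the figure's scenario grid.
    """
    if figure not in FIGURES:
        raise ValueError(f"unknown figure {figure!r}; choose from "
                         f"{sorted(FIGURES)}")
    want = FIGURES[figure]
    spec = archive.spec
    species = want["species"] or spec.species
    densities = want["densities"] or spec.densities
    lights = want["lights"] or spec.lights
    areas = want["areas"] or spec.areas
    metrics = want["metric"] if isinstance(want["metric"], list) else [want["metric"]]

    needed = [CellKey(s, d, l, a, r)
              for s in species for d in densities for l in lights
              for a in areas for r in range(spec.replicates)]
    missing = [k.label() for k in needed if k not in archive.results]
    if missing:
        raise ValueError(f"archive is missing {len(missing)} cell(s) for "
                         f"{figure}: {missing}")

    rows = []
    for key in needed:
        df = archive.results[key].summaries
        for metric in metrics:
            rows.append(pd.DataFrame({
                "scenario": key.label(),
                "species": key.species, "density": key.density,
                "light_level": key.light, "area": key.area_ha,
                "replicate": key.replicate,
                "year": df["year"],
                "volume_m3_per_ha": df["volume_m3_per_ha"],
                "stems_per_ha": df["stems_per_ha"],
                "against": df[want["against"]] if "against" in want
                else df["volume_m3_per_ha"],
                "metric": metric,
                "value": df[metric],
            }))
    return pd.concat(rows, ignore_index=True)
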