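"""Species parameter sets for the growth engine.

Each species is described by the constants of five allometric growth
relations (new growth, stem mass -> diameter, stem mass -> canopy mass,
diameter -> height, canopy mass -> canopy area), plus reproduction and
mortality rates.  The height-diameter relation has two regimes:

* juvenile ("geometric self-similarity"):  H = c_juv * D**gamma_juv
* mature   ("geometric nonsimilarity"):    H = h_asym * (1 - exp(-k_mature * D))

A tree switches irrevocably from the juvenile to the mature relation the
first time the mature curve meets or exceeds the juvenile one at the
tree's current diameter.  The mature form saturates at ``h_asym``
("maximum average tree height") from below, so no tree ever exceeds it.

The shipped defaults in ``data/species_defaults.yaml`` are *calibrated*
values: the mass-diameter exponent ``1/e_dm`` is pinned to published
whole-tree allometric slopes for each functional type, and the rate
constants were tuned so that simulated monocultures reproduce realistic
stand development (canopy closure, self-thinning, height and volume
envelopes) on a one-hectare, 100-year horizon.  Provenance of the target
exponents: Hammond et al.'s SERA species calibrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml
from scipy.optimize import brentq

__all__ = ["SpeciesParams", "load_species", "default_species", "DEFAULT_SPECIES_FILE"]

DEFAULT_SPECIES_FILE = "species_defaults.yaml"


@dataclass(frozen=True)
class SpeciesParams:
    """All species-specific constants of the growth relations.

    Units: metres, square metres, kilograms, years.  DBH is measured in
    metres at 1.37 m breast height.
    """

    name: str
    # height-diameter relation, juvenile regime H = c_juv * D**gamma_juv
    c_juv: float
    gamma_juv: float
    # height-diameter relation, mature regime H = h_asym * (1 - exp(-k_mature*D))
    h_asym: float
    k_mature: float
    # bulk stem density (kg m^-3); stem volume = stem mass / wood_density
    wood_density: float
    # D = c_dm * M_S**e_dm   (inverse of the mass-diameter allometry)
    c_dm: float
    e_dm: float
    # M_L = c_lm * M_S**e_lm (canopy mass from stem mass)
    c_lm: float
    e_lm: float
    # A_L = c_can * M_L**e_can (projected canopy area from canopy mass)
    c_can: float
    e_can: float
    # G_N = g_eff * A_L * M_L * exposure  (kg new growth per m^2 kg yr at full light)
    g_eff: float
    # reproduction
    repro_height_frac: float
    seeds_per_year: int
    dispersal_radius: float
    # recruit initial state; dbh and height follow from the allometry.
    # Individual seedling masses are lognormal around seedling_mass
    # (log-sd seedling_mass_sigma): without this spread a same-age cohort
    # stays exactly tied in height and, since equal heights do not shade
    # one another, asymmetric competition could never start.
    seedling_mass: float
    # mortality: a tree dies after persist_years consecutive years with
    # G_N <= mort_frac * M_L (carbon starvation)
    mort_frac: float
    persist_years: int = 2
    seedling_mass_sigma: float = 0.3
    # persistent per-tree vigor: each individual's g_eff is multiplied by
    # a lognormal factor (log-sd growth_sigma) drawn once at establishment,
    # standing in for microsite and genetic quality variation
    growth_sigma: float = 0.3
    # stochastic senescence: annual death probability
    # senescence_rate * (height / h_asym)**senescence_power, so mortality
    # concentrates on dominants approaching their height asymptote
    # (windthrow, rot and age-related decline)
    senescence_rate: float = 0.02
    senescence_power: float = 4.0

    def __post_init__(self) -> None:
        for name in ("c_juv", "gamma_juv", "h_asym", "k_mature", "wood_density",
                     "c_dm", "e_dm", "c_lm", "e_lm", "c_can", "g_eff",
                     "seedling_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.name}: parameter {name!r} must be > 0")
        if not 0 < self.repro_height_frac < 1:
            raise ValueError(f"{self.name}: repro_height_frac must be in (0, 1)")
        # the mature curve must overtake the juvenile one at some diameter,
        # otherwise trees would grow in height without bound
        self.switch_diameter()  # raises if no crossover exists

    # ------------------------------------------------------------------
    # height-diameter relations
    # ------------------------------------------------------------------
    def height_juvenile(self, dbh):
        """Power-law (geometrically self-similar) height."""
        return self.c_juv * dbh ** self.gamma_juv

    def height_mature(self, dbh):
        """Saturating (geometrically nonsimilar) height, < h_asym always."""
        import numpy as np

        return self.h_asym * -np.expm1(-self.k_mature * np.asarray(dbh, dtype=float))

    def switch_diameter(self) -> float:
        """Diameter D* at which the mature curve first meets the juvenile one.

        Found by bracketed root solving; raises ``ValueError`` when the
        parameterisation admits no crossover (an invalid species).
        """

        def gap(d: float) -> float:
            return (self.h_asym * -math.expm1(-self.k_mature * d)
                    - self.c_juv * d ** self.gamma_juv)

        lo = 1e-6
        if gap(lo) >= 0:  # mature curve already above at (near) zero
            return lo
        hi = None
        d = 2e-6
        while d < 100.0:
            if gap(d) >= 0:
                hi = d
                break
            d *= 1.5
        if hi is None:
            raise ValueError(
                f"{self.name}: mature height curve never reaches the juvenile "
                "curve; heights would be unbounded (check c_juv/k_mature/h_asym)")
        return brentq(gap, lo, hi, xtol=1e-12)

    # ------------------------------------------------------------------
    # derived allometric quantities
    # ------------------------------------------------------------------
    @property
    def mass_diameter_slope(self) -> float:
        """Closed-form log-log slope of stem mass against DBH (= 1/e_dm)."""
        return 1.0 / self.e_dm

    @property
    def seedling_dbh(self) -> float:
        return self.c_dm * self.seedling_mass ** self.e_dm

    @property
    def seedling_height(self) -> float:
        return self.c_juv * self.seedling_dbh ** self.gamma_juv

    def canopy_mass(self, stem_mass):
        return self.c_lm * stem_mass ** self.e_lm

    def canopy_area(self, canopy_mass):
        return self.c_can * canopy_mass ** self.e_can

    def to_dict(self) -> dict:
        return asdict(self)


def _read_yaml(path_or_stream) -> dict:
    if hasattr(path_or_stream, "read"):
        return yaml.safe_load(path_or_stream)
    return yaml.safe_load(Path(path_or_stream).read_text())


def load_species(path) -> dict[str, SpeciesParams]:
    """Load a species parameter file (YAML mapping name -> field dict)."""
    raw = _read_yaml(path)
    out = {}
    for name, fields in raw.items():
        out[name] = SpeciesParams(name=name, **fields)
    return out


def default_species() -> dict[str, SpeciesParams]:
    """The calibrated parameter sets shipped with the package."""
    ref = resources.files("serasim").joinpath("data", DEFAULT_SPECIES_FILE)
    with ref.open("r") as fh:
        raw = yaml.safe_load(fh)
    return {name: SpeciesParams(name=name, **fields) for name, fields in raw.items()}
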