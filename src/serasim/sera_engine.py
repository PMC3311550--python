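"""Annual-timestep, spatially explicit individual-based forest growth.

Each tree is a single stem carrying a single horizontal photosynthetic
disc at its top.  Growth of every individual each year is driven by five
allometric relations:

    M_S inc. by G_N,  D_S = f(M_S),  M_L = f(M_S),  H_S = f(D_S),
    G_N = g_eff * A_L * exposure

where M_S is above-ground wood mass, G_N the year's new growth, D_S the
diameter at breast height, M_L canopy mass, H_S total height and A_L
projected canopy area.  Each plant is a single photosynthetic surface
elevated by a single stem, so the light energy it can turn into new
tissue is proportional to the lit area of that surface.  Light competition is strictly asymmetric: a
point of a tree's canopy disc is shaded if and only if it lies under the
disc of a strictly taller tree; equal heights never shade one another.
Trees whose growth falls below a carbon-maintenance threshold for a run
of years die (self-thinning); trees above a reproductive height shed a
fixed number of seedlings into a dispersal disc each year.

The height-diameter relation has a juvenile power-law regime and a
mature saturating regime; the swap between them is irrevocable and
happens the first time the mature curve meets or exceeds the juvenile
one at the tree's current diameter (see :mod:`serasim.params`).

State is stored as flat numpy arrays on :class:`Stand`; single-tree
views are available through :class:`Tree` and the scalar operations
(:func:`update_height`, :func:`annual_growth`) for testing and direct
use.  Given the same :class:`SimConfig` (including seed) a run is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import forest_metrics as fm
from .params import SpeciesParams, default_species

__all__ = [
    "SimConfig", "Stand", "Tree", "RunResult",
    "init_stand", "light_exposure", "update_height", "annual_growth",
    "apply_mortality", "recruit", "step", "run",
]

# fields of SpeciesParams gathered into per-tree vectors for the kernels
_VEC_FIELDS = ("c_juv", "gamma_juv", "h_asym", "k_mature", "wood_density",
               "c_dm", "e_dm", "c_lm", "e_lm", "c_can", "e_can", "g_eff",
               "repro_height_frac", "dispersal_radius", "seedling_mass",
               "seedling_mass_sigma", "growth_sigma", "mort_frac",
               "senescence_rate", "senescence_power")


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario.

    ``species`` is either a single species name or a mapping of names to
    mixing proportions (proportions are normalised and applied as exact
    deterministic counts at planting).  ``planting_density`` is initial
    seedlings per hectare.  ``light_intensity`` is incident light as a
    fraction of full sun.
    """

    species: str | Mapping[str, float] = "abies_alba"
    planting_density: float = 10_000.0
    area_ha: float = 1.0
    light_intensity: float = 1.0
    years: int = 100
    rng_seed: int = 0
    recruitment_enabled: bool = True
    species_params: Mapping[str, SpeciesParams] | None = None
    # numerical controls for the light model: cell size of the canopy
    # raster (m) and the stand size up to which exact disc geometry is used
    light_cell: float = 0.5
    exact_threshold: int = 160
    # optional optimum basal area (m^2/ha) enabling mod-Lorey in summaries
    ba_optimum_per_ha: float | None = None

    def species_mix(self) -> dict[str, float]:
        if isinstance(self.species, str):
            return {self.species: 1.0}
        total = float(sum(self.species.values()))
        if total <= 0:
            raise ValueError("species mix proportions must sum to > 0")
        return {k: v / total for k, v in self.species.items()}

    def resolve_params(self) -> dict[str, SpeciesParams]:
        params = dict(self.species_params) if self.species_params else default_species()
        missing = [s for s in self.species_mix() if s not in params]
        if missing:
            raise ValueError(f"no parameters for species: {missing}")
        return params

    def validate(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("area_ha must be positive")
        if self.planting_density <= 0:
            raise ValueError("planting_density must be positive")
        if round(self.planting_density * self.area_ha) < 1:
            raise ValueError("planting_density * area_ha must be >= 1 seedling")
        if not 0 < self.light_intensity <= 1:
            raise ValueError("light_intensity must be in (0, 1]")
        if self.years < 0:
            raise ValueError("years must be >= 0")
        self.resolve_params()


@dataclass
class Tree:
    """A single individual (a copied view of one slot of a Stand)."""

    id: int
    x: float
    y: float
    age: int
    dbh: float
    height: float
    stem_mass: float
    canopy_mass: float
    canopy_area: float
    phase: str            # "juvenile" | "mature"
    alive: bool = True
    last_growth: float = 0.0
    species: str = ""


class Stand:
    """A bounded plot at one point in time; tree state lives in flat arrays."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        self.width = math.sqrt(config.area_ha * 1e4)
        self.length = self.width
        self.area_ha = config.area_ha
        self.light_intensity = config.light_intensity
        self.year = 0
        self.rng = np.random.default_rng(config.rng_seed)
        self.params = config.resolve_params()
        self.species_names = sorted(config.species_mix())
        self._pv = {f: np.array([getattr(self.params[s], f)
                                 for s in self.species_names])
                    for f in _VEC_FIELDS}
        self._seeds_per_year = np.array(
            [self.params[s].seeds_per_year for s in self.species_names])
        self._persist_years = np.array(
            [self.params[s].persist_years for s in self.species_names])
        self._next_id = 0
        self.dead_log: list[dict] = []
        self._alloc(0)

    # ------------------------------------------------------------------
    def _alloc(self, n: int) -> None:
        self.id = np.zeros(n, dtype=np.int64)
        self.sidx = np.zeros(n, dtype=np.int64)      # index into species_names
        self.x = np.zeros(n)
        self.y = np.zeros(n)
        self.age = np.zeros(n, dtype=np.int64)
        self.dbh = np.zeros(n)
        self.height = np.zeros(n)
        self.stem_mass = np.zeros(n)
        self.canopy_mass = np.zeros(n)
        self.canopy_area = np.zeros(n)
        self.mature = np.zeros(n, dtype=bool)
        self.last_growth = np.zeros(n)
        self.last_exposure = np.zeros(n)
        self.starve_years = np.zeros(n, dtype=np.int64)
        self.growth_mult = np.ones(n)

    @property
    def n_trees(self) -> int:
        return self.id.size

    def pv(self, name: str) -> np.ndarray:
        """Per-tree vector of species parameter ``name``."""
        return self._pv[name][self.sidx]

    def _append(self, sidx: np.ndarray, x: np.ndarray, y: np.ndarray) -> None:
        """Add seedlings of the given species at the given positions."""
        n = sidx.size
        if n == 0:
            return
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        # lognormal spread of establishment size; breaks cohort height ties
        mass = self._pv["seedling_mass"][sidx] * np.exp(
            self._pv["seedling_mass_sigma"][sidx] * self.rng.standard_normal(n))
        # persistent individual vigor (microsite / genetic quality);
        # the normal deviate is clipped so no individual is more than
        # ~5x as vigorous as the weakest (unbounded tails produce
        # physically implausible giants)
        mult = np.exp(self._pv["growth_sigma"][sidx]
                      * np.clip(self.rng.standard_normal(n), -1.6, 1.6))
        ml = self._pv["c_lm"][sidx] * mass ** self._pv["e_lm"][sidx]
        area = self._pv["c_can"][sidx] * ml ** self._pv["e_can"][sidx]
        dbh = self._pv["c_dm"][sidx] * mass ** self._pv["e_dm"][sidx]
        h_juv = self._pv["c_juv"][sidx] * dbh ** self._pv["gamma_juv"][sidx]
        h_mat = self._pv["h_asym"][sidx] * -np.expm1(-self._pv["k_mature"][sidx] * dbh)
        mature = h_mat >= h_juv
        height = np.where(mature, h_mat, h_juv)
        for name, vals in (("id", ids), ("sidx", sidx), ("x", x), ("y", y),
                           ("age", np.zeros(n, dtype=np.int64)), ("dbh", dbh),
                           ("height", height), ("stem_mass", mass),
                           ("canopy_mass", ml), ("canopy_area", area),
                           ("mature", mature),
                           ("last_growth", np.zeros(n)),
                           ("last_exposure", np.zeros(n)),
                           ("starve_years", np.zeros(n, dtype=np.int64)),
                           ("growth_mult", mult)):
            setattr(self, name, np.concatenate([getattr(self, name), vals]))

    def _remove(self, kill: np.ndarray) -> None:
        keep = ~kill
        for name in ("id", "sidx", "x", "y", "age", "dbh", "height",
                     "stem_mass", "canopy_mass", "canopy_area", "mature",
                     "last_growth", "last_exposure", "starve_years",
                     "growth_mult"):
            setattr(self, name, getattr(self, name)[keep])

    # ------------------------------------------------------------------
    def tree(self, i: int) -> Tree:
        return Tree(
            id=int(self.id[i]), x=float(self.x[i]), y=float(self.y[i]),
            age=int(self.age[i]), dbh=float(self.dbh[i]),
            height=float(self.height[i]), stem_mass=float(self.stem_mass[i]),
            canopy_mass=float(self.canopy_mass[i]),
            canopy_area=float(self.canopy_area[i]),
            phase="mature" if self.mature[i] else "juvenile",
            last_growth=float(self.last_growth[i]),
            species=self.species_names[self.sidx[i]])

    @property
    def trees(self) -> list[Tree]:
        return [self.tree(i) for i in range(self.n_trees)]

    def stem_table(self) -> pd.DataFrame:
        """Current state as a stem table (canonical schema)."""
        species = np.asarray(self.species_names, dtype=object)[self.sidx]
        rho = self.pv("wood_density")
        return pd.DataFrame({
            "year": np.full(self.n_trees, self.year, dtype=np.int64),
            "tree_id": self.id,
            "species": species,
            "x_m": self.x, "y_m": self.y,
            "age_yr": self.age,
            "dbh_m": self.dbh,
            "height_m": self.height,
            "stem_mass_kg": self.stem_mass,
            "canopy_mass_kg": self.canopy_mass,
            "canopy_area_m2": self.canopy_area,
            "stem_volume_m3": self.stem_mass / rho,
            "phase": np.where(self.mature, "mature", "juvenile"),
            "alive": np.ones(self.n_trees, dtype=bool),
        })

    def summary(self) -> pd.Series:
        return fm.stand_summary(
            self.stem_table(), area_ha=self.area_ha,
            light=self.light_intensity, species_params=self.params,
            ba_optimum_per_ha=self.config.ba_optimum_per_ha, year=self.year)


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def init_stand(config: SimConfig) -> Stand:
    """Plant round(density * area) seedlings uniformly at random.

    Multi-species mixes are allocated by exact largest-remainder counts
    and randomly interleaved, so the stated proportions hold exactly.
    """
    stand = Stand(config)
    n = int(round(config.planting_density * config.area_ha))
    mix = config.species_mix()
    names = stand.species_names
    fracs = np.array([mix[s] for s in names])
    counts = np.floor(fracs * n).astype(int)
    rem = n - counts.sum()
    if rem > 0:  # largest fractional remainders get the leftover seedlings
        order = np.argsort(-(fracs * n - counts), kind="stable")
        counts[order[:rem]] += 1
    sidx = np.repeat(np.arange(len(names)), counts)
    stand.rng.shuffle(sidx)
    x = stand.rng.uniform(0, stand.width, n)
    y = stand.rng.uniform(0, stand.length, n)
    stand._append(sidx, x, y)
    return stand


def _exact_exposure(x, y, r, h, light) -> np.ndarray:
    """Unshaded disc fractions by exact disc-intersection geometry (shapely)."""
    from shapely.geometry import Point
    from shapely.ops import unary_union

    n = x.size
    frac = np.ones(n)
    if n <= 1:
        return light * frac
    discs = [Point(x[i], y[i]).buffer(r[i], quad_segs=96) for i in range(n)]
    for i in range(n):
        dx = x - x[i]
        dy = y - y[i]
        taller = np.flatnonzero((h > h[i]) & (dx * dx + dy * dy
                                              < (r + r[i]) ** 2))
        if taller.size == 0:
            continue
        shade = unary_union([discs[j] for j in taller]).intersection(discs[i])
        frac[i] = max(0.0, 1.0 - shade.area / discs[i].area)
    return light * frac


def _raster_exposure(x, y, r, h, light, width, length, cell) -> np.ndarray:
    """Unshaded disc fractions by canopy-height-model raster quadrature.

    Discs are sampled on a regular grid of ``cell`` metres: a grid point
    belongs to a disc if its centre lies inside it, and is shaded if a
    strictly taller tree's disc also covers it.  Discs smaller than one
    cell collapse to their centre point.  The raster is padded by the
    largest radius so discs overhanging the plot edge are kept whole.
    """
    n = x.size
    if n == 0:
        return np.zeros(0)
    margin = float(np.ceil(r.max())) + cell
    x0 = -margin
    y0 = -margin
    nx = int(math.ceil((width + 2 * margin) / cell))
    ny = int(math.ceil((length + 2 * margin) / cell))
    chm = np.zeros(ny * nx)

    ix = np.clip(((x - x0) / cell).astype(np.int64), 0, nx - 1)
    iy = np.clip(((y - y0) / cell).astype(np.int64), 0, ny - 1)
    centre = iy * nx + ix
    small = r <= 0.5 * cell
    np.maximum.at(chm, centre[small], h[small])

    big = np.flatnonzero(~small)
    windows: list[tuple] = []
    chm2 = chm.reshape(ny, nx)
    for i in big:
        j0 = max(0, int((x[i] - r[i] - x0) / cell))
        j1 = min(nx, int((x[i] + r[i] - x0) / cell) + 1)
        k0 = max(0, int((y[i] - r[i] - y0) / cell))
        k1 = min(ny, int((y[i] + r[i] - y0) / cell) + 1)
        xs = x0 + (np.arange(j0, j1) + 0.5) * cell - x[i]
        ys = y0 + (np.arange(k0, k1) + 0.5) * cell - y[i]
        mask = ys[:, None] ** 2 + xs[None, :] ** 2 <= r[i] ** 2
        if not mask.any():
            windows.append(None)
            continue
        win = chm2[k0:k1, j0:j1]
        np.maximum(win, h[i], where=mask, out=win)
        windows.append((k0, k1, j0, j1, mask))

    frac = np.empty(n)
    frac[small] = (chm[centre[small]] <= h[small]).astype(float)
    for i, spec in zip(big, windows):
        if spec is None:  # disc missed every grid point; fall back to centre
            frac[i] = float(chm[centre[i]] <= h[i])
            continue
        k0, k1, j0, j1, mask = spec
        cells = chm2[k0:k1, j0:j1][mask]
        frac[i] = float(np.count_nonzero(cells <= h[i])) / cells.size
    return light * frac


def light_exposure(stand: Stand, method: str = "auto") -> np.ndarray:
    """Per-tree light exposure in [0, light_intensity].

    Exposure is the incident light times the unshaded fraction of the
    tree's canopy disc, where a point is shaded iff it lies under the
    disc of a *strictly* taller tree.  ``method`` is ``"exact"`` (disc
    unions), ``"raster"`` (grid quadrature) or ``"auto"`` (exact for
    small stands, raster above ``config.exact_threshold`` trees).
    """
    n = stand.n_trees
    if n == 0:
        return np.zeros(0)
    radius = np.sqrt(stand.canopy_area / math.pi)
    if method == "auto":
        method = "exact" if n <= stand.config.exact_threshold else "raster"
    if method == "exact":
        return _exact_exposure(stand.x, stand.y, radius, stand.height,
                               stand.light_intensity)
    if method == "raster":
        return _raster_exposure(stand.x, stand.y, radius, stand.height,
                                stand.light_intensity, stand.width,
                                stand.length, stand.config.light_cell)
    raise ValueError(f"unknown light method {method!r}")


def update_height(dbh: float, phase: str, params: SpeciesParams):
    """Height from DBH with the irrevocable juvenile->mature swap.

    While juvenile, height follows the power law; the first time the
    saturating mature curve at the current diameter meets or exceeds it,
    the tree swaps permanently to the mature curve.  The returned height
    never exceeds ``params.h_asym``.
    """
    if dbh < 0:
        raise ValueError("dbh must be >= 0")
    if phase not in ("juvenile", "mature"):
        raise ValueError(f"unknown phase {phase!r}")
    h_juv = params.c_juv * dbh ** params.gamma_juv
    h_mat = params.h_asym * -math.expm1(-params.k_mature * dbh)
    if phase == "mature" or h_mat >= h_juv:
        return h_mat, "mature"
    return h_juv, "juvenile"


def _partition_mass(total, c_lm, e_lm, ms_start):
    """Solve M_S + c_lm * M_S**e_lm = total for M_S (vectorised Newton).

    Started from below the root the iteration is monotone increasing for
    e_lm < 1, so it converges without safeguarding.
    """
    m = np.maximum(np.asarray(ms_start, dtype=float), 1e-12)
    for _ in range(80):
        f = m + c_lm * m ** e_lm - total
        fp = 1.0 + c_lm * e_lm * m ** (e_lm - 1.0)
        delta = f / fp
        m = m - delta
        if np.max(np.abs(delta) / np.maximum(m, 1e-9)) < 1e-13:
            break
    return m


def _grow_arrays(stand: Stand, exposure: np.ndarray) -> None:
    """Vectorised annual growth of every tree in place."""
    g = stand.pv("g_eff") * stand.growth_mult * stand.canopy_area * exposure
    c_lm = stand.pv("c_lm")
    e_lm = stand.pv("e_lm")
    total = stand.stem_mass + stand.canopy_mass + g
    ms = _partition_mass(total, c_lm, e_lm, stand.stem_mass)
    ml = total - ms                       # exact mass conservation
    dbh = stand.pv("c_dm") * ms ** stand.pv("e_dm")
    h_juv = stand.pv("c_juv") * dbh ** stand.pv("gamma_juv")
    h_mat = stand.pv("h_asym") * -np.expm1(-stand.pv("k_mature") * dbh)
    stand.mature |= h_mat >= h_juv
    stand.height = np.where(stand.mature, h_mat, h_juv)
    stand.stem_mass = ms
    stand.canopy_mass = ml
    stand.canopy_area = stand.pv("c_can") * ml ** stand.pv("e_can")
    stand.dbh = dbh
    stand.last_growth = g
    stand.last_exposure = exposure
    stand.age = stand.age + 1


def annual_growth(tree: Tree, exposure: float, params: SpeciesParams) -> Tree:
    """One year of growth for a single tree (scalar form of the kernel).

    New growth G_N = g_eff * A_L * exposure is partitioned so the
    canopy-mass allometry M_L = c_lm * M_S**e_lm holds afterwards, with
    the stem absorbing the remainder; DBH, height (with phase swap) and
    canopy area then follow from their allometries.
    """
    if not 0 <= exposure <= 1:
        raise ValueError("exposure must be in [0, 1]")
    g = params.g_eff * tree.canopy_area * exposure
    total = tree.stem_mass + tree.canopy_mass + g
    ms = float(_partition_mass(np.array([total]), params.c_lm, params.e_lm,
                               np.array([tree.stem_mass]))[0])
    ml = total - ms
    dbh = params.c_dm * ms ** params.e_dm
    height, phase = update_height(dbh, tree.phase, params)
    return replace(tree, age=tree.age + 1, dbh=dbh, height=height,
                   stem_mass=ms, canopy_mass=ml,
                   canopy_area=params.canopy_area(ml), phase=phase,
                   last_growth=g)


def apply_mortality(stand: Stand) -> Stand:
    """Remove carbon-starved trees (self-thinning).

    A tree is starving in a year when its new growth G_N falls to or
    below ``mort_frac * M_L`` — the canopy's maintenance demand.  After
    ``persist_years`` consecutive starving years it dies.  On top of
    starvation, dominants face a stochastic senescence hazard rising
    steeply as height approaches the species asymptote.  Removals are
    logged; stem count never increases here.
    """
    if stand.n_trees == 0:
        return stand
    starving = stand.last_growth <= stand.pv("mort_frac") * stand.canopy_mass
    # newly planted trees have not grown yet; they are not starving
    starving &= stand.age > 0
    stand.starve_years = np.where(starving, stand.starve_years + 1, 0)
    kill = stand.starve_years >= stand._persist_years[stand.sidx]
    hazard = stand.pv("senescence_rate") * (
        stand.height / stand.pv("h_asym")) ** stand.pv("senescence_power")
    kill |= stand.rng.uniform(size=stand.n_trees) < hazard
    if kill.any():
        stand.dead_log.append({
            "year": stand.year,
            "n_died": int(kill.sum()),
            "mass_died_kg": float(stand.stem_mass[kill].sum()
                                  + stand.canopy_mass[kill].sum()),
        })
        stand._remove(kill)
    return stand


def recruit(stand: Stand) -> Stand:
    """Shed seedlings around every reproductive tree.

    Trees taller than ``repro_height_frac * h_asym`` each produce up to
    ``seeds_per_year`` seedlings — the count scales with the parent's
    light exposure, so suppressed subcanopy trees contribute little seed
    rain while open-grown pioneers colonise at the full rate — at
    uniform random positions within ``dispersal_radius`` of the parent;
    positions falling outside the plot are discarded (hard,
    non-toroidal boundary).
    """
    if not stand.config.recruitment_enabled or stand.n_trees == 0:
        return stand
    parents = np.flatnonzero(
        stand.height >= stand.pv("repro_height_frac") * stand.pv("h_asym"))
    if parents.size == 0:
        return stand
    # each potential seed establishes with probability equal to the
    # parent's light exposure (binomial thinning), so fecundity declines
    # smoothly with shading instead of cutting off at a rounding edge
    counts = stand.rng.binomial(
        stand._seeds_per_year[stand.sidx[parents]],
        np.clip(stand.last_exposure[parents], 0.0, 1.0)).astype(np.int64)
    parents = parents[counts > 0]
    counts = counts[counts > 0]
    if parents.size == 0:
        return stand
    px = np.repeat(stand.x[parents], counts)
    py = np.repeat(stand.y[parents], counts)
    sidx = np.repeat(stand.sidx[parents], counts)
    radius = np.repeat(stand.pv("dispersal_radius")[parents], counts)
    m = px.size
    rho = radius * np.sqrt(stand.rng.uniform(size=m))
    theta = stand.rng.uniform(0, 2 * math.pi, m)
    nx = px + rho * np.cos(theta)
    ny = py + rho * np.sin(theta)
    inside = (nx >= 0) & (nx < stand.width) & (ny >= 0) & (ny < stand.length)
    sidx, nx, ny = sidx[inside], nx[inside], ny[inside]
    # light-demanding establishment: a seed only takes root on ground not
    # already overtopped by an existing canopy disc taller than the
    # seedling itself, so closed stands admit recruits only in gaps
    open_h = _canopy_height_at(stand, nx, ny)
    h_seedling = (stand._pv["c_juv"][sidx]
                  * (stand._pv["c_dm"][sidx]
                     * stand._pv["seedling_mass"][sidx]
                     ** stand._pv["e_dm"][sidx])
                  ** stand._pv["gamma_juv"][sidx])
    open_ground = open_h <= h_seedling
    stand._append(sidx[open_ground], nx[open_ground], ny[open_ground])
    return stand


def _canopy_height_at(stand: Stand, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Height of the tallest canopy disc covering each ground point."""
    if stand.n_trees == 0 or px.size == 0:
        return np.zeros(px.size)
    out = np.zeros(px.size)
    r2 = stand.canopy_area / math.pi
    # evaluate in blocks to bound memory on big stands
    block = max(1, int(2e6 // max(stand.n_trees, 1)))
    for i0 in range(0, px.size, block):
        sl = slice(i0, min(i0 + block, px.size))
        d2 = ((px[sl, None] - stand.x[None, :]) ** 2
              + (py[sl, None] - stand.y[None, :]) ** 2)
        covered = d2 <= r2[None, :]
        h = np.where(covered, stand.height[None, :], 0.0)
        out[sl] = h.max(axis=1)
    return out


def step(stand: Stand, light_method: str = "auto") -> Stand:
    """Advance one year: light -> growth -> mortality -> recruitment."""
    exposure = light_exposure(stand, method=light_method)
    if stand.n_trees:
        _grow_arrays(stand, exposure)
    apply_mortality(stand)
    recruit(stand)
    stand.year += 1
    return stand


@dataclass
class RunResult:
    """Per-year outputs of one simulation."""

    config: SimConfig
    summaries: pd.DataFrame                  # one row per year
    stems: pd.DataFrame | None = None        # per-year per-stem records
    final_stems: pd.DataFrame | None = None  # stem table at the last year
    dead_log: pd.DataFrame | None = None


def run(config: SimConfig, record_stems: bool = False,
        light_method: str = "auto", progress: bool = False) -> RunResult:
    """Simulate ``config.years`` years from a fresh planting.

    Returns per-year per-hectare summaries (always), per-year stem
    tables when ``record_stems`` (memory permitting: densest scenarios
    produce millions of stem-years), and the final-year stem table.
    """
    config.validate()
    stand = init_stand(config)
    summaries = [stand.summary()]
    stems = [stand.stem_table()] if record_stems else None
    for _ in range(config.years):
        step(stand, light_method=light_method)
        summaries.append(stand.summary())
        if record_stems:
            stems.append(stand.stem_table())
        if progress and stand.year % 10 == 0:
            print(f"  year {stand.year:4d}: {stand.n_trees} trees")
    return RunResult(
        config=config,
        summaries=pd.DataFrame(summaries).reset_index(drop=True),
        stems=pd.concat(stems, ignore_index=True) if record_stems else None,
        final_stems=stand.stem_table(),
        dead_log=pd.DataFrame(stand.dead_log) if stand.dead_log else
        pd.DataFrame(columns=["year", "n_died", "mass_died_kg"]),
    )
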