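"""Synthetic stem tables and height-volume series with known structure.

These generators give the metrics and regression operations inputs whose
true parameters are known in closed form, without running the simulator:
stem populations whose height is a noisy power function of DBH saturating
at a species cap (the juvenile/mature pattern of real inventories, at
densities 10^2-10^6 /ha and heights in the 6-49 m empirical envelope),
and height-volume trajectories drawn from a known cubic with a chosen
generative R^2.  Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FixtureSpec", "make_stem_table", "make_height_volume_series"]

# stem volume from basal area and height with a standard taper form factor
_FORM_FACTOR = 0.42
_WOOD_DENSITY = 500.0  # kg m^-3, nominal


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic stem population.

    DBH is lognormal (``dbh_mu``/``dbh_sigma`` on the log scale, metres);
    height follows h = a * dbh**b capped at ``h_cap`` with multiplicative
    lognormal noise of log-sd ``sigma_h`` (set 0 for an exact law, or
    ``additive_noise`` for a Gaussian alternative).
    """

    n_stems: int = 500
    dbh_mu: float = -1.6          # median DBH ~ 0.20 m
    dbh_sigma: float = 0.5
    height_a: float = 40.0
    height_b: float = 0.6667
    h_cap: float = 49.0
    sigma_h: float = 0.0
    density_per_ha: float = 1000.0
    seed: int = 0
    additive_noise: bool = False

    def __post_init__(self) -> None:
        if self.n_stems < 1:
            raise ValueError("n_stems must be >= 1")
        for name in ("dbh_sigma", "height_a", "height_b", "h_cap",
                     "density_per_ha"):
            if getattr(self, name) <= 0 and name != "dbh_sigma":
                raise ValueError(f"{name} must be positive")
        if self.sigma_h < 0:
            raise ValueError("sigma_h must be >= 0")


def make_stem_table(spec: FixtureSpec) -> pd.DataFrame:
    """Generate a stem table following the specified height law exactly.

    With ``sigma_h = 0`` every stem lies on h = a*dbh**b (up to the cap),
    so a log-log fit of the uncapped subset recovers ``height_b`` to
    numerical precision.
    """
    rng = np.random.default_rng(spec.seed)
    dbh = rng.lognormal(spec.dbh_mu, spec.dbh_sigma, spec.n_stems)
    law = spec.height_a * dbh ** spec.height_b
    h = np.minimum(law, spec.h_cap)
    if spec.sigma_h > 0:
        if spec.additive_noise:
            h = np.maximum(h + rng.normal(0, spec.sigma_h, spec.n_stems), 1e-3)
        else:
            h = h * rng.lognormal(0.0, spec.sigma_h, spec.n_stems)
    area_ha = spec.n_stems / spec.density_per_ha
    side = math.sqrt(area_ha * 1e4)
    ba = np.pi * dbh ** 2 / 4.0
    vol = _FORM_FACTOR * ba * h
    return pd.DataFrame({
        "tree_id": np.arange(spec.n_stems),
        "species": "fixture",
        "x_m": rng.uniform(0, side, spec.n_stems),
        "y_m": rng.uniform(0, side, spec.n_stems),
        "dbh_m": dbh,
        "height_m": h,
        "basal_area_m2": ba,
        "stem_volume_m3": vol,
        "stem_mass_kg": vol * _WOOD_DENSITY,
        "on_law": law <= spec.h_cap,   # stems unaffected by the cap
    })


def make_height_volume_series(coeffs, n: int = 200, seed: int = 0,
                              v_range: tuple[float, float] = (5.0, 700.0),
                              noise_sd: float | None = None,
                              target_r2: float | None = None) -> pd.DataFrame:
    """A (volume, height) series from a known cubic with known R^2.

    ``coeffs`` are cubic coefficients (c0, c1, c2, c3), lowest order
    first.  Supply either ``noise_sd`` (Gaussian height noise, m) or
    ``target_r2``; in the latter case the noise is sized so the
    *generative* R^2 = var(signal)/(var(signal)+sd^2) equals the target.
    """
    if (noise_sd is None) == (target_r2 is None):
        raise ValueError("supply exactly one of noise_sd / target_r2")
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (4,):
        raise ValueError("coeffs must be the 4 cubic coefficients c0..c3")
    rng = np.random.default_rng(seed)
    v = np.sort(rng.uniform(v_range[0], v_range[1], n))
    signal = np.polynomial.polynomial.polyval(v, coeffs)
    if target_r2 is not None:
        if not 0 < target_r2 <= 1:
            raise ValueError("target_r2 must be in (0, 1]")
        var_sig = float(np.var(signal))
        noise_sd = math.sqrt(var_sig * (1.0 / target_r2 - 1.0))
    h = signal + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"volume_m3_per_ha": v, "height_m": h,
                         "signal_m": signal})
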