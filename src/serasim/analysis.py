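"""Statistical procedures over simulated (or measured) stands.

* log-log OLS allometric exponent fits (tree level and stand level),
* cubic least-squares fits of a height classification on stand volume,
  with r^2 both on the training data and for cross-application of a
  fitted "all data" curve to individual datasets,
* mean percent difference between two height-volume trajectories on a
  shared interpolation grid,
* detection of the stand volume at which stem counts of different
  planting densities converge.

All regressions are ordinary least squares (model type II alternatives
are deliberately out of scope: the question is always how well one
variable *predicts* another).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FitResult", "fit_loglog_exponent", "fit_cubic_height_volume",
    "r2_against_reference", "fit_stand_allometry",
    "curve_percent_difference", "convergence_volume",
]


@dataclass(frozen=True)
class FitResult:
    """Coefficients and goodness of fit of one regression."""

    model: str                 # "loglog" | "cubic" | "power"
    coefficients: np.ndarray   # loglog: [intercept, slope]; cubic: c0..c3
    r2: float
    n: int
    residual_sd: float
    extras: dict = field(default_factory=dict)

    @property
    def slope(self) -> float:
        if self.model not in ("loglog", "power"):
            raise AttributeError(f"{self.model} fit has no slope")
        return float(self.coefficients[1])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.model == "loglog":
            return c[0] + c[1] * x          # operates on log10 axes
        if self.model == "power":
            return self.extras["beta"] * x ** c[1]
        if self.model == "cubic":
            return c[0] + c[1] * x + c[2] * x ** 2 + c[3] * x ** 3
        raise ValueError(self.model)


def _check_positive(arr: np.ndarray, name: str) -> None:
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(f"{name} must be strictly positive for a log-log fit; "
                         f"first offending row: {bad[0]} (value {arr[bad[0]]!r})")


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SSE/SST; zero observed variance returns 0.0 by convention."""
    sst = float(np.sum((observed - observed.mean()) ** 2))
    sse = float(np.sum((observed - predicted) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - sse / sst


def fit_loglog_exponent(x, y) -> FitResult:
    """OLS of log10(y) on log10(x); the slope is the allometric exponent."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points for an exponent fit")
    _check_positive(x, "x")
    _check_positive(y, "y")
    lx, ly = np.log10(x), np.log10(y)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    pred = res.predict()
    return FitResult(
        model="loglog", coefficients=np.asarray(res.params, dtype=float),
        r2=_r2(ly, pred), n=x.size,
        residual_sd=float(np.std(ly - pred, ddof=2)) if x.size > 2 else 0.0,
        extras={"slope_se": float(res.bse[1])})


def fit_stand_allometry(m_forest, h) -> FitResult:
    """Stand-level power law M = beta * H**alpha via log-log OLS.

    ``m_forest`` is standing biomass per hectare (any consistent unit)
    and ``h`` an average forest height; beta and alpha land in
    ``extras["beta"]`` / ``extras["alpha"]``.
    """
    base = fit_loglog_exponent(h, m_forest)
    beta = 10.0 ** base.coefficients[0]
    return FitResult(model="power", coefficients=base.coefficients,
                     r2=base.r2, n=base.n, residual_sd=base.residual_sd,
                     extras={**base.extras, "beta": float(beta),
                             "alpha": float(base.coefficients[1])})


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    """Accept a (volume, height) DataFrame or a 2-tuple of arrays."""
    if isinstance(series, pd.DataFrame):
        vcol = next((c for c in ("volume_m3_per_ha", "volume") if c in series), None)
        hcol = next((c for c in series.columns
                     if c.startswith(("h_", "h1", "height", "mod_"))
                     or c in ("h100_m",)), None)
        if vcol is None or hcol is None:
            raise ValueError("series DataFrame needs a volume column and a "
                             "height column")
        return (series[vcol].to_numpy(dtype=float),
                series[hcol].to_numpy(dtype=float))
    v, h = series
    return np.asarray(v, dtype=float).ravel(), np.asarray(h, dtype=float).ravel()


def fit_cubic_height_volume(series) -> FitResult:
    """Least-squares cubic of height on stand volume.

    ``series`` is a (volume, height) pair of arrays or a DataFrame with a
    volume column and one height column.  A constant-height series has
    zero total variance; its r^2 is reported as 0.0 by convention.
    """
    v, h = _series_arrays(series)
    ok = np.isfinite(v) & np.isfinite(h)
    v, h = v[ok], h[ok]
    if v.size < 5:
        raise ValueError("need at least 5 points for a cubic fit")
    if np.ptp(v) == 0:
        raise ValueError("degenerate design: volume is constant")
    # center/scale the design for conditioning, then expand back
    coeffs_scaled = np.polynomial.polynomial.polyfit(v, h, deg=3)
    pred = np.polynomial.polynomial.polyval(v, coeffs_scaled)
    return FitResult(model="cubic", coefficients=np.asarray(coeffs_scaled),
                     r2=_r2(h, pred), n=v.size,
                     residual_sd=float(np.std(h - pred, ddof=min(4, v.size - 1))))


def r2_against_reference(fit: FitResult, series) -> float:
    """Coefficient of determination of an existing fit on a new series.

    Computes 1 - SSE/SST of ``fit``'s predictions against the observed
    heights.  Cross-applying a curve fitted elsewhere can give negative
    values (the curve does worse than the series mean); they are
    reported as computed.
    """
    v, h = _series_arrays(series)
    ok = np.isfinite(v) & np.isfinite(h)
    v, h = v[ok], h[ok]
    if v.size == 0:
        raise ValueError("empty series")
    return _r2(h, fit.predict(v))


def _monotone_profile(v: np.ndarray, h: np.ndarray):
    """Sort by volume and average heights at duplicate volumes."""
    order = np.argsort(v, kind="mergesort")
    v, h = v[order], h[order]
    uv, inverse = np.unique(v, return_inverse=True)
    uh = np.bincount(inverse, weights=h) / np.bincount(inverse)
    return uv, uh


def curve_percent_difference(a, b, grid_step: float = 2.0) -> float:
    """Mean percent height difference of two height-volume trajectories.

    Both series are linearly interpolated onto a shared volume grid at
    ``grid_step`` (m^3) spanning the overlap of their volume ranges; the
    result is the mean of 100*|h_a - h_b|/h_a over the grid, with the
    first series as the reference (by convention the baseline / higher-
    resource scenario).  No extrapolation outside the overlap.
    """
    va, ha = _series_arrays(a)
    vb, hb = _series_arrays(b)
    va, ha = _monotone_profile(va, ha)
    vb, hb = _monotone_profile(vb, hb)
    lo = max(va.min(), vb.min())
    hi = min(va.max(), vb.max())
    if hi <= lo:
        raise ValueError("series volume ranges do not overlap")
    grid = np.arange(lo, hi + 1e-9, grid_step)
    ga = np.interp(grid, va, ha)
    gb = np.interp(grid, vb, hb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(ga - gb) / ga
    rel = rel[np.isfinite(rel)]
    if rel.size == 0:
        raise ValueError("reference heights are zero over the whole grid")
    return float(100.0 * rel.mean())


def convergence_volume(runs, cv_threshold: float = 0.12,
                       grid_step: float = 5.0) -> float | None:
    """Volume at which stem counts across planting densities converge.

    ``runs`` is a sequence (or mapping) of per-year stand summaries, one
    per planting density, each with ``volume_m3_per_ha`` and
    ``stems_per_ha`` columns.  Stem counts are interpolated onto a
    shared volume grid; the result is the smallest grid volume at which
    the coefficient of variation across scenarios drops below
    ``cv_threshold`` *and stays below it* to the end of the shared
    range.  Returns ``None`` when convergence is never sustained.

    The 0.12 default sits just above the noise floor of replicate-
    averaged stem counts in converged stands (integer stem counts and
    demographic stochasticity keep the CV near 0.10 even after the
    density signature is gone).
    """
    if isinstance(runs, dict):
        runs = list(runs.values())
    if len(runs) < 2:
        raise ValueError("need at least two density scenarios")
    profiles = []
    for df in runs:
        if len(df) == 0:
            raise ValueError("empty summary series")
        v = df["volume_m3_per_ha"].to_numpy(dtype=float)
        s = df["stems_per_ha"].to_numpy(dtype=float)
        profiles.append(_monotone_profile(v, s))
    lo = max(p[0].min() for p in profiles)
    hi = min(p[0].max() for p in profiles)
    if hi <= lo:
        raise ValueError("volume ranges of the scenarios do not overlap")
    grid = np.arange(lo, hi + 1e-9, grid_step)
    stems = np.vstack([np.interp(grid, v, s) for v, s in profiles])
    mean = stems.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, stems.std(axis=0, ddof=0) / mean, np.inf)
    below = cv < cv_threshold
    if not below[-1]:
        return None
    # first index of the terminal all-below suffix
    idx = len(below) - 1
    while idx > 0 and below[idx - 1]:
        idx -= 1
    return float(grid[idx])
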