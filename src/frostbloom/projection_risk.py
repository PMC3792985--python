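"""Bloom projection across the climate ensemble and blossom-frost-risk
statistics.

Blossom frost risk θ for a grid point and a 30-year window is the fraction
of years in which the daily minimum temperature falls to or below a
threshold β (0 °C for frost, 2 °C to allow for radiative cooling of the
blossom below air temperature) between the simulated bloom day and
July 31.  Years without bloom cannot incur blossom frost and are excluded
from the count, while the denominator stays at the window length, so θ is a
multiple of 1/30 for complete windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .climate_prep import TemperatureSeries
from .phenology import (PhenoParams, SEASON_END_DOY, compute_daylength,
                        phenological_years, run_season)

__all__ = [
    "FrostRiskField",
    "project_bloom_ensemble",
    "delta_30yr",
    "last_spring_freeze",
    "frost_risk_theta",
    "delta_theta",
    "unfulfilled_fraction",
    "pmf_kde",
]


@dataclass
class FrostRiskField:
    """Blossom frost risk per grid point for one window and threshold."""

    theta: pd.Series          # indexed by grid_id
    beta: float
    window: tuple[int, int]
    stage: str = "BBCH60"

    def __post_init__(self):
        vals = self.theta.to_numpy(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("theta must lie in [0, 1]")


def project_bloom_ensemble(params: dict[int, PhenoParams | dict[int, PhenoParams]],
                           ensemble: list[TemperatureSeries],
                           model_ids: list[int] | None = None) -> pd.DataFrame:
    """Run every model over every ensemble member.

    ``params`` maps model id → PhenoParams (shared across grid points) or
    model id → {grid_id: PhenoParams}.  Returns the full factorial as a
    tidy frame (run, model, grid_id, year, t1, t2, unfulfilled); seasons
    without bloom are kept with NaN ``t2``, not dropped.
    """
    model_ids = list(params) if model_ids is None else list(model_ids)
    rows = []
    for series in ensemble:
        seasons = [(y, doy, tmean) for y, doy, (tmean,)
                   in phenological_years(series.time, series.tmean)]
        dl = {len(doy): None for _, doy, _ in seasons}
        for model in model_ids:
            p = params[model]
            if isinstance(p, dict):
                if series.grid_id not in p:
                    raise KeyError(
                        f"no parameters for model {model} at grid point "
                        f"{series.grid_id}")
                p = p[series.grid_id]
            for year, doy, tmean in seasons:
                daylength = compute_daylength(series.lat, doy)
                res = run_season(model, p, tmean, doy, daylength)
                rows.append((series.run, model, series.grid_id, year,
                             res.t1, res.t2, res.t1_index, res.t2_index,
                             res.unfulfilled))
    return pd.DataFrame(rows, columns=["run", "model", "grid_id", "year",
                                       "t1", "t2", "t1_index", "t2_index",
                                       "unfulfilled"])


def delta_30yr(values: pd.Series, reference: tuple[int, int],
               target: tuple[int, int], min_coverage: float = 1.0) -> float:
    """Difference of window means, mean(target) − mean(reference).

    ``values`` is indexed by year; NaNs (e.g. years without bloom) are
    ignored inside a window, but each window must retain at least
    ``min_coverage`` of its years.
    """
    out = []
    for y0, y1 in (reference, target):
        w = values.loc[(values.index >= y0) & (values.index <= y1)].dropna()
        need = (y1 - y0 + 1) * min_coverage
        if len(w) < need:
            raise ValueError(f"window {y0}-{y1}: only {len(w)} usable years")
        out.append(w.mean())
    return float(out[1] - out[0])


def last_spring_freeze(tmin: np.ndarray, doy: np.ndarray,
                       threshold: float = 0.0) -> float | None:
    """Last DOY ≤ July 31 with daily minimum ≤ ``threshold`` °C, or None.

    ``tmin``/``doy`` must cover January 1 – July 31 of one calendar year.
    """
    tmin = np.asarray(tmin, float)
    doy = np.asarray(doy)
    spring = doy <= SEASON_END_DOY
    covered = set(np.unique(doy[spring]).tolist())
    if not set(range(1, SEASON_END_DOY + 1)) <= covered:
        raise ValueError("tmin must cover January 1 through July 31")
    hit = spring & (tmin <= threshold)
    if not hit.any():
        return None
    return float(doy[hit].max())


def _spring_tmin_by_year(temps: TemperatureSeries) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    idx = temps.index
    years = idx.year.values
    doys = idx.dayofyear.values
    out = {}
    for y in np.unique(years):
        m = years == y
        out[int(y)] = (temps.tmin[m], doys[m])
    return out


def frost_risk_theta(bloom: pd.Series, temps: TemperatureSeries,
                     beta: float = 0.0,
                     window: tuple[int, int] | None = None,
                     allow_partial: bool = False) -> float:
    """Blossom frost risk θ over a 30-year window.

    A year counts when min(Tmin) over the closed interval [bloom day,
    July 31] is ≤ β; bloom-day frost counts.  No-bloom years never count,
    but remain in the denominator.  Windows shorter than 30 years are
    rejected unless ``allow_partial`` (which then divides by the actual
    window length).
    """
    if temps.tmin is None:
        raise ValueError("frost counting requires daily minimum temperature")
    if window is None:
        window = (int(bloom.index.min()), int(bloom.index.max()))
    y0, y1 = window
    n_years = y1 - y0 + 1
    if n_years != 30 and not allow_partial:
        raise ValueError("theta is defined on 30-year windows "
                         "(pass allow_partial=True to override)")
    by_year = _spring_tmin_by_year(temps)
    count = 0
    for year in range(y0, y1 + 1):
        if year not in bloom.index or np.isnan(bloom.loc[year]):
            continue
        if year not in by_year:
            raise ValueError(f"no temperature data for year {year}")
        t2 = float(bloom.loc[year])
        tmin, doys = by_year[year]
        sel = (doys >= t2) & (doys <= SEASON_END_DOY)
        if sel.any() and np.nanmin(tmin[sel]) <= beta:
            count += 1
    return count / n_years


def delta_theta(reference: FrostRiskField, target: FrostRiskField) -> pd.Series:
    """Change in blossom frost risk Δθ = θ(target) − θ(reference)."""
    if reference.beta != target.beta or reference.stage != target.stage:
        raise ValueError("frost-risk fields differ in beta or stage")
    ref, tgt = reference.theta.align(target.theta, join="inner")
    if len(ref) != len(reference.theta) or len(tgt) != len(target.theta):
        raise ValueError("frost-risk fields cover different grid points")
    return tgt - ref


def unfulfilled_fraction(bloom_results: pd.DataFrame,
                         window: tuple[int, int]) -> float:
    """Share of seasons flagged unfulfilled inside the window."""
    y0, y1 = window
    sel = bloom_results[(bloom_results["year"] >= y0)
                        & (bloom_results["year"] <= y1)]
    if sel.empty:
        raise ValueError(f"no seasons inside window {y0}-{y1}")
    return float(sel["unfulfilled"].mean())


def pmf_kde(delta_values: np.ndarray, bandwidth: float | None = None,
            grid: np.ndarray | None = None,
            bandwidth_floor: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of Δθ values over grid points and runs.

    Returns ``(x, density)`` with the density integrating to one.  For
    (near-)zero-variance input the bandwidth is floored so the result is a
    narrow spike rather than a failure.
    """
    v = np.asarray(delta_values, float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("kernel density estimation needs at least 2 values")
    sd = v.std()
    if sd < bandwidth_floor:
        bw_abs = bandwidth_floor
        kde = None
    else:
        kde = gaussian_kde(v, bw_method=bandwidth)
        bw_abs = float(np.sqrt(kde.covariance[0, 0]))
    if grid is None:
        grid = np.linspace(v.min() - 4 * bw_abs, v.max() + 4 * bw_abs, 512)
    if kde is None:
        dens = np.exp(-0.5 * ((grid - v.mean()) / bw_abs) ** 2)
        dens /= np.trapezoid(dens, grid)
    else:
        dens = kde(grid)
    return grid, dens
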