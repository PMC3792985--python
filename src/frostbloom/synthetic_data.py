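"""Synthetic climate-ensemble and bloom-observation generator.

Emulates the statistical structure the projection chain assumes: an
ensemble of regional-climate realizations of one emission scenario — a
shared seasonal cycle and century-scale warming trend, plus run-specific
bias and autocorrelated daily weather noise — and annual bloom observations
produced by a known phenological model plus rounded observation noise.

Defaults describe a North-German (Lower-Saxony-like) setting: annual-mean
temperature 9 °C, seasonal half-amplitude 8.5 K (January mean near 0.5 °C),
AR(1) daily anomalies with lag-one autocorrelation 0.75 and innovation
standard deviation 2.3 K (stationary sd ≈ 3.5 K), and an A1B-like warming
of 3 K per century.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .climate_prep import TemperatureSeries
from .phenology import (PhenoParams, compute_daylength, phenological_years,
                        run_season)

__all__ = ["ScenarioConfig", "gen_climate_ensemble", "gen_bloom_observations",
           "ensemble_to_frame", "REFERENCE_PARAMS"]


#: Plausible apple-bloom parameter sets per model, used as generator truths
#: and as projection defaults when no calibration is run.  Chill-day
#: requirements and heat sums are in the range typical for *Malus domestica*
#: in a maritime temperate climate.
REFERENCE_PARAMS: dict[int, PhenoParams] = {
    1: PhenoParams(tbf=5.0, fcrit=160.0, t1=1.0),
    2: PhenoParams(tbf=4.0, tbc=8.0, ccrit=55.0, a=320.0, b=-0.010),
    3: PhenoParams(tbf=4.0, tbc=8.0, ccrit=55.0, a=700.0, b=-0.010),
    4: PhenoParams(tbf=4.0, ccrit=30.0, fcrit=190.0),
    5: PhenoParams(tbf=5.0, fcrit=170.0, c=1.0, t1=1.0),
    6: PhenoParams(tbf=4.0, tbc=8.0, ccrit=55.0, a=350.0, b=-0.010, c=1.0),
    7: PhenoParams(tbf=4.0, tbc=8.0, ccrit=55.0, a=750.0, b=-0.010, c=1.0),
}


@dataclass
class ScenarioConfig:
    """Configuration of one synthetic climate scenario.

    ``warming_per_century`` and ``run_bias`` may be scalars (shared) or
    per-run sequences.  When ``run_bias`` is None, run biases are drawn once
    from N(0, run_bias_sd) under the configured seed, emulating the
    systematic offsets of distinct climate models; likewise a per-run
    warming spread of sd ``warming_spread`` is added around the shared
    trend.
    """

    n_runs: int = 5
    n_grid: int = 4
    grid_lats: tuple[float, ...] | None = None
    grid_lons: tuple[float, ...] | None = None
    years: tuple[int, int] = (1951, 2100)
    seasonal_amplitude: float = 8.5
    annual_mean: float = 9.0
    diurnal_range: float = 8.0
    ar1_phi: float = 0.75
    noise_sd: float = 2.3
    tmin_noise_sd: float = 1.0
    warming_per_century: float | tuple[float, ...] = 3.0
    warming_spread: float = 0.4
    run_bias: float | tuple[float, ...] | None = None
    run_bias_sd: float = 0.5
    lat_gradient: float = -0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        if self.grid_lats is None:
            self.grid_lats = tuple(np.linspace(51.5, 53.5, self.n_grid))
        if self.grid_lons is None:
            self.grid_lons = tuple(np.linspace(7.0, 11.0, self.n_grid))
        if len(self.grid_lats) != self.n_grid or len(self.grid_lons) != self.n_grid:
            raise ValueError("grid_lats/grid_lons must have n_grid entries")

    def run_biases(self) -> np.ndarray:
        if self.run_bias is None:
            rng = np.random.default_rng([self.seed, 101])
            return rng.normal(0.0, self.run_bias_sd, self.n_runs)
        return np.broadcast_to(np.asarray(self.run_bias, float),
                               (self.n_runs,)).copy()

    def run_warmings(self) -> np.ndarray:
        if np.ndim(self.warming_per_century) == 0:
            rng = np.random.default_rng([self.seed, 202])
            spread = rng.normal(0.0, self.warming_spread, self.n_runs) \
                if self.warming_spread > 0 else np.zeros(self.n_runs)
            return float(self.warming_per_century) + spread
        return np.broadcast_to(np.asarray(self.warming_per_century, float),
                               (self.n_runs,)).copy()


def _ar1(phi: float, sd: float, n: int,
         generator: np.random.Generator) -> np.ndarray:
    """AR(1) series x_t = phi·x_{t−1} + e_t with innovation sd ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = generator.normal(0.0, sd, n)
    # start from the stationary distribution so early years are not special
    x0 = generator.normal(0.0, sd / np.sqrt(1.0 - phi ** 2)) if phi > 0 else 0.0
    out = lfilter([1.0], [1.0, -phi], eps, zi=[phi * x0])[0]
    return out


def gen_climate_ensemble(config: ScenarioConfig) -> list[TemperatureSeries]:
    """Generate the daily ensemble: one TemperatureSeries per run × grid point.

    Daily mean = annual mean + seasonal sinusoid (coldest mid-January)
    + linear warming trend + run bias + AR(1) noise; daily minimum =
    mean − diurnal_range/2 + independent noise, clipped so Tmin ≤ Tmean.
    Identical seeds give bit-identical output.
    """
    y0, y1 = config.years
    time = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = time.dayofyear.values.astype(float)
    frac_year = (time - time[0]).days.values / 365.25
    seasonal = -config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 15.0) / 365.25)
    biases = config.run_biases()
    warmings = config.run_warmings()
    mean_lat = float(np.mean(config.grid_lats))

    out: list[TemperatureSeries] = []
    for run in range(config.n_runs):
        trend = warmings[run] * frac_year / 100.0
        for g in range(config.n_grid):
            rng = np.random.default_rng([config.seed, run, g])
            lat, lon = config.grid_lats[g], config.grid_lons[g]
            clim = (config.annual_mean + seasonal + trend + biases[run]
                    + config.lat_gradient * (lat - mean_lat))
            tmean = clim + _ar1(config.ar1_phi, config.noise_sd, len(time), rng)
            tmin_noise = (rng.normal(0.0, config.tmin_noise_sd, len(time))
                          if config.tmin_noise_sd > 0 else 0.0)
            tmin = np.minimum(tmean - config.diurnal_range / 2.0 + tmin_noise,
                              tmean)
            tmax = tmean + (tmean - tmin)
            out.append(TemperatureSeries(
                time=time.values, tmean=tmean, tmin=tmin, tmax=tmax,
                grid_id=g, run=run, lat=lat, lon=lon, freq="D"))
    return out


def gen_bloom_observations(true_model: int, true_params: PhenoParams,
                           temps: TemperatureSeries, obs_noise_sd: float,
                           seed: int) -> pd.Series:
    """Annual bloom-DOY observations from a known model plus rounded noise.

    Returns a Series indexed by bloom year; seasons with unfulfilled
    chilling are NaN (the missing-value sentinel — no valid DOY is NaN).
    Raises if the model blooms in no season at all.
    """
    rng = np.random.default_rng([seed, true_model])
    years, values = [], []
    for year, doy, (tmean,) in phenological_years(temps.time, temps.tmean):
        daylength = compute_daylength(temps.lat, doy)
        res = run_season(true_model, true_params, tmean, doy, daylength)
        years.append(year)
        if res.unfulfilled:
            values.append(np.nan)
        else:
            v = res.t2 + (rng.normal(0.0, obs_noise_sd) if obs_noise_sd > 0 else 0.0)
            values.append(float(np.round(v)) if obs_noise_sd > 0 else float(res.t2))
    obs = pd.Series(values, index=pd.Index(years, name="year"), name="bloom_doy")
    if obs.isna().all():
        raise ValueError("model never blooms in any season (all observations missing)")
    return obs


def ensemble_to_frame(ensemble: list[TemperatureSeries]) -> pd.DataFrame:
    """Long-format table (run, grid_id, lat, lon, date, tmean, tmin[, tmax])."""
    return pd.concat([s.to_frame() for s in ensemble], ignore_index=True)
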