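"""Temperature preparation: temporal interpolation, spatial aggregation and
interpolation, and distribution-based quantile-mapping bias correction.

The container type is :class:`TemperatureSeries` — one grid point of one
climate realization, daily (canonical) or hourly.  Bias correction follows
the non-parametric monthly quantile-mapping approach: per calendar month a
monotone transfer function maps simulated quantiles onto observed quantiles,
with both empirical CDFs smoothed by a Gaussian kernel (bandwidth h = 0.1,
expressed as a fraction of the sample standard deviation) and linear tail
extrapolation beyond the calibration range so projected warming outside the
calibrated quantiles is still corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.special import ndtr

from .phenology import compute_daylength

__all__ = [
    "TemperatureSeries",
    "TransferFunction",
    "daily_to_hourly",
    "spatial_floating_mean",
    "krige_field",
    "fit_exponential_variogram",
    "build_transfer_function",
    "build_monthly_transfer_functions",
    "apply_bias_correction",
    "temperature_anomaly",
]

DEFAULT_BANDWIDTH = 0.1


@dataclass
class TemperatureSeries:
    """Air-temperature series at one grid point of one climate realization.

    ``time`` must be strictly increasing with a uniform step; temperatures
    are in °C.  ``tmin``/``tmax`` are daily extremes (absent for hourly
    series).
    """

    time: np.ndarray
    tmean: np.ndarray
    tmin: np.ndarray | None = None
    tmax: np.ndarray | None = None
    grid_id: int = 0
    run: int = 0
    lat: float = 52.5
    lon: float = 9.5
    freq: str = "D"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        self.tmean = np.asarray(self.tmean, dtype=float)
        if self.tmin is not None:
            self.tmin = np.asarray(self.tmin, dtype=float)
        if self.tmax is not None:
            self.tmax = np.asarray(self.tmax, dtype=float)
        steps = np.diff(self.time.astype("int64"))
        if steps.size and (steps <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if steps.size and len(set(steps.tolist())) > 1:
            raise ValueError("time step must be uniform")

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.time)

    def to_frame(self) -> pd.DataFrame:
        d = {"run": self.run, "grid_id": self.grid_id, "lat": self.lat,
             "lon": self.lon, "date": self.index, "tmean": self.tmean}
        if self.tmin is not None:
            d["tmin"] = self.tmin
        if self.tmax is not None:
            d["tmax"] = self.tmax
        return pd.DataFrame(d)

    def copy(self, **changes) -> "TemperatureSeries":
        out = replace(self, **changes)
        return out


# ---------------------------------------------------------------------------
# temporal interpolation

def daily_to_hourly(daily: TemperatureSeries) -> TemperatureSeries:
    """Interpolate a daily Tmin/Tmax/Tmean triple to 24 hourly values per day.

    A single cubic spline is drawn through per-day anchor points — Tmin at
    the sunrise hour (from the astronomical day length at the series
    latitude, rounded to the whole hour so the anchor coincides with an
    output sample) and Tmax at 14:00 — which keeps the curve continuous
    across day boundaries.  Days with a missing value are skipped and
    reported in the result's gap list.
    """
    if daily.tmin is None or daily.tmax is None:
        raise ValueError("daily_to_hourly requires tmin and tmax")
    idx = daily.index
    doy = idx.dayofyear.values.astype(float)
    dl = np.asarray(compute_daylength(daily.lat, doy))
    sunrise = np.clip(np.round(12.0 - dl / 2.0), 1, 11)

    ok = np.isfinite(daily.tmin) & np.isfinite(daily.tmax) & np.isfinite(daily.tmean)
    if not ok.any():
        raise ValueError("no complete daily values to interpolate")

    day_num = np.arange(idx.size, dtype=float)
    anchor_t = np.concatenate([day_num[ok] + sunrise[ok] / 24.0,
                               day_num[ok] + 14.0 / 24.0])
    anchor_v = np.concatenate([daily.tmin[ok], daily.tmax[ok]])
    order = np.argsort(anchor_t)
    spline = CubicSpline(anchor_t[order], anchor_v[order], bc_type="natural")

    hours = np.arange(idx.size * 24, dtype=float) / 24.0
    values = spline(hours)
    # blank out skipped days so gaps stay visible
    if not ok.all():
        bad = np.repeat(~ok, 24)
        values[bad] = np.nan
    time = (idx[0].to_datetime64() +
            (hours * 24).astype("timedelta64[h]").astype("timedelta64[ns]"))
    return TemperatureSeries(time=time, tmean=values, grid_id=daily.grid_id,
                             run=daily.run, lat=daily.lat, lon=daily.lon,
                             freq="h")


# ---------------------------------------------------------------------------
# spatial aggregation / interpolation

def spatial_floating_mean(field: np.ndarray) -> np.ndarray:
    """3×3 floating mean over the two leading (spatial) axes of ``field``.

    Each grid point is replaced by the mean of itself and its up-to-eight
    neighbours; edge points average over the neighbours that exist, and the
    grid resolution is unchanged.  Any trailing axes (e.g. time) are
    preserved.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim < 2:
        raise ValueError("field must have two spatial dimensions")
    padded = np.pad(field, [(1, 1), (1, 1)] + [(0, 0)] * (field.ndim - 2),
                    mode="constant", constant_values=0.0)
    valid = np.pad(np.ones(field.shape[:2]), 1, mode="constant")
    acc = np.zeros_like(field)
    cnt = np.zeros(field.shape[:2])
    for di in (0, 1, 2):
        for dj in (0, 1, 2):
            sl = padded[di:di + field.shape[0], dj:dj + field.shape[1]]
            acc = acc + sl
            cnt = cnt + valid[di:di + field.shape[0], dj:dj + field.shape[1]]
    return acc / cnt.reshape(cnt.shape + (1,) * (field.ndim - 2))


def fit_exponential_variogram(points: np.ndarray, values: np.ndarray,
                              n_bins: int = 12) -> tuple[float, float]:
    """Least-squares fit of an exponential variogram γ(d)=sill·(1−exp(−d/range)).

    Returns ``(sill, range)`` fitted to the binned empirical semivariogram.
    Falls back to a flat variogram for (near-)constant fields.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    iu = np.triu_indices(len(values), k=1)
    lags, gammas = d[iu], 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if np.allclose(gammas, 0.0):
        return 1e-12, max(float(lags.max()), 1.0)
    edges = np.linspace(0, lags.max(), n_bins + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (lags > lo) & (lags <= hi)
        if m.any():
            centers.append(lags[m].mean())
            means.append(gammas[m].mean())
    centers, means = np.array(centers), np.array(means)

    def model(h, sill, rng):
        return sill * (1.0 - np.exp(-h / rng))

    try:
        (sill, rng), _ = curve_fit(
            model, centers, means,
            p0=[max(means.max(), 1e-6), max(centers.mean(), 1e-3)],
            bounds=([1e-12, 1e-6], [np.inf, np.inf]), maxfev=5000)
    except RuntimeError:
        sill, rng = float(means.mean()), float(centers.mean())
    return float(sill), float(rng)


def krige_field(sample_points: np.ndarray, sample_values: np.ndarray,
                targets: np.ndarray,
                variogram: tuple[float, float] | None = None,
                return_weights: bool = False):
    """Ordinary kriging of ``sample_values`` onto ``targets``.

    ``sample_points`` and ``targets`` are (n, 2) coordinate arrays (e.g.
    lat/lon for the small study region, treated as planar).  ``variogram``
    is ``(sill, range)`` of an exponential model; fitted from the samples
    when omitted.  Weights solve the standard ordinary-kriging system with
    the unbiasedness constraint Σw = 1, so the estimator is exact at sample
    locations and reproduces constant fields.
    """
    pts = np.atleast_2d(np.asarray(sample_points, dtype=float))
    vals = np.asarray(sample_values, dtype=float)
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(vals)
    if n < 3:
        raise ValueError("ordinary kriging needs at least 3 samples")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 1:
        raise ValueError("sample locations are degenerate")
    if variogram is None:
        variogram = fit_exponential_variogram(pts, vals)
    sill, rng = variogram
    if sill <= 0 or rng <= 0:
        raise ValueError("variogram sill and range must be positive")

    def gamma(d):
        return sill * (1.0 - np.exp(-d / rng))

    dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma(dmat)
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    d0 = np.linalg.norm(tgt[:, None, :] - pts[None, :, :], axis=-1)
    rhs = np.empty((n + 1, len(tgt)))
    rhs[:n] = gamma(d0).T
    rhs[n] = 1.0
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular ordinary-kriging system: {exc}") from exc
    weights = sol[:n]
    estimate = weights.T @ vals
    if return_weights:
        return estimate, weights.T
    return estimate


# ---------------------------------------------------------------------------
# quantile-mapping bias correction

@dataclass
class TransferFunction:
    """Monotone quantile map from simulated to observed temperature.

    Stored as matched quantile knots ``(x, y)``; application interpolates
    linearly between knots and extrapolates the boundary slopes beyond the
    calibration range.
    """

    month: int
    x: np.ndarray
    y: np.ndarray
    h: float = DEFAULT_BANDWIDTH

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.x) < 0) or np.any(np.diff(self.y) < 0):
            raise ValueError("transfer-function knots must be non-decreasing")

    def __call__(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        out = np.interp(v, self.x, self.y)
        lo_slope = _edge_slope(self.x, self.y, 0)
        hi_slope = _edge_slope(self.x, self.y, -1)
        lo = v < self.x[0]
        hi = v > self.x[-1]
        out = np.where(lo, self.y[0] + (v - self.x[0]) * lo_slope, out)
        out = np.where(hi, self.y[-1] + (v - self.x[-1]) * hi_slope, out)
        return out


def _edge_slope(x: np.ndarray, y: np.ndarray, end: int) -> float:
    if x.size < 2:
        return 1.0
    if end == 0:
        dx, dy = x[1] - x[0], y[1] - y[0]
    else:
        dx, dy = x[-1] - x[-2], y[-1] - y[-2]
    return dy / dx if dx > 0 else 1.0


def _smoothed_quantiles(sample: np.ndarray, probs: np.ndarray,
                        h: float) -> np.ndarray:
    """Quantiles of the Gaussian-kernel-smoothed empirical CDF.

    The bandwidth ``h`` is a fraction of the sample standard deviation.
    """
    sd = sample.std()
    bw = max(h * sd, 1e-9)
    grid = np.linspace(sample.min() - 4 * bw, sample.max() + 4 * bw, 1024)
    cdf = ndtr((grid[:, None] - sample[None, :]) / bw).mean(axis=1)
    cdf, keep = np.unique(cdf, return_index=True)
    return np.interp(probs, cdf, grid[keep])


def build_transfer_function(obs, sim, month: int,
                            h: float = DEFAULT_BANDWIDTH) -> TransferFunction:
    """Build the monthly quantile-mapping transfer function sim → obs.

    Both samples must come from the same calendar month and contain at
    least 30 values.  Degenerate (constant) samples yield an identity map
    shifted by the mean difference.
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    obs, sim = obs[np.isfinite(obs)], sim[np.isfinite(sim)]
    if obs.size < 30 or sim.size < 30:
        raise ValueError("need at least 30 values per sample to calibrate")
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    if obs.std() < 1e-12 or sim.std() < 1e-12:
        shift = obs.mean() - sim.mean()
        x = np.array([sim.mean() - 1.0, sim.mean() + 1.0])
        return TransferFunction(month, x, x + shift, h)
    probs = np.linspace(0.001, 0.999, 257)
    x = _smoothed_quantiles(sim, probs, h)
    y = _smoothed_quantiles(obs, probs, h)
    x, keep = np.unique(x, return_index=True)
    y = np.maximum.accumulate(y[keep])
    return TransferFunction(month, x, y, h)


def build_monthly_transfer_functions(
        obs: TemperatureSeries, sim: TemperatureSeries,
        h: float = DEFAULT_BANDWIDTH,
        variables: tuple[str, ...] = ("tmean", "tmin"),
        calibration_years: tuple[int, int] | None = None,
) -> dict[str, dict[int, TransferFunction]]:
    """Calibrate one transfer function per month and variable.

    Daily mean and daily minimum are mapped separately, since frost counting
    relies on the corrected Tmin distribution.
    """
    out: dict[str, dict[int, TransferFunction]] = {}
    for var in variables:
        o = getattr(obs, var)
        s = getattr(sim, var)
        if o is None or s is None:
            continue
        om, sm = obs.index.month.values, sim.index.month.values
        omask = np.ones(o.shape, bool)
        smask = np.ones(s.shape, bool)
        if calibration_years is not None:
            y0, y1 = calibration_years
            omask = (obs.index.year >= y0) & (obs.index.year <= y1)
            smask = (sim.index.year >= y0) & (sim.index.year <= y1)
        out[var] = {m: build_transfer_function(o[omask & (om == m)],
                                               s[smask & (sm == m)], m, h)
                    for m in range(1, 13)}
    return out


def apply_bias_correction(sim: TemperatureSeries,
                          tfs: dict[str, dict[int, TransferFunction]]
                          ) -> TemperatureSeries:
    """Map each simulated value through its month's transfer function.

    The calendar is unchanged; within a month the mapping is monotone, so
    value ordering is preserved.
    """
    months = sim.index.month.values
    corrected = {}
    for var, monthly in tfs.items():
        raw = getattr(sim, var)
        if raw is None:
            continue
        present = set(np.unique(months).tolist())
        missing = present - set(monthly)
        if missing:
            raise ValueError(f"no transfer function for month(s) {sorted(missing)}")
        out = np.empty_like(raw)
        for m, tf in monthly.items():
            sel = months == m
            out[sel] = tf(raw[sel])
        corrected[var] = out
    return sim.copy(**corrected)


# ---------------------------------------------------------------------------
# anomalies

def temperature_anomaly(series: TemperatureSeries,
                        reference: tuple[int, int] = (1971, 2000),
                        target: tuple[int, int] = (2071, 2100),
                        variable: str = "tmean") -> float:
    """Mean over ``target`` years minus mean over ``reference`` years (K)."""
    values = getattr(series, variable)
    years = series.index.year.values
    out = []
    for y0, y1 in (reference, target):
        window = set(range(y0, y1 + 1))
        covered = set(np.unique(years[(years >= y0) & (years <= y1)]).tolist())
        if covered != window:
            raise ValueError(f"window {y0}-{y1} not fully covered by the series")
        out.append(values[(years >= y0) & (years <= y1)].mean())
    return float(out[1] - out[0])
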