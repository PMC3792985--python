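"""Variance partitioning and time of emergence of the climate-impact signal.

Follows the signal-to-noise framework for projection ensembles: area-mean
annual series per (climate run s, impact model i) are smoothed with a
10-year centered moving average and fitted with a 4th-order polynomial.
The fit residuals pool into a time-constant internal variability V; the
spread of the fits across climate runs gives the climate-model variance
M(t); the error-weighted spread across impact models of the run-mean fits
gives the impact-model variance I(t).  The total variance is

    T(t) = V + M(t) + I(t),

the weighted mean signal is G(t) = Σ_i w_i · mean_s x_{is}(t) with weights
w_i ∝ 1 / model error, and the fractional uncertainty (inverse
signal-to-noise ratio) at confidence multiplier λ is

    F(t) = λ·√T(t) / |G(t)|.

The time of emergence is the first year with F ≤ 1 that stays below the
threshold for at least five consecutive years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SmoothResult",
    "UncertaintyDecomposition",
    "moving_average",
    "smooth_signal",
    "model_weights",
    "partition_variance",
    "weighted_mean_signal",
    "fractional_uncertainty",
    "time_of_emergence",
]

TREND_ORDER = 4
ERROR_FLOOR = 0.1          # days; prevents infinite weight for a zero error
PERSISTENCE_YEARS = 5


def moving_average(values: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered moving average; returns the valid (fully covered) part."""
    values = np.asarray(values, float)
    if values.size < window:
        raise ValueError("series shorter than the averaging window")
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


@dataclass
class SmoothResult:
    """Smoothed-and-fitted ensemble: trend fits per (run, model) plus V."""

    years: np.ndarray                 # years of the valid smoothed range
    fits: pd.DataFrame                # index years, columns (run, model)
    smoothed: pd.DataFrame            # same layout, before the trend fit
    internal_variance: float          # V, pooled residual variance


def smooth_signal(table: pd.DataFrame, window: int = 10,
                  order: int = TREND_ORDER) -> SmoothResult:
    """Smooth and detrend the tidy ensemble table (year, run, model, value).

    Each (run, model) series is averaged with a ``window``-year centered
    moving mean and fitted with an order-``order`` polynomial; residual
    variance pooled over all members gives the internal variability V.
    """
    required = {"year", "run", "model", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(index="year", columns=["run", "model"],
                             values="value")
    if wide.isna().any().any():
        wide = wide.interpolate(limit_direction="both")
    years_full = wide.index.to_numpy(float)
    if years_full.size < 40:
        raise ValueError("need at least 40 annual values to partition")
    half = (window - 1) / 2.0
    years = years_full[window - 1:] - half  # centers of the valid windows
    fits = {}
    smoothed = {}
    residuals = []
    for col in wide.columns:
        sm = moving_average(wide[col].to_numpy(float), window)
        coef = np.polynomial.polynomial.polyfit(years - years.mean(), sm, order)
        fit = np.polynomial.polynomial.polyval(years - years.mean(), coef)
        fits[col] = fit
        smoothed[col] = sm
        residuals.append(sm - fit)
    V = float(np.mean(np.square(np.concatenate(residuals))))
    return SmoothResult(
        years=years,
        fits=pd.DataFrame(fits, index=pd.Index(years, name="year")),
        smoothed=pd.DataFrame(smoothed, index=pd.Index(years, name="year")),
        internal_variance=V,
    )


def model_weights(errors: dict[int, float] | pd.Series,
                  floor: float = ERROR_FLOOR) -> pd.Series:
    """Normalized weights w_i ∝ 1 / max(error_i, floor)."""
    s = pd.Series(errors, dtype=float)
    if (s < 0).any():
        raise ValueError("model errors must be non-negative")
    inv = 1.0 / s.clip(lower=floor)
    return inv / inv.sum()


@dataclass
class UncertaintyDecomposition:
    """Time-resolved variance components and the weighted signal."""

    years: np.ndarray
    V: float                          # internal variability (time-constant)
    M: np.ndarray                     # climate-run variance
    I: np.ndarray                     # impact-model variance
    G: np.ndarray                     # weighted mean signal
    weights: pd.Series

    @property
    def total(self) -> np.ndarray:
        return self.V + self.M + self.I

    @property
    def fractions(self) -> pd.DataFrame:
        T = self.total
        return pd.DataFrame({"frac_internal": self.V / T,
                             "frac_climate": self.M / T,
                             "frac_impact": self.I / T},
                            index=pd.Index(self.years, name="year"))

    def to_frame(self, lambdas: tuple[float, ...] = (0.674, 1.0, 1.645)
                 ) -> pd.DataFrame:
        out = pd.DataFrame({"V": self.V, "M": self.M, "I": self.I,
                            "Ttot": self.total, "G": self.G},
                           index=pd.Index(self.years, name="year"))
        out = out.join(self.fractions)
        for lam in lambdas:
            out[f"F@{lam:g}"] = fractional_uncertainty(self.G, self.total, lam)
        return out


def partition_variance(smooth: SmoothResult,
                       weights: pd.Series | None = None,
                       reference: tuple[int, int] | None = None
                       ) -> UncertaintyDecomposition:
    """Partition total projection variance into V, M(t) and I(t).

    ``smooth.fits`` columns are (run, model).  M(t) is the mean over impact
    models of the population variance across climate runs; I(t) is the
    weighted population variance across impact models of the run-mean fits.
    ``reference`` optionally expresses the signal G(t) as the change from a
    reference-window mean.
    """
    fits = smooth.fits
    runs = fits.columns.get_level_values(0).unique()
    models = fits.columns.get_level_values(1).unique()
    if weights is None:
        weights = pd.Series(1.0 / len(models), index=models)
    weights = weights.reindex(models)
    if weights.isna().any():
        raise ValueError("missing weight for at least one impact model")
    weights = weights / weights.sum()

    if len(runs) < 2 and len(models) < 2:
        import warnings
        warnings.warn("single run and single model: M = I = 0",
                      stacklevel=2)

    arr = np.stack([[fits[(r, m)].to_numpy(float) for m in models]
                    for r in runs])           # (runs, models, time)
    M = arr.var(axis=0, ddof=0).mean(axis=0)  # mean over models of run-variance
    run_mean = arr.mean(axis=0)               # (models, time)
    w = weights.to_numpy(float)[:, None]
    wmean = (w * run_mean).sum(axis=0)
    I = (w * (run_mean - wmean) ** 2).sum(axis=0)
    G = wmean.copy()
    if reference is not None:
        y0, y1 = reference
        sel = (smooth.years >= y0) & (smooth.years <= y1)
        if not sel.any():
            raise ValueError("reference window outside the smoothed range")
        G = G - G[sel].mean()
    return UncertaintyDecomposition(years=smooth.years,
                                    V=smooth.internal_variance,
                                    M=M, I=I, G=G, weights=weights)


def weighted_mean_signal(changes: pd.DataFrame,
                         errors: dict[int, float] | pd.Series) -> np.ndarray:
    """G(t) = Σ_i w_i · mean-over-runs change_i(t), with w ∝ 1/error.

    ``changes`` has columns (run, model) and a year index.
    """
    models = changes.columns.get_level_values(1).unique()
    w = model_weights(pd.Series(errors).reindex(models))
    run_mean = changes.T.groupby(level=1).mean().T  # year × model
    return run_mean.mul(w, axis=1).sum(axis=1).to_numpy(float)


def fractional_uncertainty(G: np.ndarray, total: np.ndarray,
                           lam: float = 1.0) -> np.ndarray:
    """F(t) = λ·√T(t) / |G(t)|; infinite where the signal is zero.

    λ encodes the confidence percentile: 0.674 → 50%, 1 → 68.3%,
    1.645 → 90%.
    """
    G = np.asarray(G, float)
    total = np.asarray(total, float)
    with np.errstate(divide="ignore"):
        return np.where(G == 0.0, np.inf, lam * np.sqrt(total) / np.abs(G))


def time_of_emergence(years: np.ndarray, F: np.ndarray,
                      threshold: float = 1.0,
                      persistence: int = PERSISTENCE_YEARS,
                      start_year: float | None = None
                      ) -> tuple[float | None, float]:
    """First year with F ≤ threshold sustained ≥ ``persistence`` years.

    Returns ``(emergence_year or None, argmin_year)``; the argmin year is
    the minimum of the fractional uncertainty.  ``start_year`` restricts
    the scan to years at or after it (typically the end of the reference
    window, where the change signal is defined).
    """
    years = np.asarray(years, float)
    F = np.asarray(F, float)
    if start_year is not None:
        keep = years >= start_year
        years, F = years[keep], F[keep]
    if years.size == 0:
        return None, np.nan
    below = F <= threshold
    emergence = None
    start = None
    for k, b in enumerate(below):
        if b and start is None:
            start = k
        elif not b:
            if start is not None and k - start >= persistence:
                emergence = float(years[start])
                break
            start = None
    if emergence is None and start is not None:
        # a run reaching the series end counts even if truncated early
        emergence = float(years[start])
    finite = np.isfinite(F)
    argmin_year = float(years[np.argmin(np.where(finite, F, np.inf))])
    return emergence, argmin_year
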