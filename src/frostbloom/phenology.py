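"""Chilling–forcing phenology models for apple bloom.

Seven model variants predict the day of year (DOY) of a bloom phenophase
(BBCH 60 / 65) from daily air temperature over one *phenological year*
(August 1 of the previous calendar year through July 31):

====  ==========================  ========  =======================
 id   type                        daylength  free parameters
====  ==========================  ========  =======================
 1    thermal time                   no      tbf, fcrit           (forcing from Jan 1)
 2    sequential chilling-forcing    no      tbf, tbc, ccrit, a, b
 3    parallel chilling-forcing      no      tbf, tbc, ccrit, a, b
 4    modified Utah                  no      tbf, ccrit, fcrit
 5    thermal time                   yes     tbf, fcrit, c, t1    (forcing start calibrated)
 6    sequential chilling-forcing    yes     tbf, tbc, ccrit, a, b, c
 7    parallel chilling-forcing      yes     tbf, tbc, ccrit, a, b, c
====  ==========================  ========  =======================

Chilling accumulates as *chill days* (rate 1 while 0 °C ≤ T ≤ tbc, the
effective range for apple development) except for model 4, which uses the
stepwise Utah weight table with negative weights at warm temperatures and a
cumulative state floored at zero.  Forcing accumulates growing-degree units
max(T − tbf, 0); the day-length-extended models multiply the forcing rate by
(D / 12 h)**c.  For the sequential and parallel models the forcing
requirement is tied to the chilling state through F* = a·exp(b·Sc), so that
a season with little accumulated chill needs more heat to reach bloom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "PhenoParams",
    "BloomResult",
    "MODEL_SPECS",
    "SEASON_END_DOY",
    "compute_daylength",
    "chill_rate",
    "force_rate",
    "run_season",
    "phenological_years",
]

#: universal end of the bloom season (July 31); later bloom counts as none.
SEASON_END_DOY = 212

#: reference day length (hours) for the day-length forcing factor.
D0_HOURS = 12.0

#: Utah chill-weight bands (upper edges in °C) and weights; the final weight
#: applies above the last edge.  Cumulative Utah chill is floored at zero.
UTAH_EDGES = np.array([1.5, 2.5, 9.2, 12.5, 16.0, 18.0])
UTAH_WEIGHTS = np.array([0.0, 0.5, 1.0, 0.5, 0.0, -0.5, -1.0])

CHILLING_MODELS = frozenset({2, 3, 4, 6, 7})
DAYLENGTH_MODELS = frozenset({5, 6, 7})
SEQUENTIAL_MODELS = frozenset({2, 6})
PARALLEL_MODELS = frozenset({3, 7})


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry describing one phenological model variant."""

    id: int
    name: str
    uses_chilling: bool
    uses_daylength: bool
    param_names: tuple[str, ...]


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "thermal time", False, False, ("tbf", "fcrit")),
    2: ModelSpec(2, "sequential chilling-forcing", True, False,
                 ("tbf", "tbc", "ccrit", "a", "b")),
    3: ModelSpec(3, "parallel chilling-forcing", True, False,
                 ("tbf", "tbc", "ccrit", "a", "b")),
    4: ModelSpec(4, "modified Utah", True, False, ("tbf", "ccrit", "fcrit")),
    5: ModelSpec(5, "thermal time + daylength", False, True,
                 ("tbf", "fcrit", "c", "t1")),
    6: ModelSpec(6, "sequential chilling-forcing + daylength", True, True,
                 ("tbf", "tbc", "ccrit", "a", "b", "c")),
    7: ModelSpec(7, "parallel chilling-forcing + daylength", True, True,
                 ("tbf", "tbc", "ccrit", "a", "b", "c")),
}


@dataclass
class PhenoParams:
    """Calibrated parameter set for one phenological model.

    Parameters not used by a model are left at ``None``.  Base temperatures
    are bounded to the effective range for apple development, 0–10 °C.

    Attributes
    ----------
    tbf : float
        Base temperature for forcing (°C).
    tbc : float, optional
        Base (upper) temperature of the chill-day band (°C), models 2/3/6/7.
    fcrit : float, optional
        Fixed forcing requirement (models 1, 4, 5).
    ccrit : float, optional
        Chilling requirement (chill days, or Utah units for model 4).
    a, b : float, optional
        Exponential link F* = a·exp(b·Sc) between forcing requirement and
        chilling state (sequential/parallel models); b is typically < 0.
    c : float, optional
        Day-length exponent, models 5–7; c ≥ 0.
    t0 : int
        Chilling start as phenological-year day index (0 = August 1).
    t1 : float, optional
        Forcing start DOY.  Fixed at 1 (January 1) for model 1; calibrated
        for model 5 (DOY ≥ 213 means the preceding autumn).
    """

    tbf: float = 0.0
    tbc: float | None = None
    fcrit: float | None = None
    ccrit: float | None = None
    a: float | None = None
    b: float | None = None
    c: float | None = None
    t0: int = 0
    t1: float | None = None

    def validate(self, model: int) -> None:
        spec = _spec(model)
        for name in spec.param_names:
            if getattr(self, name) is None:
                raise ValueError(
                    f"model {model} ({spec.name}) requires parameter {name!r}")
        if not (0.0 <= self.tbf <= 10.0):
            raise ValueError("tbf must lie in the calibration range [0, 10] degC")
        if self.tbc is not None and not (0.0 <= self.tbc <= 10.0):
            raise ValueError("tbc must lie in the calibration range [0, 10] degC")
        if self.c is not None and self.c < 0:
            raise ValueError("day-length exponent c must be >= 0")
        if "fcrit" in spec.param_names and self.fcrit is not None and self.fcrit <= 0:
            raise ValueError("fcrit must be positive")

    def copy(self, **changes) -> "PhenoParams":
        return replace(self, **changes)


@dataclass
class BloomResult:
    """Outcome of one phenological season.

    ``t1`` is the chilling-completion / forcing-start day, ``t2`` the bloom
    day, both as calendar DOY; the ``*_index`` twins count days from
    August 1 and give the phenological-year ordering.  ``unfulfilled`` marks
    seasons in which chilling was never satisfied or bloom was not reached
    by July 31.
    """

    t1: float | None
    t2: float | None
    unfulfilled: bool
    t1_index: int | None = None
    t2_index: int | None = None


def _spec(model: int) -> ModelSpec:
    try:
        return MODEL_SPECS[model]
    except KeyError:
        raise ValueError(f"unknown phenological model id {model!r}") from None


# ---------------------------------------------------------------------------
# day length

def compute_daylength(latitude: float, doy) -> np.ndarray | float:
    """Astronomical day length (hours) at ``latitude`` for day(s) of year.

    Uses the solar declination δ = −23.44°·cos(2π(doy+10)/365.25) and the
    sunset hour angle cos(H0) = −tan(φ)tan(δ); day length is 24·H0/π.
    Latitudes poleward of the polar circles are rejected (the study region
    lies near 51–54°N, well equatorward).
    """
    if abs(latitude) >= 66.6:
        raise ValueError("polar latitudes (|lat| >= 66.6 deg) are not supported")
    doy = np.asarray(doy, dtype=float)
    decl = -np.deg2rad(23.44) * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25)
    cos_h0 = -np.tan(np.deg2rad(latitude)) * np.tan(decl)
    h0 = np.arccos(np.clip(cos_h0, -1.0, 1.0))
    out = 24.0 * h0 / np.pi
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# rates

def chill_rate(model: int, T, params: PhenoParams) -> np.ndarray | float:
    """Rate of chilling Rc at temperature(s) ``T``.

    Models 2/3/6/7 use the chill-day form: one unit per day with
    0 °C ≤ T ≤ tbc, zero otherwise.  Model 4 uses the stepwise Utah weight
    table (including negative weights at warm temperatures).  Models 1 and 5
    have no chilling phase and are rejected.
    """
    spec = _spec(model)
    if not spec.uses_chilling:
        raise ValueError(f"model {model} ({spec.name}) has no chilling phase")
    T = np.asarray(T, dtype=float)
    if model == 4:
        idx = np.searchsorted(UTAH_EDGES, T, side="right")
        out = UTAH_WEIGHTS[idx]
    else:
        out = ((T >= 0.0) & (T <= params.tbc)).astype(float)
    return out if out.ndim else float(out)


def force_rate(model: int, T, D=None, params: PhenoParams | None = None
               ) -> np.ndarray | float:
    """Rate of forcing Rf = max(T − tbf, 0), times (D/12 h)**c for models 5–7."""
    spec = _spec(model)
    if params is None:
        raise ValueError("params is required")
    T = np.asarray(T, dtype=float)
    out = np.maximum(T - params.tbf, 0.0)
    if spec.uses_daylength:
        if D is None:
            raise ValueError(f"model {model} requires day length D")
        out = out * (np.asarray(D, dtype=float) / D0_HOURS) ** params.c
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# season execution

def _floored_cumsum(rates: np.ndarray) -> np.ndarray:
    """Cumulative sum reflected at zero: S_t = max(0, S_{t-1} + r_t)."""
    c = np.cumsum(rates)
    return c - np.minimum(0.0, np.minimum.accumulate(c))

def _first_at_least(cum: np.ndarray, threshold: float) -> int | None:
    hit = cum >= threshold
    if not hit.any():
        return None
    return int(np.argmax(hit))


def _forcing_start_index(params: PhenoParams, doy: np.ndarray) -> int | None:
    """Translate the forcing-start DOY t1 into a phenological-year index."""
    t1 = float(params.t1)
    if t1 >= 213.0:          # preceding autumn: Aug 1 (DOY 213) is index 0
        return int(round(t1)) - 213
    spring = np.nonzero(doy == int(round(t1)))[0]
    return int(spring[-1]) if spring.size else None


def run_season(model: int, params: PhenoParams, tmean: np.ndarray,
               doy: np.ndarray, daylength: np.ndarray | None = None,
               return_trace: bool = False):
    """Run one phenological year (Aug 1 → Jul 31) and return a BloomResult.

    Parameters
    ----------
    tmean, doy : arrays of daily mean temperature (°C) and calendar DOY,
        aligned and covering the full phenological year in order.
    daylength : array of day length (hours), required for models 5–7.
    return_trace : if True, also return a dict with the chilling and
        forcing state series (for step-by-step verification).
    """
    spec = _spec(model)
    params.validate(model)
    tmean = np.asarray(tmean, dtype=float)
    doy = np.asarray(doy)
    if tmean.shape != doy.shape:
        raise ValueError("tmean and doy must be aligned")
    if tmean.size < 365:
        raise ValueError("a phenological season must cover a full year")
    if spec.uses_daylength:
        if daylength is None:
            raise ValueError(f"model {model} requires a day-length series")
        daylength = np.asarray(daylength, dtype=float)

    n = tmean.size
    rf = force_rate(model, tmean, daylength, params)
    trace: dict[str, np.ndarray] = {}

    t1_idx: int | None = None
    t2_idx: int | None = None

    if model in (1, 5):
        start = _forcing_start_index(params, doy) if model == 5 else \
            int(np.nonzero(doy == 1)[0][-1])
        if start is None or start >= n:
            start = None
        if start is not None:
            sf = np.cumsum(rf[start:])
            rel = _first_at_least(sf, params.fcrit)
            t1_idx = start
            t2_idx = None if rel is None else start + rel
            trace["sf"] = sf
    else:
        rc = np.asarray(chill_rate(model, tmean, params), dtype=float).copy()
        if params.t0 > 0:
            rc[:params.t0] = 0.0
        sc = _floored_cumsum(rc) if model == 4 else np.cumsum(rc)
        trace["sc"] = sc
        if model in SEQUENTIAL_MODELS or model == 4:
            t1_idx = _first_at_least(sc, params.ccrit)
            if t1_idx is not None and t1_idx + 1 < n:
                fcrit = params.fcrit if model == 4 else \
                    params.a * np.exp(params.b * sc[t1_idx])
                sf = np.cumsum(rf[t1_idx + 1:])
                rel = _first_at_least(sf, fcrit)
                t2_idx = None if rel is None else t1_idx + 1 + rel
                trace["sf"] = sf
                trace["fcrit_effective"] = np.asarray(fcrit)
        else:  # parallel: chilling and gated forcing accumulate concurrently
            start = min(params.t0, n - 1)
            gate = np.clip(sc / params.ccrit, 0.0, 1.0)
            eff = gate * rf
            eff[:start] = 0.0
            sf = np.cumsum(eff)
            threshold = params.a * np.exp(params.b * sc)
            hit = sf >= threshold
            t2_idx = int(np.argmax(hit)) if hit.any() else None
            t1_idx = _first_at_least(sc, params.ccrit)
            trace["sf"] = sf
            trace["fcrit_effective"] = threshold

    unfulfilled = t2_idx is None
    result = BloomResult(
        t1=None if t1_idx is None else float(doy[t1_idx]),
        t2=None if t2_idx is None else float(doy[t2_idx]),
        unfulfilled=unfulfilled,
        t1_index=t1_idx,
        t2_index=t2_idx,
    )
    return (result, trace) if return_trace else result


# ---------------------------------------------------------------------------
# calendar helper

def phenological_years(time: np.ndarray, *series: np.ndarray
                       ) -> Iterator[tuple[int, np.ndarray, tuple[np.ndarray, ...]]]:
    """Split daily series into phenological years (Aug 1 → Jul 31).

    Yields ``(bloom_year, doy, per_series_slices)`` for every complete
    season.  ``bloom_year`` is the calendar year containing the spring.
    """
    t = pd.DatetimeIndex(time)
    years = t.year.values
    months = t.month.values
    pheno_year = np.where(months >= 8, years + 1, years)
    doy_all = t.dayofyear.values
    for y in np.unique(pheno_year):
        mask = pheno_year == y
        if mask.sum() < 365:
            continue
        idx = np.nonzero(mask)[0]
        yield int(y), doy_all[idx], tuple(s[idx] for s in series)
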