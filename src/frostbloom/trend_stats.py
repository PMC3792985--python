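"""Trend tests for single projection time series.

Continuous series (bloom day, chilling completion, last spring freeze) use
the Mann–Kendall test with tie-corrected variance and continuity
correction.  Event series (years with blossom frost) use the Cox–Lewis
test: under a homogeneous (no-trend) occurrence process the event times
are uniform over the observation period, so the standardized mean event
time

    U = (t̄ − L/2) / (L / √(12·n))

is asymptotically standard normal.  Both tests report two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["TrendTestResult", "mann_kendall", "cox_lewis"]


@dataclass
class TrendTestResult:
    statistic: float          # S for Mann–Kendall, U for Cox–Lewis
    z: float                  # normalized test statistic
    p_value: float            # two-sided
    n: int


def mann_kendall(series: np.ndarray) -> TrendTestResult:
    """Mann–Kendall trend test of an annual series (ties allowed, n ≥ 4).

    S = Σ_{i<j} sign(x_j − x_i); Var(S) uses the tie correction
    Σ t(t−1)(2t+5)/18, and Z applies the ±1 continuity correction.
    """
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise ValueError("Mann-Kendall test needs at least 4 values")
    sgn = np.sign(x[None, :] - x[:, None])
    S = float(np.triu(sgn, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:          # all values tied
        return TrendTestResult(statistic=S, z=0.0, p_value=1.0, n=n)
    if S > 0:
        z = (S - 1) / np.sqrt(var)
    elif S < 0:
        z = (S + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * norm.sf(abs(z))
    return TrendTestResult(statistic=S, z=float(z), p_value=float(min(p, 1.0)),
                           n=n)


def cox_lewis(event_years, period: tuple[float, float]) -> TrendTestResult:
    """Cox–Lewis test for a trend in event occurrence times.

    ``event_years`` are the calendar years with an event inside ``period``
    (start, end); each event time is taken at the year midpoint relative to
    the period start.  Zero events yield the no-trend result (U = 0, p = 1)
    with a warning.
    """
    start, end = period
    L = float(end) - float(start) + 1.0
    if L <= 0:
        raise ValueError("empty observation period")
    events = np.asarray(event_years, float)
    events = events[(events >= start) & (events <= end)]
    n = events.size
    if n == 0:
        import warnings
        warnings.warn("no events in the period: reporting no trend",
                      stacklevel=2)
        return TrendTestResult(statistic=0.0, z=0.0, p_value=1.0, n=0)
    t = events - float(start) + 0.5
    U = (t.mean() - L / 2.0) / (L / np.sqrt(12.0 * n))
    p = 2.0 * norm.sf(abs(U))
    return TrendTestResult(statistic=float(U), z=float(U),
                           p_value=float(min(p, 1.0)), n=n)
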