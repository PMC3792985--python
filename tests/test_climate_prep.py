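"""Tests for temporal interpolation, spatial operators and bias correction."""

import numpy as np
import pandas as pd
import pytest

from frostbloom.climate_prep import (TemperatureSeries, TransferFunction,
                                     apply_bias_correction,
                                     build_monthly_transfer_functions,
                                     build_transfer_function, daily_to_hourly,
                                     fit_exponential_variogram, krige_field,
                                     spatial_floating_mean,
                                     temperature_anomaly)


def _daily_series(tmin, tmax, tmean, start="2000-03-01", lat=52.5):
    n = len(tmean)
    time = pd.date_range(start, periods=n, freq="D").values
    return TemperatureSeries(time=time, tmean=np.asarray(tmean, float),
                             tmin=np.asarray(tmin, float),
                             tmax=np.asarray(tmax, float), lat=lat)


# ---------------------------------------------------------------------------
# daily -> hourly

def test_constant_day_interpolates_flat():
    s = _daily_series([5.0] * 10, [5.0] * 10, [5.0] * 10)
    hourly = daily_to_hourly(s)
    assert hourly.tmean.size == 240
    assert np.allclose(hourly.tmean, 5.0, atol=1e-9)


def test_round_trip_on_synthetic_diurnal_cycle():
    """Aggregate an asymmetric diurnal cycle to daily min/max/mean, then
    re-interpolate; the reconstruction error stays below 0.6 K."""
    n_days = 30
    hours = np.arange(n_days * 24) % 24
    # asymmetric diurnal curve: minimum at sunrise (6 h), maximum at 14 h
    rising = (hours >= 6) & (hours <= 14)
    truth = np.where(
        rising, 10.0 - 5.0 * np.cos(np.pi * (hours - 6.0) / 8.0),
        10.0 + 5.0 * np.cos(np.pi * ((hours - 14.0) % 24) / 16.0))
    daily = truth.reshape(n_days, 24)
    s = _daily_series(daily.min(axis=1), daily.max(axis=1),
                      daily.mean(axis=1))
    hourly = daily_to_hourly(s)
    # first/last day feel the natural-spline boundary; judge the interior
    mae = np.abs(hourly.tmean[48:-48] - truth[48:-48]).mean()
    assert mae < 0.6


def test_round_trip_daily_mean_close_on_smooth_input():
    n_days = 30
    hours = np.arange(n_days * 24) % 24
    truth = 8.0 + 4.0 * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
    daily = truth.reshape(n_days, 24)
    s = _daily_series(daily.min(axis=1), daily.max(axis=1),
                      daily.mean(axis=1))
    hourly = daily_to_hourly(s)
    recon = hourly.tmean.reshape(n_days, 24).mean(axis=1)
    assert np.abs(recon[2:-2] - daily.mean(axis=1)[2:-2]).max() < 0.1


def test_subzero_tmin_reaches_hourly_values():
    s = _daily_series([-3.0] * 5, [8.0] * 5, [2.0] * 5)
    hourly = daily_to_hourly(s)
    for d in range(1, 4):
        assert hourly.tmean[d * 24:(d + 1) * 24].min() <= 0.0


def test_missing_day_is_skipped_and_flagged():
    tmin = [1.0, np.nan, 1.0, 1.0, 1.0]
    s = _daily_series(tmin, [9.0] * 5, [5.0] * 5)
    hourly = daily_to_hourly(s)
    assert np.isnan(hourly.tmean[24:48]).all()
    assert np.isfinite(hourly.tmean[:24]).all()


# ---------------------------------------------------------------------------
# spatial floating mean

def test_floating_mean_constant_field_unchanged():
    f = np.full((5, 7), 3.3)
    assert np.allclose(spatial_floating_mean(f), 3.3)


def test_floating_mean_single_interior_spike():
    f = np.zeros((5, 5))
    f[2, 2] = 9.0
    assert spatial_floating_mean(f)[2, 2] == pytest.approx(1.0)


def test_floating_mean_matches_brute_force_loop():
    rng = np.random.default_rng(0)
    f = rng.normal(size=(6, 8))
    got = spatial_floating_mean(f)
    for i in range(6):
        for j in range(8):
            block = f[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            assert got[i, j] == pytest.approx(block.mean())


def test_floating_mean_preserves_time_axis():
    rng = np.random.default_rng(1)
    f = rng.normal(size=(4, 4, 10))
    got = spatial_floating_mean(f)
    assert got.shape == f.shape
    assert np.allclose(got[..., 3],
                       spatial_floating_mean(f[..., 3]))


# ---------------------------------------------------------------------------
# kriging

def _ok_system_oracle(pts, vals, target, sill, rng_):
    """Direct solve of the ordinary-kriging equations."""
    n = len(vals)
    gamma = lambda d: sill * (1 - np.exp(-d / rng_))
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = gamma(np.linalg.norm(pts[i] - pts[j]))
    A[n, :n] = A[:n, n] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = gamma(np.linalg.norm(target - pts[i]))
    b[n] = 1.0
    w = np.linalg.solve(A, b)[:n]
    return w @ vals


def test_kriging_exact_at_sample_locations():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 10, (8, 2))
    vals = rng.normal(10, 3, 8)
    est = krige_field(pts, vals, pts, variogram=(2.0, 3.0))
    assert np.allclose(est, vals, atol=1e-8)


def test_kriging_reproduces_constant_field():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 10, (6, 2))
    est = krige_field(pts, np.full(6, 7.0), rng.uniform(0, 10, (5, 2)),
                      variogram=(1.0, 2.0))
    assert np.allclose(est, 7.0, atol=1e-10)


def test_kriging_matches_linear_system_oracle():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 10, (10, 2))
    vals = rng.normal(5, 2, 10)
    targets = rng.uniform(0, 10, (5, 2))
    est = krige_field(pts, vals, targets, variogram=(2.5, 4.0))
    for k in range(5):
        assert est[k] == pytest.approx(
            _ok_system_oracle(pts, vals, targets[k], 2.5, 4.0), abs=1e-8)


def test_kriging_weights_sum_to_one():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 10, (7, 2))
    vals = rng.normal(size=7)
    _, w = krige_field(pts, vals, rng.uniform(0, 10, (4, 2)),
                       variogram=(1.0, 3.0), return_weights=True)
    assert np.allclose(w.sum(axis=1), 1.0, atol=1e-10)


def test_kriging_rejects_degenerate_input():
    with pytest.raises(ValueError):
        krige_field(np.zeros((2, 2)), [1.0, 2.0], np.zeros((1, 2)))
    pts = np.repeat([[1.0, 1.0]], 4, axis=0)
    with pytest.raises(ValueError):
        krige_field(pts, [1, 2, 3, 4], np.zeros((1, 2)), variogram=(1.0, 1.0))


def test_variogram_fit_recovers_flat_field():
    rng = np.random.default_rng(6)
    pts = rng.uniform(0, 5, (12, 2))
    sill, rg = fit_exponential_variogram(pts, np.full(12, 2.0))
    assert sill <= 1e-10


# ---------------------------------------------------------------------------
# quantile mapping

def test_transfer_identity_for_identical_distributions():
    rng = np.random.default_rng(7)
    obs = rng.normal(5, 3, 10_000)
    sim = rng.normal(5, 3, 10_000)
    tf = build_transfer_function(obs, sim, month=4)
    probe = np.linspace(np.quantile(sim, 0.01), np.quantile(sim, 0.99), 200)
    assert np.abs(tf(probe) - probe).max() < 0.2


def test_transfer_recovers_location_shift():
    rng = np.random.default_rng(8)
    obs = rng.normal(5, 3, 8000)
    sim = obs + 2.0
    tf = build_transfer_function(obs, sim, month=1)
    probe = np.linspace(np.quantile(sim, 0.05), np.quantile(sim, 0.95), 100)
    assert np.allclose(tf(probe), probe - 2.0, atol=0.15)


def test_transfer_function_is_monotone():
    rng = np.random.default_rng(9)
    for _ in range(5):
        obs = rng.gamma(2.0, 2.0, 500)
        sim = rng.normal(3, 2, 500)
        tf = build_transfer_function(obs, sim, month=6)
        probe = np.linspace(sim.min() - 5, sim.max() + 5, 500)
        assert np.all(np.diff(tf(probe)) >= -1e-12)


def test_degenerate_constant_distribution_gives_shift_map():
    obs = np.full(50, 4.0)
    sim = np.full(50, 1.0)
    tf = build_transfer_function(obs, sim, month=2)
    assert tf(np.array([1.0]))[0] == pytest.approx(4.0)


def test_transfer_requires_enough_data():
    with pytest.raises(ValueError):
        build_transfer_function(np.arange(10), np.arange(40), month=3)


def test_bias_correction_identity_and_order(baseline_series):
    s = baseline_series
    ident = {m: TransferFunction(m, np.array([-40.0, 45.0]),
                                 np.array([-40.0, 45.0]))
             for m in range(1, 13)}
    out = apply_bias_correction(s, {"tmean": ident})
    assert np.allclose(out.tmean, s.tmean)
    # monotone maps preserve value ordering within a month
    tfs = build_monthly_transfer_functions(s, s.copy(tmean=s.tmean - 2.0),
                                           variables=("tmean",))
    corr = apply_bias_correction(s.copy(tmean=s.tmean - 2.0), tfs)
    jan = s.index.month == 1
    orig_order = np.argsort(s.tmean[jan])
    assert np.array_equal(np.argsort(corr.tmean[jan]), orig_order)


def test_bias_correction_missing_month_errors(baseline_series):
    tfs = {"tmean": {1: TransferFunction(1, np.array([-30.0, 40.0]),
                                         np.array([-30.0, 40.0]))}}
    with pytest.raises(ValueError):
        apply_bias_correction(baseline_series, tfs)


# ---------------------------------------------------------------------------
# anomalies

def test_anomaly_zero_for_identical_windows(baseline_series):
    s = baseline_series
    assert temperature_anomaly(s, (1971, 2000), (1971, 2000)) == 0.0


def test_anomaly_matches_linear_trend(warming_series):
    # +3 K/century, window centers 100 years apart
    dt = temperature_anomaly(warming_series, (1971, 2000), (2071, 2100))
    assert dt == pytest.approx(3.0, abs=0.35)


def test_anomaly_incomplete_window_errors(baseline_series):
    with pytest.raises(ValueError):
        temperature_anomaly(baseline_series, (1971, 2000), (1990, 2019))


def test_series_validation():
    t = pd.date_range("2000-01-01", periods=5, freq="D").values
    with pytest.raises(ValueError):
        TemperatureSeries(time=t[[0, 2, 1, 3, 4]], tmean=np.zeros(5))
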