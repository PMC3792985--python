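"""Unit and property tests for the seven chilling-forcing models."""

import numpy as np
import pandas as pd
import pytest

from frostbloom.phenology import (MODEL_SPECS, PhenoParams, chill_rate,
                                  compute_daylength, force_rate,
                                  phenological_years, run_season)
from frostbloom.synthetic_data import REFERENCE_PARAMS

from conftest import constant_season


# ---------------------------------------------------------------------------
# day length

def brute_force_daylength(lat, doy, n=20000):
    """Fraction of the day with geometric solar elevation > 0, in hours."""
    hours = np.linspace(0.0, 24.0, n, endpoint=False)
    decl = -np.deg2rad(23.44) * np.cos(2 * np.pi * (doy + 10) / 365.25)
    H = np.deg2rad((hours - 12.0) * 15.0)
    lat_r = np.deg2rad(lat)
    sin_elev = (np.sin(lat_r) * np.sin(decl)
                + np.cos(lat_r) * np.cos(decl) * np.cos(H))
    return 24.0 * (sin_elev > 0).mean()


def test_daylength_equator_is_12h_all_year():
    dl = compute_daylength(0.0, np.arange(1, 367))
    assert np.all(np.abs(dl - 12.0) < 0.2)


@pytest.mark.parametrize("lat", [-45.0, 0.0, 35.0, 52.5, 60.0])
def test_daylength_equinox_near_12h(lat):
    assert compute_daylength(lat, 80) == pytest.approx(12.0, abs=0.3)


@pytest.mark.parametrize("lat,doy", [(52.5, 172), (52.5, 355), (35.0, 100),
                                     (60.0, 250)])
def test_daylength_matches_solar_elevation_integration(lat, doy):
    assert compute_daylength(lat, doy) == pytest.approx(
        brute_force_daylength(lat, doy), abs=0.2)


def test_daylength_rejects_polar_latitudes():
    with pytest.raises(ValueError):
        compute_daylength(70.0, 172)


# ---------------------------------------------------------------------------
# rates

def test_chill_day_band_is_inclusive():
    p = PhenoParams(tbf=4.0, tbc=6.0, ccrit=50.0, a=300.0, b=-0.01)
    assert chill_rate(2, 6.0, p) == 1.0
    assert chill_rate(2, 6.1, p) == 0.0
    assert chill_rate(2, 0.0, p) == 1.0
    assert chill_rate(2, -0.1, p) == 0.0


def test_chill_rate_rejected_for_pure_forcing_models():
    p = PhenoParams(tbf=4.0, fcrit=100.0, t1=1.0)
    for model in (1, 5):
        with pytest.raises(ValueError):
            chill_rate(model, 3.0, p)


def test_utah_weights_sum_matches_hand_computation():
    p = PhenoParams(tbf=4.0, ccrit=30.0, fcrit=190.0)
    temps = np.array([-2.0, 1.0, 2.0, 5.0, 9.0, 10.0, 13.0, 17.0, 20.0])
    # hand-assigned weights per band: <1.5:0, [1.5,2.5):0.5, [2.5,9.2):1,
    # [9.2,12.5):0.5, [12.5,16):0, [16,18):-0.5, >=18:-1
    expected = [0.0, 0.0, 0.5, 1.0, 1.0, 0.5, 0.0, -0.5, -1.0]
    assert np.allclose(chill_rate(4, temps, p), expected)
    assert chill_rate(4, temps, p).sum() == pytest.approx(sum(expected))


def test_force_rate_daylength_factor():
    p6 = REFERENCE_PARAMS[6].copy(c=1.0, tbf=4.0)
    # c=1, T = tbf+2, D=18 -> rate = 2 * 1.5
    assert force_rate(6, 6.0, 18.0, p6) == pytest.approx(3.0)
    # D = 12h reference -> factor exactly 1
    assert force_rate(6, 6.0, 12.0, p6) == pytest.approx(2.0)
    # c = 0 collapses to the base rate for any day length
    p0 = p6.copy(c=0.0)
    p2 = REFERENCE_PARAMS[2].copy(tbf=4.0)
    for D in (8.0, 12.0, 16.0):
        assert force_rate(6, 6.0, D, p0) == force_rate(2, 6.0, None, p2)


# ---------------------------------------------------------------------------
# season execution

def test_thermal_time_constant_forcing_arithmetic():
    # constant T = tbf + 5 and Fcrit = 50 -> bloom 10 days after Jan 1
    tmean, doy = constant_season(10.0)
    p = PhenoParams(tbf=5.0, fcrit=50.0, t1=1.0)
    res = run_season(1, p, tmean, doy)
    assert res.t2 == 10.0  # Jan 1 accumulates the first 5 units
    assert not res.unfulfilled


def test_sequential_never_chills_in_warm_winter():
    tmean, doy = constant_season(20.0)
    p = REFERENCE_PARAMS[2]
    res = run_season(2, p, tmean, doy)
    assert res.unfulfilled and res.t2 is None


def test_sequential_matches_day_by_day_trace():
    """Hand-crafted 90-day chill block then constant warm spring."""
    tmean, doy = constant_season(20.0)
    tmean = tmean.copy()
    tmean[30:120] = 3.0     # 90 days inside the chill band
    tmean[120:] = 12.0      # constant forcing at 12 - tbf = 8 units/day
    p = PhenoParams(tbf=4.0, tbc=6.0, ccrit=60.0, a=300.0, b=-0.01)
    res, trace = run_season(2, p, tmean, doy, return_trace=True)
    # chilling: day 30 is the first chill day; 60 days later -> index 89
    assert res.t1_index == 89
    # forcing rate is zero until the warm spell at index 120 (3 degC < tbf),
    # then 8 units/day against the requirement a*exp(b*60)
    fcrit = 300.0 * np.exp(-0.01 * 60.0)
    days_needed = int(np.ceil(fcrit / 8.0))
    assert res.t2_index == 120 + days_needed - 1
    assert trace["sc"][89] == 60.0


def test_model_nesting_exact():
    """Models 5/6/7 at c=0 reproduce models 1/2/3 bloom dates exactly."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        tmean, doy = constant_season(0.0)
        seasonal = 10.0 - 9.0 * np.cos(
            2 * np.pi * (np.arange(tmean.size) - 170) / 365.25)
        tm = seasonal + rng.normal(0, 3, tmean.size)
        dl = compute_daylength(52.5, doy)
        pairs = [(5, 1, REFERENCE_PARAMS[1].copy(c=0.0)),
                 (6, 2, REFERENCE_PARAMS[2].copy(c=0.0)),
                 (7, 3, REFERENCE_PARAMS[3].copy(c=0.0))]
        for ext, base, params in pairs:
            r_ext = run_season(ext, params, tm, doy, dl)
            r_base = run_season(base, params, tm, doy, dl)
            assert r_ext.t2 == r_base.t2
            assert r_ext.unfulfilled == r_base.unfulfilled


def test_warming_forcing_phase_never_delays_bloom():
    """With chilling satisfied, uniform spring warming is monotone."""
    rng = np.random.default_rng(3)
    tmean, doy = constant_season(0.0)
    base = 9.0 - 9.0 * np.cos(2 * np.pi * (np.arange(tmean.size) - 170) / 365.25)
    dl = compute_daylength(52.5, doy)
    jan1 = np.nonzero(doy == 1)[0][-1]
    for model in range(1, 8):
        tm = base + rng.normal(0, 2, base.size)
        warmed = tm.copy()
        warmed[jan1:] += 2.0   # warm only the spring (forcing phase)
        p = REFERENCE_PARAMS[model]
        r0 = run_season(model, p, tm, doy, dl)
        r1 = run_season(model, p, warmed, doy, dl)
        if not r0.unfulfilled and not r1.unfulfilled \
                and r0.t2_index >= jan1 and r1.t2_index >= jan1:
            assert r1.t2_index <= r0.t2_index


def test_less_winter_chill_weakly_delays_dormancy_release():
    tmean, doy = constant_season(0.0)
    base = 9.0 - 9.0 * np.cos(2 * np.pi * (np.arange(tmean.size) - 170) / 365.25)
    dl = compute_daylength(52.5, doy)
    warmed = base + 2.0      # uniformly warmer winter -> less chill exposure
    for model in (2, 3, 4, 6, 7):
        p = REFERENCE_PARAMS[model]
        r0 = run_season(model, p, base, doy, dl)
        r1 = run_season(model, p, warmed, doy, dl)
        if r0.t1_index is not None and r1.t1_index is not None:
            assert r1.t1_index >= r0.t1_index


def test_t1_precedes_t2_in_phenological_ordering():
    tmean, doy = constant_season(0.0)
    rng = np.random.default_rng(9)
    base = 9.0 - 9.0 * np.cos(2 * np.pi * (np.arange(tmean.size) - 170) / 365.25)
    dl = compute_daylength(52.5, doy)
    for model in range(1, 8):
        tm = base + rng.normal(0, 3, base.size)
        res = run_season(model, REFERENCE_PARAMS[model], tm, doy, dl)
        if res.t1_index is not None and res.t2_index is not None:
            assert res.t1_index < res.t2_index


def test_params_validation_catches_missing_and_out_of_bounds():
    with pytest.raises(ValueError):
        run_season(2, PhenoParams(tbf=4.0), *constant_season(5.0))
    with pytest.raises(ValueError):
        PhenoParams(tbf=12.0, fcrit=100.0, t1=1.0).validate(1)
    with pytest.raises(ValueError):
        run_season(9, REFERENCE_PARAMS[2], *constant_season(5.0))


def test_phenological_years_splits_aug_to_jul():
    time = pd.date_range("1999-01-01", "2002-12-31", freq="D").values
    vals = np.arange(time.size, dtype=float)
    seasons = list(phenological_years(time, vals))
    years = [y for y, _, _ in seasons]
    assert years == [2000, 2001, 2002]
    for _, doy, (v,) in seasons:
        assert doy[0] in (213, 214)             # Aug 1 (leap-year shift)
        assert doy[-1] in (212, 213)            # Jul 31
        assert v.size in (365, 366)
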