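"""Configuration-driven orchestration of the full projection chain.

Stages run in method order — generate (or ingest) the climate ensemble,
bias-correct against a reference realization, generate/ingest bloom
observations and calibrate the phenological models, project bloom over the
full run × model × grid factorial, derive blossom-frost risk and its
changes, partition uncertainty and find the time of emergence, and test
single-series trends.  Every random stage is seeded from the config, so a
re-run with the same configuration reproduces its artifacts bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, climate_prep, phenology, projection_risk, \
    synthetic_data, trend_stats, uncertainty
from .calibration import SAConfig, fit_params, simulate_bloom
from .climate_prep import (TemperatureSeries, apply_bias_correction,
                           build_monthly_transfer_functions,
                           temperature_anomaly)
from .phenology import PhenoParams
from .projection_risk import (FrostRiskField, delta_30yr, frost_risk_theta,
                              pmf_kde, project_bloom_ensemble,
                              unfulfilled_fraction)
from .synthetic_data import (REFERENCE_PARAMS, ScenarioConfig,
                             ensemble_to_frame, gen_bloom_observations,
                             gen_climate_ensemble)
from .trend_stats import cox_lewis, mann_kendall
from .uncertainty import (fractional_uncertainty, model_weights,
                          partition_variance, smooth_signal,
                          time_of_emergence)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report",
           "write_ensemble_csv", "read_ensemble_csv", "ensemble_to_dataset"]

log = logging.getLogger("frostbloom")


# ---------------------------------------------------------------------------
# gridded I/O

def write_ensemble_csv(ensemble: list[TemperatureSeries], path) -> None:
    """Long-format CSV: run, grid_id, lat, lon, date, tmean, tmin[, tmax]."""
    ensemble_to_frame(ensemble).to_csv(path, index=False)


def read_ensemble_csv(path) -> list[TemperatureSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for (run, gid), grp in df.groupby(["run", "grid_id"], sort=True):
        grp = grp.sort_values("date")
        out.append(TemperatureSeries(
            time=grp["date"].to_numpy(), tmean=grp["tmean"].to_numpy(),
            tmin=grp["tmin"].to_numpy() if "tmin" in grp else None,
            tmax=grp["tmax"].to_numpy() if "tmax" in grp else None,
            run=int(run), grid_id=int(gid),
            lat=float(grp["lat"].iloc[0]), lon=float(grp["lon"].iloc[0])))
    return out


def ensemble_to_dataset(ensemble: list[TemperatureSeries]):
    """Gridded xarray Dataset with dimensions (run, grid, time)."""
    import xarray as xr
    runs = sorted({s.run for s in ensemble})
    grids = sorted({s.grid_id for s in ensemble})
    ref = ensemble[0]
    shape = (len(runs), len(grids), len(ref.time))
    tmean = np.full(shape, np.nan)
    tmin = np.full(shape, np.nan)
    lats = np.full(len(grids), np.nan)
    lons = np.full(len(grids), np.nan)
    for s in ensemble:
        i, j = runs.index(s.run), grids.index(s.grid_id)
        tmean[i, j] = s.tmean
        if s.tmin is not None:
            tmin[i, j] = s.tmin
        lats[j], lons[j] = s.lat, s.lon
    return xr.Dataset(
        {"tmean": (("run", "grid", "time"), tmean),
         "tmin": (("run", "grid", "time"), tmin)},
        coords={"run": runs, "grid": grids, "time": ref.time,
                "lat": ("grid", lats), "lon": ("grid", lons)})


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Everything a full run needs; validated before any stage executes."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    model_ids: tuple[int, ...] = (2, 3, 6, 7)
    truth_model: int = 6
    obs_noise_sd: float = 2.0
    calibrate: bool = False          # False → use REFERENCE_PARAMS directly
    sa_config: SAConfig = field(default_factory=lambda: SAConfig(maxiter=120))
    bias_correct: bool = True
    betas: tuple[float, ...] = (0.0, 2.0)
    reference_window: tuple[int, int] = (1971, 2000)
    target_window: tuple[int, int] = (2070, 2099)
    lambdas: tuple[float, ...] = (0.674, 1.0, 1.645)
    alpha: float = 0.05
    obs_seed: int | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        for m in set(self.model_ids) | {self.truth_model}:
            if m not in phenology.MODEL_SPECS:
                raise ValueError(f"unknown model id {m}")
        if self.obs_seed is None:
            raise ValueError("obs_seed must be set explicitly "
                             "(every random stage needs a seed)")
        y0, y1 = self.scenario.years
        for w in (self.reference_window, self.target_window):
            if w[0] < y0 or w[1] > y1:
                raise ValueError(f"window {w} outside scenario years")


@dataclass
class PipelineResult:
    config: PipelineConfig
    bloom: pd.DataFrame                  # run, model, grid_id, year, t1, t2
    params: dict[int, PhenoParams]
    model_errors: dict[int, float]
    risk: pd.DataFrame                   # run, model, grid_id, beta, theta ref/target, delta
    summary: dict
    uncertainty_tables: dict[str, pd.DataFrame]
    trends: pd.DataFrame


# ---------------------------------------------------------------------------
# stages

def _window_theta(bloom_grp: pd.Series, temps, beta, window):
    return frost_risk_theta(bloom_grp, temps, beta=beta, window=window)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full chain and (optionally) write artifacts to out_dir."""
    config.validate()
    log.info("stage 1/7: generating climate ensemble (%d runs x %d grid)",
             config.scenario.n_runs, config.scenario.n_grid)
    ensemble = gen_climate_ensemble(config.scenario)

    # stage 2: bias correction of each run against a bias-free reference
    # realization of the same scenario (synthetic stand-in for observations)
    if config.bias_correct:
        log.info("stage 2/7: quantile-mapping bias correction")
        ref_cfg = ScenarioConfig(**{**asdict(config.scenario),
                                    "n_runs": 1, "run_bias": 0.0,
                                    "warming_spread": 0.0,
                                    "seed": config.scenario.seed + 7919})
        reference = {s.grid_id: s for s in gen_climate_ensemble(ref_cfg)}
        y0 = config.scenario.years[0]
        cal_years = (y0, min(y0 + 54, config.reference_window[1]))
        corrected = []
        for s in ensemble:
            tfs = build_monthly_transfer_functions(
                reference[s.grid_id], s, calibration_years=cal_years)
            corrected.append(apply_bias_correction(s, tfs))
        ensemble = corrected
    else:
        reference = None

    # stage 3: bloom observations + calibration (or reference parameters)
    log.info("stage 3/7: phenological parameters (calibrate=%s)",
             config.calibrate)
    truth = REFERENCE_PARAMS[config.truth_model]
    obs_series = ensemble[0] if reference is None else \
        reference[ensemble[0].grid_id]
    obs = gen_bloom_observations(config.truth_model, truth, obs_series,
                                 config.obs_noise_sd, config.obs_seed)
    params: dict[int, PhenoParams] = {}
    model_errors: dict[int, float] = {}
    cal_window = config.reference_window
    obs_cal = obs.loc[(obs.index >= cal_window[0])
                      & (obs.index <= cal_window[1])]
    for m in config.model_ids:
        if config.calibrate:
            fit = fit_params(m, obs_cal, obs_series,
                             sa_config=config.sa_config)
            params[m] = fit.params
            model_errors[m] = max(fit.rmse, 1e-6)
        else:
            params[m] = REFERENCE_PARAMS[m]
            pred = simulate_bloom(m, params[m], obs_series)
            common = obs_cal.dropna().index.intersection(pred.dropna().index)
            err = float(np.sqrt(np.mean(
                (pred.loc[common] - obs_cal.loc[common]) ** 2)))
            model_errors[m] = err

    # stage 4: bloom projection (full factorial)
    log.info("stage 4/7: projecting bloom over the ensemble")
    bloom = project_bloom_ensemble(params, ensemble,
                                   model_ids=list(config.model_ids))

    # stage 5: frost risk
    log.info("stage 5/7: blossom frost risk")
    series_by = {(s.run, s.grid_id): s for s in ensemble}
    risk_rows = []
    for (run, model, gid), grp in bloom.groupby(["run", "model", "grid_id"]):
        b = grp.set_index("year")["t2"]
        for beta in config.betas:
            th_ref = frost_risk_theta(b, series_by[(run, gid)], beta=beta,
                                      window=config.reference_window)
            th_tgt = frost_risk_theta(b, series_by[(run, gid)], beta=beta,
                                      window=config.target_window)
            risk_rows.append((run, model, gid, beta, th_ref, th_tgt,
                              th_tgt - th_ref))
    risk = pd.DataFrame(risk_rows, columns=[
        "run", "model", "grid_id", "beta", "theta_ref", "theta_target",
        "delta_theta"])

    # stage 6: uncertainty partitioning (temperature and bloom)
    log.info("stage 6/7: uncertainty partitioning")
    uncertainty_tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    bloom_area = (bloom.groupby(["run", "model", "year"])["t2"]
                  .mean().reset_index()
                  .rename(columns={"t2": "value"}))
    sm_bloom = smooth_signal(bloom_area)
    weights = model_weights(model_errors)
    dec_bloom = partition_variance(sm_bloom, weights=weights,
                                   reference=config.reference_window)
    uncertainty_tables["bloom"] = dec_bloom.to_frame(config.lambdas)

    temp_rows = []
    for s in ensemble:
        annual = pd.Series(s.tmean, index=s.index).groupby(
            s.index.year).mean()
        for y, v in annual.items():
            temp_rows.append((s.run, 0, int(y), v))
    temp_area = (pd.DataFrame(temp_rows,
                              columns=["run", "model", "year", "value"])
                 .groupby(["run", "model", "year"]).mean().reset_index())
    sm_temp = smooth_signal(temp_area)
    dec_temp = partition_variance(sm_temp,
                                  reference=config.reference_window)
    uncertainty_tables["temperature"] = dec_temp.to_frame(config.lambdas)

    emergence = {}
    for name, dec in (("temperature", dec_temp), ("bloom", dec_bloom)):
        for lam in config.lambdas:
            F = fractional_uncertainty(dec.G, dec.total, lam)
            toe, argmin = time_of_emergence(
                dec.years, F, start_year=config.reference_window[1])
            emergence[(name, lam)] = {"emergence_year": toe,
                                      "min_uncertainty_year": argmin}
    summary["emergence"] = emergence

    # stage 7: single-series trend tests
    log.info("stage 7/7: trend tests")
    trend_rows = []
    y0, y1 = config.scenario.years[0], config.scenario.years[1]
    for (run, model, gid), grp in bloom.groupby(["run", "model", "grid_id"]):
        b = grp.set_index("year")["t2"].dropna()
        if len(b) >= 4:
            mk = mann_kendall(b.to_numpy())
            trend_rows.append((run, model, gid, "bloom_mk", mk.statistic,
                               mk.z, mk.p_value, mk.p_value <= config.alpha))
    for (run, gid), s in series_by.items():
        freeze_years = []
        for year in range(y0 + 1, y1 + 1):
            m = s.index.year == year
            doy = s.index.dayofyear.values[m]
            f = projection_risk.last_spring_freeze(s.tmin[m], doy)
            if f is not None:
                freeze_years.append(year)
        cl = cox_lewis(freeze_years, (y0 + 1, y1))
        trend_rows.append((run, -1, gid, "freeze_coxlewis", cl.statistic,
                           cl.z, cl.p_value, cl.p_value <= config.alpha))
    trends = pd.DataFrame(trend_rows, columns=[
        "run", "model", "grid_id", "test", "statistic", "z", "p_value",
        "significant"])

    result = PipelineResult(config=config, bloom=bloom, params=params,
                            model_errors=model_errors, risk=risk,
                            summary=summary,
                            uncertainty_tables=uncertainty_tables,
                            trends=trends)
    if config.out_dir:
        _write_artifacts(result, Path(config.out_dir))
    return result


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.bloom.to_csv(out / "bloom.csv", index=False)
    result.risk.to_csv(out / "risk.csv", index=False)
    result.trends.to_csv(out / "trends.csv", index=False)
    for name, tab in result.uncertainty_tables.items():
        tab.to_csv(out / f"uncertainty_{name}.csv")
    with open(out / "params.json", "w") as fh:
        json.dump({m: asdict(p) for m, p in result.params.items()}, fh,
                  indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonify(result.summary), fh, indent=2)
    log.info("artifacts written to %s", out)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Summary tables: per-model error, Δbloom / Δθ, emergence years."""
    cfg = result.config
    error_table = pd.DataFrame(
        {"model": list(result.model_errors),
         "rmse_days": [result.model_errors[m] for m in result.model_errors],
         "weight": model_weights(result.model_errors).reindex(
             list(result.model_errors)).to_numpy()})

    rows = []
    for model, grp in result.bloom.groupby("model"):
        area = grp.groupby("year")["t2"].mean()
        rows.append((model, delta_30yr(area, cfg.reference_window,
                                       cfg.target_window, min_coverage=0.5)))
    delta_bloom = pd.DataFrame(rows, columns=["model", "delta_bloom_days"])

    delta_risk = (result.risk.groupby(["model", "beta"])["delta_theta"]
                  .mean().reset_index()
                  .rename(columns={"delta_theta": "mean_delta_theta"}))

    emergence = pd.DataFrame(
        [(var, lam, v["emergence_year"], v["min_uncertainty_year"])
         for (var, lam), v in result.summary["emergence"].items()],
        columns=["variable", "lambda", "emergence_year",
                 "min_uncertainty_year"])

    return {"model_errors": error_table, "delta_bloom": delta_bloom,
            "delta_theta": delta_risk, "emergence": emergence}
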