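"""End-to-end pipeline: simulate -> preprocess -> select -> validate -> map.

One :class:`PipelineConfig` drives a full run; every stage logs its row
counts and exclusions to stderr, outputs are written atomically (tmp file
then rename), and a run manifest records the config hash and every
derived seed so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io as cio, warming as cw
from .chilling import (
    CUConfig,
    DailyTemperatureSeries,
    GridSpec,
    filter_by_missing_rate,
    impute_missing,
)
from .geo import classify_suitability, network_period_max_cu, svm_interpolate
from .model import ModelFit, assemble_design, grid_search
from .synthetic import (
    ClimateParams,
    TrueModel,
    gen_qy_observations,
    gen_temperature_series,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("chillqy.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-serialisable."""

    seed: int = 0
    # --- simulation of the home site -------------------------------------
    climate: ClimateParams = field(default_factory=ClimateParams)
    truth: TrueModel = field(default_factory=TrueModel.default)
    start_year: int = 2013
    n_train_seasons: int = 3  # one further season is held out for validation
    n_lines: int = 2
    n_replicates: int = 3
    sampling_interval_days: int = 14
    # --- preprocessing / fitting -----------------------------------------
    max_missing_rate: float = 0.10
    aggregation: str = "per_line_date_mean"
    eps: float = 1e-3
    temperature_sum_kind: str = "deficit"
    grid: GridSpec = field(default_factory=GridSpec)
    interval_kind: str = "confidence"
    # --- geographic suitability ------------------------------------------
    run_geo: bool = True
    geo_n_sites: int = 40
    geo_lat_range: tuple[float, float] = (0.0, 60.0)
    geo_lon_range: tuple[float, float] = (0.0, 40.0)
    geo_resolution: float = 2.0
    cu_threshold: float = 35.0
    # --- warming trend -----------------------------------------------------
    run_warming: bool = True
    warming_n_sites: int = 30
    warming_lat_range: tuple[float, float] = (31.0, 45.0)
    warming_lon_range: tuple[float, float] = (129.0, 142.0)
    warming_rate: float = 0.03  # degrees C per year imposed on the network
    warming_start_year: int = 1981
    warming_end_year: int = 2020
    target_years: tuple[int, ...] = (1985, 2085)
    qy_threshold: float = 0.20
    warming_resolution: float = 0.5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {
            "thresholds": {
                s: [t.low, t.high, t.step] for s, t in self.grid.thresholds.items()
            },
            "windows": [self.grid.windows.min_L, self.grid.windows.max_L,
                        self.grid.windows.step],
            "cu_types": list(self.grid.cu_types),
            "temp_stats": list(self.grid.temp_stats),
        }
        return d

    def to_yaml(self, path) -> None:
        _atomic_write_text(path, yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "climate" in d and isinstance(d["climate"], dict):
            d["climate"] = ClimateParams(**d["climate"])
        if "truth" in d and isinstance(d["truth"], dict):
            t = dict(d["truth"])
            if isinstance(t.get("cu_config"), dict):
                t["cu_config"] = CUConfig(**t["cu_config"])
            d["truth"] = TrueModel(**t)
        if "grid" in d and isinstance(d["grid"], dict):
            g = d["grid"]
            from .chilling import ThresholdRange, WindowRange

            d["grid"] = GridSpec(
                thresholds={s: ThresholdRange(*v) for s, v in g["thresholds"].items()},
                windows=WindowRange(*g["windows"]),
                cu_types=tuple(g.get("cu_types", ("day_count", "temperature_sum"))),
                temp_stats=tuple(g.get("temp_stats", ("max", "min", "avg"))),
            )
        for key in ("geo_lat_range", "geo_lon_range", "warming_lat_range",
                    "warming_lon_range", "target_years"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config fields {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic_write_csv(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % 2**31) for s in state]


def _trim_boundary_missing(series: DailyTemperatureSeries) -> DailyTemperatureSeries:
    """Drop leading/trailing fully- or partly-missing days so interior
    interpolation has anchored boundaries."""
    f = series.frame
    ok = f.notna().all(axis=1)
    if not ok.any():
        raise ValueError(f"site {series.site_id}: no complete day in record")
    first, last = ok.idxmax(), ok[::-1].idxmax()
    return DailyTemperatureSeries(series.site_id, f.loc[first:last])


def _season_bounds(start_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    return pd.Timestamp(start_year, 11, 1), pd.Timestamp(start_year + 1, 3, 31)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every requested stage; returns a dict of artifact paths.

    Any stage failure aborts with :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    seeds = _derived_seeds(config.seed, 8 + config.n_train_seasons + 1)
    n_seasons = config.n_train_seasons + 1

    def stage(name):
        def wrap(fn):
            try:
                log.info("stage %s: start", name)
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrap

    # ---- simulate ---------------------------------------------------------
    def _simulate():
        start = pd.Timestamp(config.start_year, 7, 1)
        end = pd.Timestamp(config.start_year + n_seasons, 3, 31)
        n_days = (end - start).days + 1
        # the trees respond to the complete weather; station gaps are an
        # observation artifact, so QY is generated from the ungapped twin
        recorded = gen_temperature_series(
            config.climate.with_seed(seeds[0]), start, n_days, site_id="home"
        )
        complete = gen_temperature_series(
            dataclasses.replace(config.climate, missing_fraction=0.0, seed=seeds[0]),
            start, n_days, site_id="home",
        )
        obs_frames = []
        for i in range(n_seasons):
            first, last = _season_bounds(config.start_year + i)
            obs_frames.append(
                gen_qy_observations(
                    complete, config.truth, first, config.sampling_interval_days,
                    last, config.n_lines, config.n_replicates,
                    seed=seeds[1 + i],
                )
            )
        obs = pd.concat(obs_frames, ignore_index=True)
        cio.write_climate_csv(recorded, out / "climate.csv")
        cio.write_qy_csv(obs, out / "qy.csv")
        artifacts["climate"] = str(out / "climate.csv")
        artifacts["qy"] = str(out / "qy.csv")
        manifest["stages"]["simulate"] = {
            "n_days": len(recorded), "n_observations": len(obs),
            "seeds": seeds[: 1 + n_seasons],
        }
        return recorded, obs

    series, obs = stage("simulate")(_simulate)

    # ---- filter / impute --------------------------------------------------
    def _preprocess():
        s = _trim_boundary_missing(series)
        rejected = []
        for stat in ("max", "min", "avg"):
            d = filter_by_missing_rate(s, stat, config.max_missing_rate)
            log.info("filter %s: rate %.4f accepted=%s", stat, d.missing_rate,
                     d.accepted)
            if not d.accepted:
                rejected.append((stat, d.missing_rate))
        if rejected:
            raise PipelineError(
                "stage 'preprocess' failed: all usable records excluded — "
                f"missing rates {rejected} exceed {config.max_missing_rate}"
            )
        imputed = impute_missing(s)
        manifest["stages"]["preprocess"] = {
            "n_days": len(imputed),
            "missing_rates": {
                stat: series.missing_rate(stat) for stat in ("max", "min", "avg")
            },
        }
        return imputed

    imputed = stage("preprocess")(_preprocess)

    # ---- grid search on training seasons ---------------------------------
    def _select():
        train_end = _season_bounds(config.start_year + config.n_train_seasons - 1)[1]
        train_obs = obs[obs["date"] <= train_end]
        result = grid_search(
            imputed, train_obs, config.grid, config.aggregation,
            config.temperature_sum_kind, config.eps,
        )
        _atomic_write_csv(result.fits, out / "aic_table.csv")
        best = result.best
        summary = {
            "cu_type": best.config.cu_type,
            "temp_stat": best.config.temp_stat,
            "threshold": best.config.threshold,
            "window": best.config.window,
            "a": best.a, "b": best.b, "sigma": best.sigma,
            "n_obs": best.n_obs, "log_lik": best.log_lik, "aic": best.aic,
            "r_squared": best.r_squared,
            "n_ties": len(result.tie_report),
        }
        _atomic_write_text(out / "best_model.json",
                           json.dumps(summary, indent=2, sort_keys=True) + "\n")
        artifacts["aic_table"] = str(out / "aic_table.csv")
        artifacts["best_model"] = str(out / "best_model.json")
        manifest["stages"]["select"] = {
            "n_models": len(result.fits), "n_train_obs": len(train_obs),
        }
        return result, train_obs

    result, train_obs = stage("select")(_select)

    # ---- per-season validation -------------------------------------------
    def _evaluate():
        from .chilling import compute_cu

        best = result.best
        cu = compute_cu(imputed, best.config, config.temperature_sum_kind)
        train_design = assemble_design(cu, train_obs, config.aggregation, config.eps)
        rows, lines = [], []
        for i in range(n_seasons):
            year = config.start_year + i
            first, last = _season_bounds(year)
            season_obs = obs[(obs["date"] >= first) & (obs["date"] <= last)]
            design = assemble_design(cu, season_obs, config.aggregation, config.eps)
            preds = evaluation.predict_with_intervals(
                best, design["cu"], train_design, dates=design["date"]
            )
            preds = preds.drop_duplicates("date")
            obs_points = design.rename(columns={"logit_qy": "logit_qy_obs"})
            obs_points["qy"] = cio_inverse(obs_points["logit_qy_obs"])
            n_in, n_tot = evaluation.coverage_count(
                preds, obs_points[["date", "qy"]], config.interval_kind
            )
            r, r2 = evaluation.prediction_metrics(
                best.predict_qy(design["cu"].to_numpy()),
                obs_points["qy"].to_numpy(), scale="logit", eps=config.eps,
            )
            kind = "validation" if i == config.n_train_seasons else "training"
            rows.append({
                "season": f"{year}-{year + 1}", "role": kind,
                "n_points": n_tot, "n_within": n_in,
                "interval_kind": config.interval_kind,
                "pearson_r": r, "r_squared_pred": r2,
            })
            per_point = obs_points.merge(preds, on="date")
            per_point.insert(0, "season", f"{year}-{year + 1}")
            lines.append(per_point)
        report = pd.DataFrame(rows)
        _atomic_write_csv(report, out / "validation_summary.csv")
        _atomic_write_csv(pd.concat(lines, ignore_index=True),
                          out / "validation_points.csv")
        artifacts["validation_summary"] = str(out / "validation_summary.csv")
        artifacts["validation_points"] = str(out / "validation_points.csv")
        manifest["stages"]["evaluate"] = {"n_seasons": n_seasons}
        return report

    stage("evaluate")(_evaluate)

    # ---- geographic suitability ------------------------------------------
    if config.run_geo:
        def _geo():
            best = result.best
            start = pd.Timestamp(config.start_year, 7, 1)
            n_days = 365 * 2 + best.config.window
            sites = cio.gen_site_network(
                config.geo_n_sites, config.geo_lat_range, config.geo_lon_range,
                start, n_days, config.climate, seed=seeds[-2],
            )
            period = (start + pd.Timedelta(days=best.config.window),
                      start + pd.Timedelta(days=n_days - 1))
            values, excluded = network_period_max_cu(
                sites, best.config, period, config.max_missing_rate
            )
            if values.empty:
                raise PipelineError(
                    "stage 'geo' failed: all sites excluded by the missing-rate "
                    "filter"
                )
            grid = svm_interpolate(values, config.geo_resolution, "regression",
                                   seed=seeds[-2])
            classified, n_suitable = classify_suitability(
                grid, config.cu_threshold, "cu_max"
            )
            _atomic_write_csv(values, out / "geo_sites.csv")
            _atomic_write_csv(classified.cells, out / "geo_grid.csv")
            artifacts["geo_sites"] = str(out / "geo_sites.csv")
            artifacts["geo_grid"] = str(out / "geo_grid.csv")
            manifest["stages"]["geo"] = {
                "n_sites": len(values), "n_excluded": len(excluded),
                "n_cells": len(classified.cells), "n_suitable": n_suitable,
                "seed": seeds[-2],
            }

        stage("geo")(_geo)

    # ---- warming trend ----------------------------------------------------
    if config.run_warming:
        def _warming():
            best = result.best
            warm_climate = dataclasses.replace(
                config.climate, warming_rate=config.warming_rate
            )
            start = pd.Timestamp(config.warming_start_year, 7, 1)
            end = pd.Timestamp(config.warming_end_year + 1, 3, 31)
            sites = cio.gen_site_network(
                config.warming_n_sites, config.warming_lat_range,
                config.warming_lon_range, start, (end - start).days + 1,
                warm_climate, seed=seeds[-1],
            )
            trend_rows, site_rows = [], []
            for site in sites:
                annual, _skipped = cw.seasonal_min_qy(site, best)
                trend = cw.fit_trend(annual)
                trend_rows.append({
                    "site_id": site.site_id, "lat": site.latitude,
                    "lon": site.longitude, "slope": trend.slope,
                    "intercept": trend.intercept, "n_seasons": trend.n_seasons,
                })
                row = {"site_id": site.site_id, "lat": site.latitude,
                       "lon": site.longitude}
                for ty in config.target_years:
                    row[f"qy_{ty}"] = cw.extrapolate(trend, ty)
                site_rows.append(row)
            trends = pd.DataFrame(trend_rows)
            per_site = pd.DataFrame(site_rows)
            counts = {}
            for ty in config.target_years:
                counts[str(ty)] = cw.count_suitable_sites(
                    per_site[f"qy_{ty}"], config.qy_threshold
                )
                per_site[f"suitable_{ty}"] = per_site[f"qy_{ty}"] > config.qy_threshold
            _atomic_write_csv(trends, out / "warming_trends.csv")
            _atomic_write_csv(per_site, out / "warming_sites.csv")
            artifacts["warming_trends"] = str(out / "warming_trends.csv")
            artifacts["warming_sites"] = str(out / "warming_sites.csv")
            manifest["stages"]["warming"] = {
                "n_sites": len(per_site), "suitable_counts": counts,
                "seed": seeds[-1],
            }

        stage("warming")(_warming)

    _atomic_write_text(out / "run_manifest.json",
                       json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = str(out / "run_manifest.json")
    log.info("pipeline complete: %d artifact(s) in %s", len(artifacts), out)
    return artifacts


def cio_inverse(logit_vals) -> np.ndarray:
    from .model import inverse_logit

    return inverse_logit(np.asarray(logit_vals, dtype=float))
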