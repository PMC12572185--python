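"""Run configuration and pipeline orchestration.

A :class:`RunConfig` (usually loaded from YAML) describes the synthetic
sites, calibration settings and scenario grid; :func:`run_pipeline`
executes the stages in dependency order (synth -> chronology ->
calibrate -> forecast -> diagnose -> validate -> stationarity), writes
every artifact as CSV/JSON under the output directory and records a
manifest with content hashes. A fixed config + seed reproduces
byte-identical outputs. The global seed fans out to per-site seeds by a
stable CRC32 hash of the site id, so sites never share random streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as _cal
from . import chronology as _chron
from . import diagnostics as _diag
from . import scenarios as _scen
from . import synth as _synth
from . import validation as _val
from .containers import MonthlyClimateSeries, VSLiteParameters
from .model import simulate
from .rwl import write_rwl

__all__ = ["RunConfig", "SiteConfig", "run_pipeline", "site_seed", "load_config"]

log = logging.getLogger("ringcast")

ALL_STAGES = ("synth", "chronology", "calibrate", "forecast", "diagnose", "validate", "stationarity")


def site_seed(global_seed: int, site_id: str) -> int:
    """Per-site seed from the global seed and a stable hash of the id."""
    return int((global_seed + zlib.crc32(site_id.encode())) % (2**31 - 1))


@dataclass
class SiteConfig:
    site_id: str = "site-1"
    latitude: float = 49.0
    mean_annual_temp: float = 8.0
    temp_seasonal_amplitude: float = 9.5
    annual_precip: float = 650.0
    precip_seasonality: float = 0.35
    truth: dict = field(default_factory=dict)  # optional truth parameter overrides
    n_trees: int = 12
    noise_sd: float = 0.05


@dataclass
class RunConfig:
    out_dir: str = "ringcast-run"
    seed: int = 0
    years: tuple[int, int] = (1960, 2020)
    sites: list[SiteConfig] = field(default_factory=lambda: [SiteConfig()])
    n_draws: int = 10_000
    n_boot: int = 1000
    warming_per_period: float = 1.0
    precip_shift: float = -2.0
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"

    def truth_params(self, site: SiteConfig) -> VSLiteParameters:
        return VSLiteParameters(**site.truth) if site.truth else VSLiteParameters()


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sites = [SiteConfig(**s) for s in raw.pop("sites", [])]
    cfg = RunConfig(**raw)
    if sites:
        cfg.sites = sites
    if isinstance(cfg.years, list):
        cfg.years = tuple(cfg.years)
    if isinstance(cfg.stages, list):
        cfg.stages = tuple(cfg.stages)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the manifest (also written to
    ``<out_dir>/manifest.json``). A stage failure halts the run, leaving a
    FAILED marker naming the site and stage."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]
    manifest = {"config": dataclasses.asdict(config), "artifacts": {}}
    produced: list[Path] = []

    state: dict[str, dict] = {s.site_id: {} for s in config.sites}
    try:
        for stage in stages:
            for site in config.sites:
                log.info("stage=%s site=%s", stage, site.site_id)
                _run_stage(stage, site, config, state[site.site_id], out, produced)
    except Exception as exc:
        (out / "FAILED").write_text(f"{exc}\n")
        raise
    for path in produced:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _run_stage(stage, site, config, st, out, produced):
    seed = site_seed(config.seed, site.site_id)
    truth = config.truth_params(site)
    if stage == "synth":
        spec = _synth.SyntheticSiteSpec(
            site_id=site.site_id,
            latitude=site.latitude,
            mean_annual_temp=site.mean_annual_temp,
            temp_seasonal_amplitude=site.temp_seasonal_amplitude,
            annual_precip=site.annual_precip,
            precip_seasonality=site.precip_seasonality,
            years=config.years,
            seed=seed,
        )
        st["climate"] = _synth.generate_climate(spec)
        st["trees"] = _synth.generate_pseudo_observed_rings(
            st["climate"], truth, n_trees=site.n_trees, noise_sd=site.noise_sd, seed=seed + 1
        )
        st["anomalies"] = _synth.generate_anomaly_table(
            warming_per_period=config.warming_per_period, precip_shift=config.precip_shift
        )
        p = out / f"{site.site_id}-climate.csv"
        st["climate"].to_frame().to_csv(p, index=False)
        produced.append(p)
        p = out / f"{site.site_id}-rings.rwl"
        write_rwl(st["trees"], p)
        produced.append(p)
        p = out / "anomalies.csv"
        st["anomalies"].to_csv(p, index=False)
        if p not in produced:
            produced.append(p)
    elif stage == "chronology":
        st["chronology"] = _chron.build_chronology(st["trees"], site_id=site.site_id)
        p = out / f"{site.site_id}-chronology.csv"
        st["chronology"].to_frame().to_csv(p, index=False)
        produced.append(p)
    elif stage == "calibrate":
        st["calibration"] = _cal.random_search_calibrate(
            st["chronology"], st["climate"], n_draws=config.n_draws, seed=seed
        )
        res = st["calibration"]
        p = out / f"{site.site_id}-calibration.json"
        p.write_text(json.dumps({
            "site_id": site.site_id,
            "params": dataclasses.asdict(res.best_params),
            "r": res.r, "p_value": res.p_value, "ci95": list(res.ci95),
            "t_stat": res.t_stat, "df": res.df, "n_draws": res.n_draws,
            "seed": res.seed, "window": list(res.calibration_window),
        }, indent=2) + "\n")
        produced.append(p)
    elif stage == "forecast":
        params = st["calibration"].best_params
        stats = _scen.normal_period_stats(st["climate"])
        climatologies = _scen.build_all_climatologies(stats, st["anomalies"])
        st["forecasts"] = {
            (c.scenario, c.period, c.kind): _scen.burn_in_forecast(c, params)
            for c in climatologies
        }
        frame = pd.concat([c.to_frame() for c in climatologies], ignore_index=True)
        p = out / f"{site.site_id}-climatologies.csv"
        frame.to_csv(p, index=False)
        produced.append(p)
    elif stage == "diagnose":
        params = st["calibration"].best_params
        st["baseline_sim"] = simulate(st["climate"], params)
        base = st["baseline_sim"]
        baseline_trw = base.trw_proxy[1:]
        rows = []
        for (scen, period, kind), fsim in st["forecasts"].items():
            year = int(fsim.years[0])
            deficit = _diag.growth_deficit(fsim, year)
            season = _diag.growing_season(fsim, year)
            ratio, pct = _diag.relative_trw(fsim.trw_proxy[0], baseline_trw)
            welch = _diag.welch_one_sample(fsim.trw_proxy[0], baseline_trw)
            rows.append({
                "site_id": site.site_id, "scenario": scen, "period": period, "kind": kind,
                "cold_deficit": deficit.cold_deficit, "drought_deficit": deficit.drought_deficit,
                "season_start": season.start_month, "season_end": season.end_month,
                "peaks": _diag.count_growth_peaks(fsim.grINT[0]),
                "relative_trw": ratio, "pct_change": pct,
                "welch_t": welch.t_stat, "welch_p": welch.p_value,
            })
        p = out / f"{site.site_id}-diagnostics.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        produced.append(p)
    elif stage == "validate":
        base = st["baseline_sim"]
        year = int(base.years[-1])
        trace = _synth.generate_dendrometer_trace(base, year, seed=seed + 2)
        growth = _val.zero_growth_extract(trace)
        monthly = _val.monthly_growth_totals(growth)
        iy = base.year_index(year)
        if monthly.sum() > 0 and base.grINT[iy].sum() > 0:
            comp = _val.monthly_standardize_and_compare(monthly, base.grINT[iy])
            row = {"site_id": site.site_id, "year": year, "r": comp.r,
                   "rmse": comp.rmse, "peak_offset": comp.peak_offset}
        else:
            row = {"site_id": site.site_id, "year": year, "r": np.nan,
                   "rmse": np.nan, "peak_offset": np.nan}
        p = out / f"{site.site_id}-validation.csv"
        pd.DataFrame([row]).to_csv(p, index=False)
        produced.append(p)
    elif stage == "stationarity":
        res = _cal.stationarity_test(
            st["chronology"], st["climate"], n_draws=config.n_draws,
            n_boot=config.n_boot, seed=seed,
        )
        p = out / f"{site.site_id}-stationarity.json"
        p.write_text(json.dumps({
            "site_id": site.site_id, "verdict": res.verdict,
            "slopes": list(res.slopes), "slope_diff": res.slope_diff,
            "slope_diff_ci95": list(res.slope_diff_ci95), "p_slope": res.p_slope,
        }, indent=2, default=str) + "\n")
        produced.append(p)
    else:
        raise ValueError(f"unknown stage {stage!r}")
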