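"""End-to-end pipeline driver: DEM -> psi series -> ARIMA T_end -> surrogate.

Stages are individually toggleable; when the DEM stage is off, the synthetic
curve generator supplies the segregation-index traces so the forecasting and
surrogate stages can run in seconds.  Every run writes a manifest recording
seeds, versions, per-stage wall-clock and a SHA-256 hash of each output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .engine import run_simulation
from .forecast import forecast_to_cutoff
from .mixing import series_from_trajectory
from .params import (ContactModelParams, DESCRIPTOR_NAMES,
                     MaterialProcessParams, VesselGeometry)
from .surrogate import assemble_table, fit_and_crossvalidate
from .synth import (DEFAULT_RANGES, SyntheticCurveSpec,
                    generate_mixing_curve, mixing_kinetics_from_params)
from .trajectory import write_trajectory_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``stages`` is an ordered subset of {"dem", "synth_curves", "forecast",
    "surrogate"}.  Every stochastic stage derives its seed from ``seed`` so
    a config fully determines the outputs.
    """

    seed: int = 0
    stages: tuple[str, ...] = ("synth_curves", "forecast", "surrogate")
    cutoff_psi: float = 1.1
    n_runs: int = 40
    curve_noise_sd: float = 0.01
    curve_n_points: int = 150
    curve_duration_frac: float = 0.75  # observed window / analytic crossing
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    # DEM stage settings (used only when "dem" is enabled)
    material: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    duration_s: float = 2.0
    snapshot_interval_s: float = 0.02
    # forecasting / surrogate settings
    forecast_kwargs: dict = field(default_factory=lambda: {
        "p_max": 8, "d_max": 2, "q_max": 2, "patience": 3})
    surrogate_methods: tuple[str, ...] = ("rf", "svr", "plsr", "elastic_net")
    surrogate_n_estimators: int = 500

    def __post_init__(self) -> None:
        if self.cutoff_psi <= 1.0:
            raise ValueError("cutoff_psi must exceed 1")
        bad = set(self.stages) - {"dem", "synth_curves", "forecast", "surrogate"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "surrogate_methods" in raw:
            raw["surrogate_methods"] = tuple(raw["surrogate_methods"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sample_designs(config: PipelineConfig) -> list[MaterialProcessParams]:
    rng = np.random.default_rng(config.seed)
    designs = []
    for _ in range(config.n_runs):
        kw = {}
        for name in DESCRIPTOR_NAMES:
            lo, hi = config.ranges.get(name, DEFAULT_RANGES[name])
            val = float(rng.uniform(lo, hi))
            kw[name] = int(round(val)) if name == "n_particles" else val
        designs.append(MaterialProcessParams(**kw))
    return designs


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order, writing standard files.

    Returns a dict of in-memory artifacts (series, estimates, table,
    surrogate report, manifest).  A stage failure propagates after earlier
    stages' files are already on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"granumix_version": __version__, "seed": config.seed,
                      "stages": list(config.stages), "stage_seconds": {},
                      "files": {}, "stage_seeds": {}}
    artifacts: dict = {"manifest": manifest}
    series_list: list = []
    run_params: list[MaterialProcessParams] = []

    def _record(path: Path) -> None:
        manifest["files"][path.name] = _sha256(path)

    if "dem" in config.stages:
        t0 = time.perf_counter()
        params = MaterialProcessParams(**config.material)
        geometry = VesselGeometry(**config.geometry)
        contact = ContactModelParams(**config.numerics)
        manifest["stage_seeds"]["dem"] = config.seed
        snaps = run_simulation(params, geometry, contact,
                               duration_s=config.duration_s,
                               snapshot_interval_s=config.snapshot_interval_s,
                               seed=config.seed)
        traj_path = outdir / "trajectory.csv"
        write_trajectory_csv(snaps, traj_path)
        _record(traj_path)
        series = series_from_trajectory(snaps, geometry)
        path = outdir / "series_dem.csv"
        series.to_csv(path)
        _record(path)
        series_list.append(series)
        run_params.append(params)
        artifacts["dem_snapshots"] = snaps
        manifest["stage_seconds"]["dem"] = time.perf_counter() - t0

    if "synth_curves" in config.stages:
        t0 = time.perf_counter()
        manifest["stage_seeds"]["synth_curves"] = config.seed
        designs = _sample_designs(config)
        for k, params in enumerate(designs):
            psi0, rate_k = mixing_kinetics_from_params(params)
            spec = SyntheticCurveSpec(
                psi0=psi0, rate_k=rate_k, rpm=params.rpm,
                noise_sd=config.curve_noise_sd,
                n_points=config.curve_n_points,
                duration_s=config.curve_duration_frac * SyntheticCurveSpec(
                    psi0=psi0, rate_k=rate_k, rpm=params.rpm,
                    ).analytic_crossing(config.cutoff_psi),
                seed=config.seed * 100_003 + k)
            series = generate_mixing_curve(spec)
            path = outdir / f"series_{k:03d}.csv"
            series.to_csv(path)
            _record(path)
            series_list.append(series)
            run_params.append(params)
        manifest["stage_seconds"]["synth_curves"] = time.perf_counter() - t0

    if "forecast" in config.stages:
        t0 = time.perf_counter()
        estimates = []
        for k, series in enumerate(series_list):
            est = forecast_to_cutoff(series.times, series.psi_bulk,
                                     cutoff=config.cutoff_psi,
                                     **config.forecast_kwargs)
            estimates.append(est)
            path = outdir / f"endpoint_{k:03d}.json"
            path.write_text(json.dumps(est.as_dict(), indent=2))
            _record(path)
        artifacts["estimates"] = estimates
        manifest["stage_seconds"]["forecast"] = time.perf_counter() - t0

    if "surrogate" in config.stages:
        t0 = time.perf_counter()
        if "estimates" not in artifacts:
            raise ValueError("surrogate stage requires the forecast stage")
        table = assemble_table(list(zip(run_params, artifacts["estimates"])))
        table_path = outdir / "table.csv"
        table.write(table_path)
        _record(table_path)
        _record(table_path.with_suffix(".meta.json"))
        manifest["stage_seeds"]["surrogate"] = config.seed
        report = fit_and_crossvalidate(
            table, methods=config.surrogate_methods, seed=config.seed,
            n_estimators=config.surrogate_n_estimators)
        report_path = outdir / "surrogate_report.json"
        report_path.write_text(json.dumps(report.as_dict(), indent=2))
        _record(report_path)
        artifacts["table"] = table
        artifacts["surrogate_report"] = report
        manifest["stage_seconds"]["surrogate"] = time.perf_counter() - t0

    artifacts["series"] = series_list
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d files in %s",
                len(manifest["files"]), outdir)
    return artifacts
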