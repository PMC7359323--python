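"""Synthetic generators, trajectory I/O, pipeline driver and CLI glue."""

from __future__ import annotations

import json

import numpy as np
import pytest
from click.testing import CliRunner

from granumix.cli import main as cli_main
from granumix.forecast import forecast_to_cutoff
from granumix.pipeline import PipelineConfig, run_pipeline
from granumix.synth import (DEFAULT_RANGES, SyntheticCurveSpec,
                            SyntheticDesignSpec, generate_design_table,
                            generate_mixing_curve)
from granumix.trajectory import (read_liggghts_dump, read_trajectory_csv,
                                 write_trajectory_csv)

from conftest import desk_params


# ------------------------------------------------------------------- curves
class TestSyntheticCurve:
    def test_analytic_crossing_closed_form(self):
        spec = SyntheticCurveSpec(psi0=1.9, rate_k=0.2, rpm=60.0,
                                  noise_sd=0.0)
        # crossing in revolutions is ln((psi0-1)/(cutoff-1))/k
        revs = np.log(0.9 / 0.1) / 0.2
        assert spec.analytic_crossing(1.1) == pytest.approx(
            60.0 * revs / 60.0)

    def test_doubling_rpm_halves_crossing_seconds(self):
        a = SyntheticCurveSpec(psi0=1.8, rate_k=0.15, rpm=20.0, noise_sd=0.0)
        b = SyntheticCurveSpec(psi0=1.8, rate_k=0.15, rpm=40.0, noise_sd=0.0)
        assert a.analytic_crossing(1.1) == pytest.approx(
            2.0 * b.analytic_crossing(1.1))

    def test_fixed_seed_reproduces_noisy_curve(self):
        spec = SyntheticCurveSpec(noise_sd=0.02, seed=77)
        x = generate_mixing_curve(spec)
        y = generate_mixing_curve(spec)
        assert np.array_equal(x.psi_bulk, y.psi_bulk)

    def test_curve_respects_bounds_and_metadata(self):
        spec = SyntheticCurveSpec(psi0=2.0, rate_k=0.05, rpm=10.0,
                                  noise_sd=0.3, n_points=300, seed=5)
        series = generate_mixing_curve(spec)
        assert series.psi_bulk.min() >= 0.0
        assert series.psi_bulk.max() <= 2.0
        assert series.meta["analytic_crossing_1.1"] == pytest.approx(
            spec.analytic_crossing(1.1))

    @pytest.mark.parametrize("psi0, rate_k, rpm", [
        (1.9, 0.1, 20.0), (1.5, 0.3, 45.0), (1.8, 0.2, 60.0)])
    def test_forecast_recovers_analytic_crossing(self, psi0, rate_k, rpm):
        spec = SyntheticCurveSpec(psi0=psi0, rate_k=rate_k, rpm=rpm,
                                  noise_sd=0.0, n_points=100,
                                  duration_s=0.8 * SyntheticCurveSpec(
                                      psi0=psi0, rate_k=rate_k, rpm=rpm,
                                  ).analytic_crossing(1.1))
        series = generate_mixing_curve(spec)
        est = forecast_to_cutoff(series.times, series.psi_bulk, cutoff=1.1,
                                 p_max=4, patience=3)
        assert est.t_end == pytest.approx(spec.analytic_crossing(1.1),
                                          rel=0.05)

    def test_design_table_ranges_and_metadata(self):
        spec = SyntheticDesignSpec(n_rows=30, seed=8, noise_sd=0.1)
        table = generate_design_table(spec)
        assert table.n_rows == 30
        for name, (lo, hi) in DEFAULT_RANGES.items():
            col = table.frame[name]
            assert col.min() >= lo and col.max() <= hi
        assert table.metadata["planted"]["active"]


# ----------------------------------------------------------------------- io
class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path, small_settled_snapshot):
        path = tmp_path / "traj.csv"
        snaps = [small_settled_snapshot]
        # add a second, shifted snapshot so monotonicity is exercised
        import dataclasses
        second = dataclasses.replace(small_settled_snapshot, time=0.5,
                                     revolutions=1.0)
        write_trajectory_csv([snaps[0], second], path)
        back = read_trajectory_csv(path, rpm=120.0)
        assert len(back) == 2
        assert np.allclose(back[0].positions,
                           small_settled_snapshot.positions)
        assert np.array_equal(back[0].labels, small_settled_snapshot.labels)
        assert back[1].revolutions == pytest.approx(1.0)

    def test_liggghts_dump_parser(self, tmp_path):
        dump = """ITEM: TIMESTEP
1000
ITEM: NUMBER OF ATOMS
3
ITEM: BOX BOUNDS pp pp pp
0 1
0 1
0 1
ITEM: ATOMS id type x y z vx vy vz radius
2 1 0.1 0.2 0.3 0 0 -1 0.003
1 2 0.4 0.5 0.6 1 0 0 0.003
3 1 0.7 0.8 0.9 0 1 0 0.003
"""
        path = tmp_path / "dump.liggghts"
        path.write_text(dump)
        [snap] = read_liggghts_dump(path, timestep_dt=1e-5, rpm=30.0)
        assert snap.time == pytest.approx(0.01)
        assert list(snap.ids) == [1, 2, 3]     # sorted by id
        assert list(snap.labels) == [2, 1, 1]
        assert snap.positions[0, 0] == pytest.approx(0.4)
        assert snap.velocities[1, 2] == pytest.approx(-1.0)


# ----------------------------------------------------------------- pipeline
FAST_PIPELINE = dict(
    seed=3, n_runs=14, curve_noise_sd=0.005, curve_n_points=80,
    curve_duration_frac=0.85,
    forecast_kwargs={"p_max": 2, "d_max": 1, "q_max": 1, "patience": 2},
    surrogate_methods=("elastic_net", "plsr"),
)


class TestPipeline:
    def test_synthetic_stages_produce_table_and_report(self, tmp_path):
        config = PipelineConfig(**FAST_PIPELINE)
        artifacts = run_pipeline(config, tmp_path / "run")
        assert "dem_snapshots" not in artifacts      # DEM never invoked
        table = artifacts["table"]
        excluded = table.metadata["n_excluded_no_crossing"]
        assert table.n_rows + excluded == 14
        assert table.n_rows >= 10
        report = artifacts["surrogate_report"]
        assert set(report.methods) == {"elastic_net", "plsr"}
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["seed"] == 3
        assert len(manifest["files"]) >= 14 * 2 + 2

    def test_rerun_reproduces_file_hashes(self, tmp_path):
        config = PipelineConfig(**FAST_PIPELINE)
        run_pipeline(config, tmp_path / "a")
        run_pipeline(config, tmp_path / "b")
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert ma["files"] == mb["files"]

    def test_surrogate_without_forecast_rejected(self, tmp_path):
        config = PipelineConfig(stages=("synth_curves", "surrogate"),
                                n_runs=12)
        with pytest.raises(ValueError, match="forecast"):
            run_pipeline(config, tmp_path / "bad")

    def test_dem_stage_yields_decreasing_psi(self, tmp_path):
        from scipy.stats import spearmanr
        config = PipelineConfig(
            seed=1, stages=("dem",),
            material=dict(desk_params(n_particles=500, rpm=90.0,
                                      cake_height=0.03).as_dict()),
            geometry={"vessel_radius": 0.04, "blade_count": 2,
                      "blade_height": 0.008},
            duration_s=2.0, snapshot_interval_s=0.05)
        artifacts = run_pipeline(config, tmp_path / "dem")
        series = artifacts["series"][0]
        rho = spearmanr(series.times, series.psi_bulk).statistic
        assert rho < 0  # the bed mixes: psi trends downward
        assert (tmp_path / "dem" / "trajectory.csv").exists()


# ---------------------------------------------------------------------- cli
class TestCLI:
    def test_synth_curve_and_forecast_commands(self, tmp_path):
        runner = CliRunner()
        curve = tmp_path / "curve.csv"
        res = runner.invoke(cli_main, [
            "synth-curve", "--psi0", "1.9", "--rate-k", "0.2", "--rpm", "30",
            "--n-points", "80", "--duration", "25", "--out", str(curve)])
        assert res.exit_code == 0, res.output
        report = tmp_path / "report.json"
        res = runner.invoke(cli_main, [
            "forecast", "--series", str(curve), "--cutoff", "1.1",
            "--p-max", "3", "--out", str(report)])
        assert res.exit_code == 0, res.output
        payload = json.loads(report.read_text())
        assert payload["cutoff_psi"] == 1.1
        assert payload["t_end"] is not None

    def test_synth_table_and_surrogate_commands(self, tmp_path):
        runner = CliRunner()
        table = tmp_path / "table.csv"
        res = runner.invoke(cli_main, [
            "synth-table", "--n-rows", "14", "--noise-sd", "0.1",
            "--seed", "2", "--out", str(table)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "sur.json"
        res = runner.invoke(cli_main, [
            "surrogate", "--table", str(table), "--methods", "plsr",
            "--seed", "2", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert "plsr" in json.loads(out.read_text())["methods"]


# -------------------------------------------------------------------- plots
class TestPlots:
    def test_design_space_violin_has_nine_panels(self, tmp_path):
        from granumix.plots import plot_design_space
        table = generate_design_table(SyntheticDesignSpec(n_rows=20, seed=1,
                                                          noise_sd=0.1))
        fig = plot_design_space(table, path=tmp_path / "violins.png")
        assert len(fig.axes) == 9
        assert (tmp_path / "violins.png").exists()

    def test_series_plot_draws_regions_and_cutoff(self):
        from granumix.plots import plot_series
        spec = SyntheticCurveSpec(noise_sd=0.01, n_points=50, seed=2)
        series = generate_mixing_curve(spec)
        fig = plot_series(series, cutoff=1.1)
        assert fig.axes[0].lines  # at least the bulk trace
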