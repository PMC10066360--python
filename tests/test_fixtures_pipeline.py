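"""Fixture generation, the CLI surface, and the end-to-end pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from tokengame import (
    STUDY_CONFIG,
    RunConfig,
    cumulative_matrix,
    load_config,
    load_game,
    locked_pair_game,
    make_fixtures,
    null_fixture_game,
    run_pipeline,
    toy4_game,
)
from tokengame.cli import main


class TestFixtures:
    def test_toy4_fixture_validates_and_matches_hand_count(self, tmp_path):
        written = make_fixtures(seed=0, out_dir=tmp_path)
        d = written["toy4"]
        game = load_game(d / "players.csv", d / "allocations.csv",
                         load_config(d / "config.yaml"))
        assert np.array_equal(cumulative_matrix(game, 3).Y,
                              cumulative_matrix(toy4_game(), 3).Y)

    def test_fixtures_regenerate_bit_identically(self, tmp_path):
        a = make_fixtures(seed=9, out_dir=tmp_path / "a")
        b = make_fixtures(seed=9, out_dir=tmp_path / "b")
        for name in a:
            for fname in ("players.csv", "allocations.csv", "config.yaml"):
                assert (a[name] / fname).read_text() == (b[name] / fname).read_text()

    def test_locked_pair_mutual_counts_are_40(self):
        game = locked_pair_game(seed=4)
        Y = cumulative_matrix(game, 40).Y
        assert Y[2, 7] == 40 and Y[7, 2] == 40

    def test_null_fixture_is_study_scale(self):
        game = null_fixture_game(seed=4)
        assert game.config == STUDY_CONFIG


class TestCli:
    def test_fixtures_explore_fit_round_trip(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, ["fixtures", "--seed", "1",
                                   "--out", str(tmp_path / "fx")])
        assert res.exit_code == 0, res.output
        d = tmp_path / "fx" / "toy4"
        game_args = ["--players", str(d / "players.csv"),
                     "--allocations", str(d / "allocations.csv"),
                     "--config", str(d / "config.yaml")]

        res = runner.invoke(main, ["explore", *game_args,
                                   "--out", str(tmp_path / "ex")])
        assert res.exit_code == 0, res.output
        props = pd.read_csv(tmp_path / "ex" / "proportions.csv")
        assert props.loc[props.t == 3, ["ingroup", "outgroup", "self"]].iloc[0].tolist() \
            == pytest.approx([0.5, 1 / 3, 1 / 6])

        res = runner.invoke(main, ["fit", *game_args, "--model", "reciprocity",
                                   "--round", "3", "--out", str(tmp_path / "fit.csv")])
        assert res.exit_code == 0, res.output
        fit = pd.read_csv(tmp_path / "fit.csv")
        assert fit.rho.iloc[0] == pytest.approx(17 / 41)

    def test_simulate_writes_replicates(self, tmp_path):
        runner = CliRunner()
        fxd = tmp_path / "fx"
        runner.invoke(main, ["fixtures", "--seed", "1", "--out", str(fxd)])
        res = runner.invoke(main, [
            "simulate", "--config", str(fxd / "toy4" / "config.yaml"),
            "--seed", "2", "--replicates", "3", "--out", str(tmp_path / "sims")])
        assert res.exit_code == 0, res.output
        dirs = sorted(p.name for p in (tmp_path / "sims").iterdir())
        assert dirs == ["replicate_0000", "replicate_0001", "replicate_0002"]

    def test_null_compare_and_influence_smoke(self, tmp_path):
        runner = CliRunner()
        fxd = tmp_path / "fx"
        runner.invoke(main, ["fixtures", "--seed", "1", "--out", str(fxd)])
        d = fxd / "toy4"
        game_args = ["--players", str(d / "players.csv"),
                     "--allocations", str(d / "allocations.csv"),
                     "--config", str(d / "config.yaml")]
        res = runner.invoke(main, ["null-compare", *game_args, "--replicates", "50",
                                   "--seed", "3", "--rounds", "3",
                                   "--out", str(tmp_path / "nc")])
        assert res.exit_code == 0, res.output
        report = pd.read_csv(tmp_path / "nc" / "null_comparison.csv")
        assert set(report.term) == {"alpha", "rho", "gamma"}

        res = runner.invoke(main, ["influence", *game_args, "--replicates", "10",
                                   "--seed", "3", "--out", str(tmp_path / "inf.csv")])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(tmp_path / "inf.csv")
        assert table.d_rho_std.mean() == pytest.approx(1.0)

    def test_viz_exports_graphml(self, tmp_path):
        runner = CliRunner()
        fxd = tmp_path / "fx"
        runner.invoke(main, ["fixtures", "--seed", "1", "--out", str(fxd)])
        d = fxd / "toy4"
        res = runner.invoke(main, [
            "viz", "--players", str(d / "players.csv"),
            "--allocations", str(d / "allocations.csv"),
            "--config", str(d / "config.yaml"),
            "--seed", "3", "--out", str(tmp_path / "net")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "net.graphml").exists()


class TestPipeline:
    def test_fast_run_on_toy4_emits_every_output(self, tmp_path):
        cfg = RunConfig(seed=5, out_dir=str(tmp_path / "run"), fast=True,
                        null_replicates=40, influence_replicates=10)
        paths = run_pipeline(toy4_game(), cfg)
        for key in ("proportions", "pairs", "fits", "null_draws",
                    "null_comparison", "influence", "network", "manifest"):
            assert paths[key].exists(), key
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["null_replicates_used"] == 40

    def test_rerun_is_numerically_identical(self, tmp_path):
        cfg_a = RunConfig(seed=5, out_dir=str(tmp_path / "a"), fast=True,
                          null_replicates=30, influence_replicates=5)
        cfg_b = RunConfig(seed=5, out_dir=str(tmp_path / "b"), fast=True,
                          null_replicates=30, influence_replicates=5)
        pa = run_pipeline(toy4_game(), cfg_a)
        pb = run_pipeline(toy4_game(), cfg_b)
        for key in ("proportions", "fits", "null_comparison", "influence"):
            assert pa[key].read_text() == pb[key].read_text()
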