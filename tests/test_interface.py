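import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from catelute.cli import main
from catelute.io import RunManifest, read_release_csv, write_release_csv
from catelute.model_core import ReleaseProfile


def _profile(sample_id="s1", **meta):
    return ReleaseProfile(
        sample_id=sample_id,
        times=np.array([1.0, 2.0, 4.0]),
        release_per_area=np.array([0.5, 1.25, 2.0]),
        metadata=meta,
    )


class TestReleaseCsv:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "release.csv"
        original = [_profile("a", condition="control", size="14Fr"), _profile("b")]
        write_release_csv(original, path)
        back = read_release_csv(path)
        assert [p.sample_id for p in back] == ["a", "b"]
        for orig, rt in zip(original, back):
            assert np.array_equal(orig.times, rt.times)
            assert np.array_equal(orig.release_per_area, rt.release_per_area)
        assert back[0].metadata["condition"] == "control"

    def test_empty_file_returns_empty_list_with_warning(self, tmp_path, caplog):
        path = tmp_path / "empty.csv"
        write_release_csv([], path)
        with caplog.at_level("WARNING"):
            assert read_release_csv(path) == []
        assert any("empty" in r.message for r in caplog.records)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,time_h\na,1.0\n")
        with pytest.raises(ValueError, match="release_ug_cm2"):
            read_release_csv(path)

    def test_non_numeric_cell_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,time_h,release_ug_cm2\na,1.0,0.5\na,2.0,oops\n")
        with pytest.raises(ValueError, match=r"\[2\]"):
            read_release_csv(path)

    def test_duplicate_sample_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,time_h,release_ug_cm2\na,1.0,0.5\na,1.0,0.6\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_release_csv(path)

    def test_out_of_order_rows_rejected_naming_first_bad_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,time_h,release_ug_cm2\na,1.0,0.5\na,4.0,2.0\na,2.0,1.0\n"
        )
        with pytest.raises(ValueError, match="row: 3"):
            read_release_csv(path)


class TestManifest:
    def test_round_trip(self, tmp_path):
        m = RunManifest(subcommand="simulate", config={"size": "14Fr"}, seed=3, artifacts=["a.csv"], duration_s=1.2)
        m.write(tmp_path / "manifest.json")
        back = RunManifest.read(tmp_path / "manifest.json")
        assert back == m


@pytest.fixture()
def runner():
    return CliRunner()


# fast numerics via config file so CLI tests stay cheap
_FAST_CFG = """\
n_nodes: 51
dt_load_h: 0.05
dt_rest_h: 0.25
dt_delivery_h: 0.5
"""


def _write_cfg(tmp_path, extra=""):
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(_FAST_CFG + extra)
    return str(cfg)


class TestCli:
    def test_simulate_writes_artifacts_and_plateau(self, runner, tmp_path):
        cfg = _write_cfg(tmp_path)
        out = tmp_path / "run"
        res = runner.invoke(main, ["simulate", "--config", cfg, "--out", str(out), "--size", "14Fr", "--condition", "control"])
        assert res.exit_code == 0, res.output
        profiles = read_release_csv(out / "release.csv")
        assert profiles[0].release_per_area[-1] == pytest.approx(30.0, rel=0.25)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["subcommand"] == "simulate"
        assert (out / "wall.csv").exists() and (out / "reservoir.csv").exists()

    def test_simulate_deterministic_outputs(self, runner, tmp_path):
        cfg = _write_cfg(tmp_path)
        outs = []
        for name in ("r1", "r2"):
            out = tmp_path / name
            res = runner.invoke(main, ["simulate", "--config", cfg, "--out", str(out)])
            assert res.exit_code == 0, res.output
            outs.append((out / "release.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_generate_seeded_byte_identical(self, runner, tmp_path):
        cfg = _write_cfg(tmp_path)
        payloads = []
        for name in ("g1", "g2"):
            out = tmp_path / name
            res = runner.invoke(main, ["generate", "--config", cfg, "--seed", "1", "--out", str(out)])
            assert res.exit_code == 0, res.output
            payloads.append((out / "dataset.csv").read_bytes())
        assert payloads[0] == payloads[1]

    def test_generate_unknown_config_key_rejected(self, runner, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("bogus_key: 1\n")
        res = runner.invoke(main, ["generate", "--config", str(cfg)])
        assert res.exit_code == 2
        assert "bogus_key" in res.output

    def test_fit_on_generated_dataset_converges(self, runner, tmp_path):
        """Closed loop through the CLI: generate -> fit recovers the generating
        parameters and reports convergence."""
        out_gen = tmp_path / "gen"
        res = runner.invoke(main, ["generate", "--seed", "5", "--noise-scale", "0.0", "--out", str(out_gen)])
        assert res.exit_code == 0, res.output
        out_fit = tmp_path / "fit"
        res = runner.invoke(main, ["fit", "--data", str(out_gen / "dataset.csv"), "--out", str(out_fit)])
        assert res.exit_code == 0, res.output
        report = (out_fit / "fit_report.txt").read_text()
        assert "converged = true" in report
        d_line = [ln for ln in report.splitlines() if ln.startswith("D_cm2_per_h")][0]
        assert float(d_line.split("=")[1]) == pytest.approx(1.744e-5, rel=0.05)
        assert (out_fit / "fitted_curves.csv").exists()

    def test_sweep_writes_long_format(self, runner, tmp_path):
        cfg = _write_cfg(tmp_path)
        out = tmp_path / "sw"
        res = runner.invoke(
            main,
            ["sweep", "--config", cfg, "--loads", "6,12", "--rests", "0,12", "--delivery", "24", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        table = pd.read_csv(out / "sweep.csv")
        assert list(table.columns) == ["load_h", "rest_h", "time_h", "release_ug_cm2"]
        assert set(zip(table.load_h, table.rest_h)) == {(6, 0), (6, 12), (12, 0), (12, 12)}

    def test_report_renders_figure_and_summary(self, runner, tmp_path):
        cfg = _write_cfg(tmp_path)
        out = tmp_path / "rep"
        res = runner.invoke(main, ["report", "--config", cfg, "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "report.png").stat().st_size > 0
        assert "final_release_ug_cm2" in (out / "summary.txt").read_text()

    def test_unknown_subcommand_usage_error(self, runner):
        res = runner.invoke(main, ["frobnicate"])
        assert res.exit_code != 0
        assert "Usage" in res.output or "No such command" in res.output
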