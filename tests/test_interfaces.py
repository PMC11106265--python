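"""Delimited I/O, epoch containers, pipeline driver, and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from riskreact.cli import main as cli_main
from riskreact.decode import EpochSet
from riskreact.io import (
    SchemaError,
    read_choices,
    read_covariate,
    read_probes,
    write_choices,
    write_probes,
)
from riskreact.models import ModelParams, simulate_choices
from riskreact.pipeline import load_config, run_pipeline
from riskreact.rtprobe import ProbeTrial


TINY_COHORT = {
    "n_subjects": 6,
    "n_subjects_rt": 12,
    "n_sensors": 10,
    "localizer_times_ms": list(range(10, 151, 20)),
    "task_times_ms": list(range(0, 151, 20)),
    "n_reps_per_block": 8,
    "n_localizer_blocks": 2,
    "code_center_ms": 80.0,
    "task_locus_ms": 80.0,
}


@pytest.fixture(scope="module")
def choices(design):
    params = ModelParams(
        "additive",
        {"beta_gain": 0.2, "beta_loss": -0.2, "beta_prob": 4.0, "beta_rew": 0.06},
    )
    return {
        0: simulate_choices(params, design, seed=0),
        1: simulate_choices(params, design, seed=1),
    }


class TestBehaviorIO:
    def test_choices_roundtrip(self, tmp_path, choices):
        path = tmp_path / "choices.tsv"
        write_choices(choices, path)
        back = read_choices(path)
        assert set(back) == {0, 1}
        for s in (0, 1):
            assert [o.accept for o in back[s]] == [o.accept for o in choices[s]]
            assert [o.trial.r_O1 for o in back[s]] == pytest.approx(
                [o.trial.r_O1 for o in choices[s]]
            )

    def test_missing_column_names_offender(self, tmp_path, choices):
        path = tmp_path / "choices.tsv"
        write_choices(choices, path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t").drop(columns=["accept"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="accept"):
            read_choices(path)

    def test_probe_roundtrip_and_rt_validation(self, tmp_path):
        trials = [
            ProbeTrial(0, "O1", 0.8, 0.2, 50.0, 10.0, 0.4),
            ProbeTrial(0, "OS", np.nan, np.nan, 40.0, np.nan, 0.5),
            ProbeTrial(1, "O2", 0.4, 0.6, 20.0, 60.0, -0.1),
        ]
        path = tmp_path / "probes.tsv"
        write_probes(trials, path)
        with pytest.warns(UserWarning, match="rejected 1"):
            back = read_probes(path)
        assert len(back) == 2  # negative-RT row dropped
        assert back[0].p_probed == pytest.approx(0.8)

    def test_covariate_reader(self, tmp_path):
        path = tmp_path / "cov.tsv"
        path.write_text("subject\tvalue\n0\t61.5\n1\t48.0\n")
        series = read_covariate(path)
        assert series.loc[0] == 61.5
        with pytest.raises(SchemaError, match="score"):
            read_covariate(path, column="score")


class TestEpochContainer:
    def test_roundtrip(self, tmp_path, rng):
        epochs = EpochSet(
            data=rng.normal(0, 1, (4, 6, 10)),
            event_labels=np.array(["O1", "O2", "OS", "P1", "P2", "P3", "P4",
                                   "ITI", "ITI", "O1"], dtype=object),
            times_ms=np.arange(10, 70, 10.0),
        )
        epochs.save(tmp_path / "e.h5")
        back = EpochSet.load(tmp_path / "e.h5")
        assert np.allclose(back.data, epochs.data)
        assert list(back.event_labels) == list(epochs.event_labels)
        assert np.allclose(back.times_ms, epochs.times_ms)


class TestPipeline:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config({"not_a_key": 1})
        a = load_config({"seed": 3})
        b = load_config({"seed": 3})
        assert a.hash == b.hash
        assert a.hash != load_config({"seed": 4}).hash

    def test_run_deterministic_and_structured(self, tmp_path):
        cfg = load_config({
            "seed": 2,
            "cohort": TINY_COHORT,
            "n_perm": 100,
            "em_max_iter": 30,
            "run_probe_arm": False,
        })
        rep1 = run_pipeline(cfg, out_dir=tmp_path / "run1")
        rep2 = run_pipeline(cfg)
        assert rep1["group_stats"] == rep2["group_stats"]
        assert rep1["config_hash"] == cfg.hash
        written = json.loads((tmp_path / "run1" / "report.json").read_text())
        assert written["group_stats"].keys() == rep1["group_stats"].keys()
        for key, entry in rep1["group_stats"].items():
            assert 0.0 < entry["p_fwe"] <= 1.0
            assert np.isfinite(entry["peak_t"])


class TestCLI:
    def test_taskgen(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "design.tsv"
        result = runner.invoke(
            cli_main, ["taskgen", "--seed", "0", "--variant", "meg", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert "288 decision trials" in result.output
        assert out.exists() and out.with_suffix(".tsv.json").exists()

    def test_fit_command(self, tmp_path, choices):
        table = tmp_path / "choices.tsv"
        write_choices(choices, table)
        out = tmp_path / "fit.json"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["fit", "--model", "additive", "--choices", str(table),
             "--seed", "0", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert payload["model"] == "additive"
        assert len(payload["subjects"]) == 2
        assert np.isfinite(payload["ibic"])

    def test_rtprobe_command(self, tmp_path):
        trials = [ProbeTrial(0, "O1", 0.8, 0.2, 50.0, 10.0, 0.3 + 0.01 * k)
                  for k in range(5)]
        trials += [ProbeTrial(0, "O2", 0.2, 0.8, 10.0, 50.0, 0.5 + 0.01 * k)
                   for k in range(5)]
        path = tmp_path / "probes.tsv"
        write_probes(trials, path)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["rtprobe", "--probes", str(path)])
        assert result.exit_code == 0, result.output
        assert "beta_prob_rt" in result.output
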