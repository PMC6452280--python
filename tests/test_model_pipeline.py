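import json

import pytest
from click.testing import CliRunner

from glucaudit import TranscriptionAudit
from glucaudit.cli import main as cli_main
from glucaudit.errors import ConfigError, DataIntegrityError
from glucaudit.pipeline import load_generator_config, run_pipeline
from glucaudit.records import write_stream
from glucaudit.stats import render_report
from glucaudit.synthetic import GeneratorConfig


@pytest.fixture(scope="module")
def fitted(small_study):
    model = TranscriptionAudit(small_study.meters, small_study.entries, small_study.episodes)
    return model.fit()


def test_counts_conserved_per_source(fitted, small_study):
    n = len(small_study.meters)
    for s in ("paper_log", "flow_sheet"):
        matched = sum(r.matched(s) for r in fitted.linkage.results)
        assert matched + fitted.undocumented[s]["n"] == n


def test_taxonomy_partitions_documented_in_both(fitted):
    cl = fitted.classified
    both = cl[cl.paper_documented & cl.flow_documented]
    assert len(both) == fitted.undocumented["documented_both"]
    assert both.label.isin(
        ["no_error", "paper_log_error", "flow_sheet_error", "both_error"]
    ).all()
    counts = both.label.value_counts()
    assert counts.sum() == len(both)


def test_per_source_errors_equal_nonzero_discrepancies(fitted):
    cl = fitted.classified
    assert fitted.errors["paper_log"]["errors"] == int(
        (cl.paper_documented & (cl.paper_discrepancy != 0)).sum()
    )
    assert fitted.errors["flow_sheet"]["errors"] == int(
        (cl.flow_documented & (cl.flow_discrepancy != 0)).sum()
    )


def test_summary_renders_every_block(fitted):
    text = fitted.summary()
    for token in ("paper_log", "flow_sheet", "chi-square", "Docking latency",
                  "Insulin errors", "after discharge"):
        assert token in text


def test_report_percentages_recompute_from_stored_fractions(fitted):
    for s in ("paper_log", "flow_sheet", "both"):
        u = fitted.undocumented[s]
        assert u["pct"] == pytest.approx(100.0 * u["n"] / fitted.undocumented["n_tests"])
        e = fitted.errors[s]
        if e["analyzed"]:
            assert e["pct"] == pytest.approx(100.0 * e["errors"] / e["analyzed"])


def test_render_report_rejects_inconsistent_universes(fitted, small_study):
    with pytest.raises(DataIntegrityError, match="disagree"):
        render_report(
            small_study.episodes,
            small_study.meters[:-1],  # one record short of the tallies
            fitted.undocumented,
            fitted.errors,
            fitted.shift_tests,
            fitted.insulin,
            fitted.docking,
            0,
            fitted.patients_affected,
        )


# ---------------------------------------------------------------- pipeline

def test_pipeline_persists_all_artifacts_and_is_reproducible(tmp_path):
    cfg = GeneratorConfig(n_patients=20)
    res1 = run_pipeline(tmp_path / "run1", seed=77, config=cfg)
    res2 = run_pipeline(tmp_path / "run2", seed=77, config=cfg)
    for name in ("meters.csv", "entries.csv", "episodes.csv", "groundtruth.csv",
                 "matches.csv", "audit.csv", "report.txt", "manifest.json"):
        assert (tmp_path / "run1" / name).exists()
    assert (tmp_path / "run1" / "report.txt").read_bytes() == (
        tmp_path / "run2" / "report.txt"
    ).read_bytes()
    assert res1.summary() == res2.summary()


def test_pipeline_on_user_csvs_equals_direct_fit(tmp_path, small_study):
    indir = tmp_path / "in"
    indir.mkdir()
    write_stream(small_study.meters, indir / "meters.csv", "meter")
    write_stream(small_study.entries, indir / "entries.csv", "entry")
    write_stream(small_study.episodes, indir / "episodes.csv", "episode")
    res = run_pipeline(
        tmp_path / "out",
        seed=1,
        meters_csv=indir / "meters.csv",
        entries_csv=indir / "entries.csv",
        episodes_csv=indir / "episodes.csv",
    )
    direct = TranscriptionAudit(
        small_study.meters, small_study.entries, small_study.episodes
    ).fit()
    assert res.summary() == direct.summary()
    manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
    assert manifest["synthetic"] is False


def test_rerun_from_persisted_intermediates_reproduces_report(tmp_path):
    out1 = tmp_path / "first"
    run_pipeline(out1, seed=5, config=GeneratorConfig(n_patients=15))
    out2 = tmp_path / "second"
    run_pipeline(
        out2,
        seed=5,
        meters_csv=out1 / "meters.csv",
        entries_csv=out1 / "entries.csv",
        episodes_csv=out1 / "episodes.csv",
    )
    assert (out1 / "report.txt").read_text() == (out2 / "report.txt").read_text()


def test_malformed_generator_config_names_bad_key(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("n_patients: 10\nbogus_knob: 3\n")
    with pytest.raises(ConfigError, match="bogus_knob"):
        load_generator_config(p)


def test_partial_csv_inputs_rejected(tmp_path):
    with pytest.raises(ConfigError, match="all of"):
        run_pipeline(tmp_path, seed=1, meters_csv="meters.csv")


# ---------------------------------------------------------------- CLI

def test_cli_generate_then_report(tmp_path):
    runner = CliRunner()
    out = tmp_path / "data"
    r = runner.invoke(cli_main, ["generate", "--seed", "3", "--out", str(out)])
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        [
            "report",
            "--meters", str(out / "meters.csv"),
            "--entries", str(out / "entries.csv"),
            "--episodes", str(out / "episodes.csv"),
        ],
    )
    assert r.exit_code == 0, r.output
    assert "transcription-error audit" in r.output


def test_cli_sample_and_link(tmp_path):
    runner = CliRunner()
    out = tmp_path / "data"
    runner.invoke(cli_main, ["generate", "--seed", "4", "--out", str(out)])
    r = runner.invoke(
        cli_main,
        ["sample", "--fraction", "0.2", "--seed", "2",
         "--meters", str(out / "meters.csv"), "--out", str(tmp_path / "sampled.csv")],
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        ["link", "--meters", str(out / "meters.csv"),
         "--entries", str(out / "entries.csv"), "--out", str(tmp_path / "matches.csv")],
    )
    assert r.exit_code == 0, r.output
    assert (tmp_path / "matches.csv").exists()
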