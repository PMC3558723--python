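"""End-to-end survey orchestration, configuration and CLI."""

import filecmp

import pandas as pd
import pytest
from click.testing import CliRunner

from tcrsurvey import fixtures as fx
from tcrsurvey.cli import main as cli_main
from tcrsurvey.config import SurveyConfig
from tcrsurvey.errors import ConfigError, ManifestError
from tcrsurvey.survey import run_survey


@pytest.fixture(scope="module")
def survey_inputs(tmp_path_factory):
    """All five scenarios written into one structures directory + manifest."""
    root = tmp_path_factory.mktemp("survey")
    sdir = root / "structures"
    sdir.mkdir()
    tables, truths = [], {}
    for name in fx.SCENARIOS:
        bundle = fx.make_crystal_scenario(name, seed=2)
        fx.write_scenario(bundle, sdir)
        tables.append(bundle.manifest.table)
        truths[bundle.entry_id] = bundle.truth
    manifest_path = root / "manifest.tsv"
    pd.concat(tables, ignore_index=True).to_csv(manifest_path, sep="\t", index=False)
    return dict(root=root, sdir=sdir, manifest=manifest_path, truths=truths)


def test_survey_rows_match_fixture_truth(survey_inputs):
    res = run_survey(
        survey_inputs["manifest"], survey_inputs["sdir"],
        out_dir=survey_inputs["root"] / "out",
        strandmap_dir=survey_inputs["sdir"],
    )
    survey = res["survey"].set_index("entry_id")
    assert len(survey) == len(fx.SCENARIOS)
    for entry_id, truth in survey_inputs["truths"].items():
        row = survey.loc[entry_id]
        assert row["status"] == "ok"
        assert truth.expected_verdict in row["verdict"]
        assert row["n_complexes"] == truth.n_complexes
        expected_m2 = 1 if truth.expected_model2_consistent else 0
        assert row["n_model2_consistent"] == expected_m2
    # exactly the planted-dimer scenarios yield model-consistent pairs
    assert survey["n_model2_consistent"].sum() == 2


def test_rerun_is_byte_identical(survey_inputs):
    for run in ("rep1", "rep2"):
        run_survey(
            survey_inputs["manifest"], survey_inputs["sdir"],
            out_dir=survey_inputs["root"] / run,
            strandmap_dir=survey_inputs["sdir"],
        )
    for name in ("survey.tsv", "contacts.tsv", "assessments.tsv"):
        assert filecmp.cmp(
            survey_inputs["root"] / "rep1" / name,
            survey_inputs["root"] / "rep2" / name,
            shallow=False,
        )


def test_survey_independent_of_manifest_row_order(survey_inputs):
    shuffled_path = survey_inputs["root"] / "shuffled.tsv"
    table = pd.read_csv(survey_inputs["manifest"], sep="\t")
    table.sample(frac=1.0, random_state=13).to_csv(shuffled_path, sep="\t", index=False)
    a = run_survey(survey_inputs["manifest"], survey_inputs["sdir"],
                   strandmap_dir=survey_inputs["sdir"])
    b = run_survey(shuffled_path, survey_inputs["sdir"],
                   strandmap_dir=survey_inputs["sdir"])
    assert a["survey"].equals(b["survey"])
    assert a["contacts"].equals(b["contacts"])


def test_missing_structure_reported_as_skipped(survey_inputs, tmp_path):
    table = pd.read_csv(survey_inputs["manifest"], sep="\t")
    extra = table.iloc[:4].copy()
    extra["entry_id"] = "TOY-MISSING"
    path = tmp_path / "with_missing.tsv"
    pd.concat([table, extra], ignore_index=True).to_csv(path, sep="\t", index=False)
    res = run_survey(path, survey_inputs["sdir"], strandmap_dir=survey_inputs["sdir"])
    row = res["survey"].set_index("entry_id").loc["TOY-MISSING"]
    assert row["status"] == "skipped" and row["verdict"] == "skipped"
    assert len(res["survey"]) == len(fx.SCENARIOS) + 1


def test_empty_manifest_is_hard_error(tmp_path, survey_inputs):
    path = tmp_path / "empty.tsv"
    path.write_text(
        "entry_id\tcomplex_index\tchain_id\tmolecule\tdomain_name\tstart\tend\tspecies\n"
    )
    with pytest.raises(ManifestError, match="empty"):
        run_survey(path, survey_inputs["sdir"])


def test_provenance_sidecar_records_config_and_checksums(survey_inputs):
    import json

    out = survey_inputs["root"] / "prov"
    run_survey(survey_inputs["manifest"], survey_inputs["sdir"], out_dir=out,
               strandmap_dir=survey_inputs["sdir"])
    sidecar = json.loads((out / "provenance.json").read_text())
    assert sidecar["config"]["contact_cutoff"] == 4.5
    assert len(sidecar["structure_checksums_sha256"]) == len(fx.SCENARIOS)


def test_config_file_round_trip(tmp_path):
    path = tmp_path / "survey.cfg"
    path.write_text(
        "# thresholds\ncontact_cutoff = 4.0\nmate_radius = 6.0\n"
        "orientation_tilt_boundary = 40\n"
    )
    cfg = SurveyConfig.from_file(path)
    assert cfg.contact_cutoff == 4.0
    assert cfg.orientation_tilt_boundary == 40.0
    assert cfg.symmetry_min_angle == 160.0  # untouched default


def test_config_unknown_key_named_in_error(tmp_path):
    path = tmp_path / "bad.cfg"
    path.write_text("contact_radius = 4.0\n")
    with pytest.raises(ConfigError, match="contact_radius"):
        SurveyConfig.from_file(path)


def test_config_requires_mate_radius_above_cutoff():
    with pytest.raises(ConfigError, match="mate_radius"):
        SurveyConfig(contact_cutoff=5.0, mate_radius=4.5)


def test_cli_simulate_then_survey_then_glyco(tmp_path):
    runner = CliRunner()
    out = tmp_path / "sim"
    r = runner.invoke(
        cli_main, ["simulate", "--scenario", "upright-2fold-dimer", "--seed", "4",
                   "--out", str(out)],
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        ["survey", "--manifest", str(out / "TOY-UPRIGHT-2FOLD-DIMER_manifest.tsv"),
         "--structures", str(out), "--strandmaps", str(out),
         "--out", str(tmp_path / "report")],
    )
    assert r.exit_code == 0, r.output
    survey = pd.read_csv(tmp_path / "report" / "survey.tsv", sep="\t")
    assert survey.loc[0, "verdict"] == "Cα forms dimer"

    fasta = tmp_path / "seqs.fasta"
    fasta.write_text(">s1\nAAANVSAAA\n")
    r = runner.invoke(cli_main, ["glyco", "--fasta", str(fasta)])
    assert r.exit_code == 0, r.output
    assert "NVS" in r.output and "True" in r.output
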