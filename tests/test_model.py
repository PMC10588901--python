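"""Model/Results surface, report bundle, shipped studies, CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from typer.testing import CliRunner

from sevcms.cli import app
from sevcms.datasets import DatasetError, StudyConfig, combine_tables
from sevcms.model import CompositeSeverityModel, run_workflow, stage_seed
from sevcms.simulate import default_three_group_spec, generate_dataset
from sevcms.studies import (
    adult_epilepsy_config, make_adult_tables, make_young_table,
    young_genetic_config,
)


@pytest.fixture(scope="module")
def demo():
    table, gt = generate_dataset(default_three_group_spec(seed=8))
    cfg = StudyConfig(
        group_burden_map={"naive": "exclude", "sham": 0, "treated": 1},
        k=3, seed=8)
    results = CompositeSeverityModel(table, cfg).fit()
    return table, gt, results


def test_stage_seeds_distinct_and_in_range():
    s1 = stage_seed(123, "ranking")
    s2 = stage_seed(123, "cluster")
    assert s1 != s2
    assert 0 <= s1 < 2 ** 31 - 1 and 0 <= s2 < 2 ** 31 - 1


def test_end_to_end_treated_scores_highest(demo):
    table, gt, results = demo
    meta = results.table_pruned.meta.set_index("animal_id")
    gm = results.composite.scores.groupby(meta["group"]).mean()
    assert gm["treated"] > gm["sham"]
    assert gm["treated"] > gm["naive"]
    tops = results.allocation.top_cluster_sums.set_index("group")["top_clusters_pct"]
    assert tops["treated"] > tops["sham"]


def test_results_shapes_consistent(demo):
    table, _, results = demo
    assert len(results.assignments) == table.n_animals
    assert results.composite.n_selected == results.n_selected_components
    assert results.cluster_model.k == 3
    assert len(results.cluster_model.thresholds) == 2
    assert 0 < results.explained_percent(1) < 100
    assert "Composite severity workflow" in results.summary()
    assert "severity levels are relative" in results.cluster_model.disclaimer


def test_validate_dry_run(demo):
    table, _, results = demo
    info = CompositeSeverityModel(table, results.model.config).validate()
    assert info["n_animals"] == table.n_animals
    assert info["unmapped_groups"] == []


def test_report_bundle_deterministic(tmp_path, demo):
    """Identical seed + input -> byte-identical numeric report."""
    table, _, results = demo
    cfg = results.model.config
    out1, out2 = tmp_path / "r1", tmp_path / "r2"
    CompositeSeverityModel(table, cfg).fit().write_report(out1, plots=False)
    CompositeSeverityModel(table, cfg).fit().write_report(out2, plots=False)
    names1 = sorted(p.name for p in out1.iterdir())
    assert "summary.json" in names1 and "composite_scores.csv" in names1
    for name in names1:
        if name == "timings.json":  # wall-clock, excluded by design
            continue
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name


def test_missing_k_without_elbow_is_error():
    table, _ = generate_dataset(default_three_group_spec(
        n_parameters=2, n_informative=1, missing_rate=0.0, seed=0))
    cfg = StudyConfig(group_burden_map={"naive": "exclude", "sham": 0, "treated": 1},
                      seed=0)
    with pytest.raises(DatasetError, match="config.k"):
        CompositeSeverityModel(table, cfg).fit()


def test_run_workflow_combines_tables():
    tables = make_adult_tables(seed=1)
    results = run_workflow(tables, adult_epilepsy_config(seed=1))
    assert results.table_pruned.n_animals == 98


def test_adult_structural_counts():
    """30 raw parameters -> 22 after preselection -> 17 after pruning."""
    tables = make_adult_tables(seed=0)
    combined = combine_tables(tables)
    assert len(combined.parameters) == 30
    results = CompositeSeverityModel(combined, adult_epilepsy_config()).fit()
    assert len(results.table_preselected.parameters) == 22
    assert len(results.table_pruned.parameters) == 17
    assert results.cluster_model.k == 6
    reasons = {r["parameter"]: r["reason"] for r in results.preselection.removed}
    assert reasons["mgs"] == "missingness"


def test_young_structural_counts():
    """19/20 raw -> 13/14 preselected -> 11/12 pruned (early/late)."""
    for bracket, pre, post in (("early_adolescence", 13, 11),
                               ("late_adolescence", 14, 12)):
        table = make_young_table(bracket)
        assert len(table.parameters) == pre + 6  # + VWR + 5 manual exclusions
        results = CompositeSeverityModel(table, young_genetic_config()).fit()
        assert len(results.table_preselected.parameters) == pre
        assert len(results.table_pruned.parameters) == post
        assert results.cluster_model.k == 4


def test_roc_tables_per_model():
    tables = make_adult_tables(seed=2)
    results = run_workflow(tables, adult_epilepsy_config(seed=2))
    assert set(results.roc_tables) == {"kainate", "hippocampal_kindling",
                                       "amygdala_kindling"}
    for frame in results.roc_tables.values():
        assert ((frame["auc_oriented"] >= 0.5) & (frame["auc_oriented"] <= 1)).all()


# -- CLI ---------------------------------------------------------------------

runner = CliRunner()


def write_demo_inputs(tmp_path):
    table, _ = generate_dataset(default_three_group_spec(seed=4))
    data = tmp_path / "data.csv"
    table.to_csv(data)
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "group_burden_map: {naive: exclude, sham: 0, treated: 1}\nk: 3\nseed: 4\n")
    return data, cfg


def test_cli_run_writes_report(tmp_path):
    data, cfg = write_demo_inputs(tmp_path)
    out = tmp_path / "results"
    res = runner.invoke(app, ["run", "-i", str(data), "-c", str(cfg),
                              "-o", str(out), "--no-plots"])
    assert res.exit_code == 0, res.output
    assert (out / "summary.json").exists()
    assert "Severity clusters: k = 3" in res.output


def test_cli_dry_run(tmp_path):
    data, cfg = write_demo_inputs(tmp_path)
    res = runner.invoke(app, ["run", "-i", str(data), "-c", str(cfg), "--dry-run"])
    assert res.exit_code == 0, res.output
    assert json.loads(res.output)["n_animals"] == 90


def test_cli_bad_input_exit_code(tmp_path):
    res = runner.invoke(app, ["run", "-i", str(tmp_path / "missing.csv")])
    assert res.exit_code == 1


def test_cli_simulate_and_preselect(tmp_path, monkeypatch):
    monkeypatch.chdir(tmp_path)
    res = runner.invoke(app, ["simulate", "--out", "syn.csv", "--truth", "t.json",
                              "--seed", "2"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(app, ["preselect", "-i", "syn.csv"])
    assert res.exit_code == 0, res.output
    assert Path("preselected.csv").exists()
    truth = json.loads(Path("t.json").read_text())
    assert truth["severity_order"] == ["naive", "sham", "treated"]
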