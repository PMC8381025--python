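"""Simulation-study and analysis workflows: determinism, shapes, recomputation."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from strandmastery import (
    QMatrix,
    ResponseMatrix,
    SimulationCondition,
    StudyConfig,
    consistency,
    generate_form,
    exam_like_condition,
    run_analysis,
    run_condition,
    run_simulation_study,
    score_correlations,
)
from strandmastery.cli import main as cli_main
from strandmastery.rasch import marginal_deviance
from strandmastery.workflow import condition_seed

SMALL = dict(rho_grid=[0.0, 0.5], strand_sizes=[4, 6], n_persons=150, n_forms=2, seed=11)


def _dir_files(d: Path):
    return sorted(p.name for p in d.iterdir())


class TestStudyConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("mode: simulate\nrho_grid: [0.0, 0.9]\nn_forms: 3\nseed: 5\n")
        cfg = StudyConfig.from_yaml(p)
        assert cfg.rho_grid == [0.0, 0.9]
        assert cfg.n_forms == 3

    def test_invalid_grid_fails_before_compute(self):
        with pytest.raises(ValueError):
            StudyConfig(rho_grid=[0.0, 1.5])
        with pytest.raises(ValueError):
            StudyConfig(mode="frobnicate")

    def test_analyze_requires_existing_files(self):
        with pytest.raises(FileNotFoundError):
            StudyConfig(mode="analyze", responses="no.csv", qmatrix="no.csv")


class TestSimulationStudy:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = StudyConfig(**SMALL)
        run_simulation_study(cfg, out_dir=tmp_path / "a")
        run_simulation_study(cfg, out_dir=tmp_path / "b")
        names = _dir_files(tmp_path / "a")
        assert names == _dir_files(tmp_path / "b")
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_single_form_matches_direct_condition_run(self):
        cfg = StudyConfig(rho_grid=[0.3], strand_sizes=[4, 6], n_persons=150, n_forms=1, seed=9)
        (study_res,) = run_simulation_study(cfg)
        direct = run_condition(
            SimulationCondition(
                n_persons=150, strand_sizes=[4, 6], rho=0.3, n_forms=1,
                seed=condition_seed(9, 0),
            )
        )
        for m in ("ctt", "rasch", "dina"):
            assert np.allclose(study_res.mean_accuracy[m], direct.mean_accuracy[m])

    def test_report_shape_and_log(self, tmp_path):
        cfg = StudyConfig(**SMALL)
        run_simulation_study(cfg, out_dir=tmp_path)
        long = pd.read_csv(tmp_path / "accuracy_long.csv")
        assert len(long) == 2 * 3 * 2  # rhos x models x strands
        assert set(long["model"]) == {"ctt", "rasch", "dina"}
        log = json.loads((tmp_path / "run_log.json").read_text())
        assert log["master_seed"] == 11
        assert log["failed_forms"] == [[], []]
        assert "numpy" in log["versions"]


@pytest.fixture(scope="module")
def exam_fixture(tmp_path_factory):
    """A scaled-down synthetic exam-shaped dataset (8 domains) on disk."""
    d = tmp_path_factory.mktemp("exam")
    cond = exam_like_condition(seed=314, scale=0.15)
    form = generate_form(cond, 0)
    form.responses.to_csv(d / "responses.csv")
    form.q.to_csv(d / "qmatrix.csv")
    return d


class TestAnalysis:
    @pytest.fixture(scope="class")
    def report_and_dir(self, exam_fixture, tmp_path_factory):
        out = tmp_path_factory.mktemp("report")
        cfg = StudyConfig(
            mode="analyze",
            responses=str(exam_fixture / "responses.csv"),
            qmatrix=str(exam_fixture / "qmatrix.csv"),
        )
        return run_analysis(cfg, out_dir=out), out

    def test_report_covers_all_domains_and_pairs(self, report_and_dir):
        report, _ = report_and_dir
        assert len(report.domains) == 8
        for table in (report.consistency, report.correlations):
            assert table["domain"].tolist() == report.domains
            assert set(table.columns) == {"domain", "ctt_rasch", "ctt_dina", "rasch_dina"}
        assert ((report.consistency[["ctt_rasch", "ctt_dina", "rasch_dina"]] >= 0).all().all())
        assert ((report.consistency[["ctt_rasch", "ctt_dina", "rasch_dina"]] <= 1).all().all())
        assert (report.correlations[["ctt_rasch", "ctt_dina", "rasch_dina"]].abs() <= 1).all().all()
        assert (report.flag_counts["n_items"].sum()) == report.dina_items.shape[0]

    def test_self_comparison_is_perfect(self, report_and_dir):
        report, _ = report_and_dir
        assert (consistency(report.mastery["ctt"], report.mastery["ctt"]) == 1.0).all()
        assert np.allclose(score_correlations(report.scores["ctt"], report.scores["ctt"]), 1.0)

    def test_rasch_deviance_recomputable_from_artifacts(self, report_and_dir, exam_fixture):
        """Report deviance equals -2 log L recomputed from the saved difficulties."""
        report, out = report_and_dir
        items = pd.read_csv(out / "rasch_items.csv")
        x = ResponseMatrix.from_csv(exam_fixture / "responses.csv")
        q = QMatrix.from_csv(exam_fixture / "qmatrix.csv")
        total = 0.0
        for k, domain in enumerate(report.domains):
            b = items.loc[items["domain"] == domain, "difficulty"].to_numpy()
            strand = x.subset_items(q.attribute_items(k))
            total += marginal_deviance(strand, b)
        assert total == pytest.approx(report.deviances["rasch"], rel=1e-6)

    def test_dina_deviance_recomputable_from_artifacts(self, report_and_dir, exam_fixture):
        """Report deviance equals -2 log L recomputed from saved g, s, and weights."""
        report, out = report_and_dir
        items = pd.read_csv(out / "dina_items.csv")
        weights = pd.read_csv(
            out / "dina_class_weights.csv", dtype={"profile": str}
        )
        x = ResponseMatrix.from_csv(exam_fixture / "responses.csv").values.astype(float)
        q = QMatrix.from_csv(exam_fixture / "qmatrix.csv")
        profiles = np.array([[int(c) for c in p] for p in weights["profile"]])
        eta_ci = (profiles @ q.entries.T == q.entries.sum(axis=1)[None, :]).astype(int)
        g = items["guess"].to_numpy()
        s = items["slip"].to_numpy()
        p_ci = np.where(eta_ci == 1, 1 - s[None, :], g[None, :])
        ll = x @ np.log(p_ci).T + (1 - x) @ np.log1p(-p_ci).T
        from scipy.special import logsumexp

        dev = -2 * logsumexp(ll + np.log(weights["weight"].to_numpy())[None, :], axis=1).sum()
        assert dev == pytest.approx(report.deviances["dina"], rel=1e-6)

    def test_byte_identical_reruns(self, exam_fixture, tmp_path):
        cfg = StudyConfig(
            mode="analyze",
            responses=str(exam_fixture / "responses.csv"),
            qmatrix=str(exam_fixture / "qmatrix.csv"),
        )
        run_analysis(cfg, out_dir=tmp_path / "a")
        run_analysis(cfg, out_dir=tmp_path / "b")
        names = _dir_files(tmp_path / "a")
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_item_id_mismatch_reported(self, exam_fixture, tmp_path):
        q = QMatrix.from_csv(exam_fixture / "qmatrix.csv")
        q.item_names = [f"renamed{i}" for i in range(q.n_items)]
        qpath = tmp_path / "q2.csv"
        q.to_csv(qpath)
        cfg = StudyConfig(
            mode="analyze",
            responses=str(exam_fixture / "responses.csv"),
            qmatrix=str(qpath),
        )
        with pytest.raises(ValueError, match="item IDs"):
            run_analysis(cfg)


class TestCli:
    def test_simulate_and_analyze_commands(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "mode: simulate\nrho_grid: [0.0]\nstrand_sizes: [4, 6]\n"
            "n_persons: 120\nn_forms: 1\nseed: 3\n"
        )
        r = runner.invoke(
            cli_main, ["simulate", "--config", str(cfg), "--out", str(tmp_path / "sim")]
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "sim" / "accuracy_table.csv").exists()

        r = runner.invoke(
            cli_main,
            ["make-fixture", "--out-responses", str(tmp_path / "x.csv"),
             "--out-qmatrix", str(tmp_path / "q.csv"), "--scale", "0.05", "--seed", "1"],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            ["analyze", "--responses", str(tmp_path / "x.csv"),
             "--qmatrix", str(tmp_path / "q.csv"), "--out", str(tmp_path / "rep")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "rep" / "consistency.csv").exists()
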