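"""Group-comparison model/results surface and the pipeline/CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fanet import CohortConfig, ConnectomeGroupModel, generate_cohort, run_group_analysis
from fanet.cli import main as cli_main
from fanet.pipeline import RunConfig, read_metadata, run, write_metadata

SMALL_COHORT = CohortConfig(n_asd=8, n_hc=6, n_nodes=30, base_degree=6,
                            rewire_prob=0.1, target_nodes=(1, 2, 3, 4),
                            seed=77)
FIT_KW = dict(n_perm=300, n_random=8, swaps_per_edge=4, seed=1)


@pytest.fixture(scope="module")
def small_results():
    matrices, metas = generate_cohort(SMALL_COHORT)
    return ConnectomeGroupModel(matrices, metas).fit(**FIT_KW)


class TestModelFit:
    def test_tables_have_expected_shape(self, small_results):
        r = small_results
        assert len(r.global_metrics) == 14
        assert set(r.global_tests["metric"]) == {
            "Cw", "Lw", "gamma", "lambda", "sigma", "Sw", "Eglobal", "Elocal"}
        assert len(r.nodal_tests) == 3 * 30
        assert r.nodal_tests["q"].between(0, 1).all()
        assert r.global_tests["p"].between(1 / 301, 1).all()

    def test_sigma_column_is_gamma_over_lambda(self, small_results):
        g = small_results.global_metrics
        np.testing.assert_allclose(g["sigma"], g["gamma"] / g["lambda"],
                                   atol=1e-12)

    def test_nodal_efficiency_mean_matches_global(self, small_results):
        r = small_results
        eg = r.global_metrics["Eglobal"].to_numpy()
        nodal_mean = r.nodal_metrics["nodal_efficiency"].mean(axis=1)
        np.testing.assert_allclose(nodal_mean, eg, atol=1e-9)

    def test_summary_mentions_all_global_metrics(self, small_results):
        text = small_results.summary()
        for name in ("Lw", "Eglobal", "Elocal", "gamma", "sigma"):
            assert name in text
        assert "8 ASD, 6 HC" in text

    def test_save_writes_all_tables(self, small_results, tmp_path):
        small_results.save(tmp_path)
        for f in ("metrics_global.csv", "metrics_nodal.csv",
                  "group_tests_global.csv", "group_tests_nodal.csv",
                  "correlations.csv", "summary.txt"):
            assert (tmp_path / f).exists()
        nodal = pd.read_csv(tmp_path / "metrics_nodal.csv")
        assert len(nodal) == 14 * 30 * 3

    def test_plot_returns_axes(self, small_results):
        import matplotlib
        matplotlib.use("Agg")
        ax = small_results.plot_global_metrics()
        assert len(ax.patches) == 16   # 8 metrics x 2 groups

    def test_functional_entry_point_equivalent(self):
        matrices, metas = generate_cohort(SMALL_COHORT)
        r2 = run_group_analysis(matrices, metas, **FIT_KW)
        pd.testing.assert_frame_equal(
            r2.global_tests,
            ConnectomeGroupModel(matrices, metas).fit(**FIT_KW).global_tests)

    def test_mismatched_metadata_rejected(self):
        matrices, metas = generate_cohort(SMALL_COHORT)
        with pytest.raises(ValueError, match="differ in length"):
            ConnectomeGroupModel(matrices, metas[:-1])
        bad = metas[:-1] + [metas[0]]
        with pytest.raises(ValueError, match="duplicate"):
            ConnectomeGroupModel(matrices, bad)

    def test_correlations_only_for_significant_metrics(self, small_results):
        r = small_results
        sig_names = set(r.significant_global) | set(
            r.nodal_tests.loc[r.nodal_tests["significant"], "metric"])
        assert set(r.correlations["metric"]) <= sig_names


class TestPipeline:
    def test_synthetic_run_writes_artifacts_and_is_deterministic(self, tmp_path):
        cfg = RunConfig(cohort=SMALL_COHORT, n_perm=200, n_random=6,
                        swaps_per_edge=4, seed=5,
                        outdir=str(tmp_path / "run1"))
        res = run(cfg)
        assert res is not None
        out = tmp_path / "run1"
        assert (out / "provenance.yaml").exists()
        assert (out / "cohort.csv").exists()
        assert len(list((out / "matrices").glob("*.tsv"))) == 14

        cfg2 = RunConfig(cohort=SMALL_COHORT, n_perm=200, n_random=6,
                         swaps_per_edge=4, seed=5,
                         outdir=str(tmp_path / "run2"))
        run(cfg2)
        for name in ("group_tests_global.csv", "metrics_global.csv",
                     "cohort.csv"):
            assert (out / name).read_bytes() == \
                (tmp_path / "run2" / name).read_bytes()

    def test_single_group_falls_back_to_metrics_only(self, tmp_path):
        matrices, metas = generate_cohort(SMALL_COHORT)
        hc = [m for m in metas if m.group == "HC"]
        mats = [m for m in matrices if m.subject_id.startswith("hc")]
        mdir = tmp_path / "mats"
        mdir.mkdir()
        from fanet.construction import write_matrix
        for m in mats:
            write_matrix(m, mdir / f"{m.subject_id}.tsv")
        write_metadata(hc, tmp_path / "meta.csv")
        cfg = RunConfig(mode="matrices", matrix_dir=str(mdir),
                        meta_path=str(tmp_path / "meta.csv"),
                        outdir=str(tmp_path / "out"))
        with pytest.warns(UserWarning, match="cannot support inference"):
            res = run(cfg)
        assert res is None
        assert (tmp_path / "out" / "metrics_global.csv").exists()

    def test_fibers_mode_matches_synthetic_matrices(self, tmp_path):
        from fanet import matrix_to_fibers, write_fibers
        from fanet.construction import read_matrix
        matrices, metas = generate_cohort(SMALL_COHORT)
        fibers = []
        for m in matrices:
            fibers += matrix_to_fibers(m, fibers_per_edge=2, spread=0.02,
                                       seed=3)
        write_fibers(fibers, tmp_path / "fibers.csv")
        write_metadata(metas, tmp_path / "meta.csv")
        cfg = RunConfig(mode="fibers", fiber_path=str(tmp_path / "fibers.csv"),
                        meta_path=str(tmp_path / "meta.csv"), n_nodes=30,
                        n_perm=100, n_random=4, swaps_per_edge=3,
                        outdir=str(tmp_path / "out"))
        run(cfg)
        back = read_matrix(tmp_path / "out" / "matrices" / "asd001.tsv",
                           "asd001")
        np.testing.assert_allclose(back.weights, matrices[0].weights,
                                   atol=1e-9)

    def test_metadata_roundtrip(self, tmp_path):
        _, metas = generate_cohort(SMALL_COHORT)
        write_metadata(metas, tmp_path / "m.csv")
        assert read_metadata(tmp_path / "m.csv") == metas


class TestCli:
    def test_generate_then_metrics(self, tmp_path):
        runner = CliRunner()
        cfgfile = tmp_path / "cohort.yaml"
        cfgfile.write_text(
            "cohort:\n  n_asd: 3\n  n_hc: 2\n  n_nodes: 30\n"
            "  base_degree: 6\n  rewire_prob: 0.1\n"
            "  target_nodes: [1, 2, 3, 4]\n  seed: 3\n")
        res = runner.invoke(cli_main, ["generate", "--config", str(cfgfile),
                                       "--outdir", str(tmp_path / "c")])
        assert res.exit_code == 0, res.output
        tsvs = sorted((tmp_path / "c" / "matrices").glob("*.tsv"))
        assert len(tsvs) == 5

        res = runner.invoke(cli_main, ["metrics", str(tsvs[0]),
                                       "--out", str(tmp_path / "g.csv")])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(tmp_path / "g.csv")
        assert {"Cw", "Lw", "Eglobal", "Elocal"} <= set(df.columns)

    def test_nulls_command(self, tmp_path):
        runner = CliRunner()
        from fanet.construction import write_matrix
        matrices, _ = generate_cohort(SMALL_COHORT)
        p = tmp_path / "w.tsv"
        write_matrix(matrices[0], p)
        res = runner.invoke(cli_main, ["nulls", str(p), "--n-random", "5",
                                       "--swaps-per-edge", "3"])
        assert res.exit_code == 0, res.output
        assert "gamma=" in res.output
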