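"""Model/Results facade, end-to-end pipeline and CLI wiring."""

import numpy as np
import pytest
from click.testing import CliRunner

from tfminet import (
    GrnSpec,
    RunConfig,
    TFNetworkModel,
    ValidationError,
    generate_grn,
    load_expression,
    run_pipeline,
    run_simulate,
    truth_tf_list,
)
from tfminet.cli import main as cli_main

SMALL_SPEC = GrnSpec(
    n_tf_hubs=3,
    targets_per_hub=2,
    n_paralog_groups=0,
    paralog_group_size=0,
    n_cascades=1,
    n_background=5,
    n_samples=100,
    link="mixed",
    noise_sd=0.3,
    seed=2,
)


@pytest.fixture(scope="module")
def small_fit():
    matrix, truth = generate_grn(SMALL_SPEC)
    model = TFNetworkModel(matrix, truth_tf_list(truth), mode="full")
    return model.fit(dpi_epsilons=(0.0, 0.2), n_permutations=1000, seed=3), truth


class TestModelFacade:
    def test_node_universe_shared_across_tolerances(self, small_fit):
        results, _ = small_fit
        nets = list(results.networks.values())
        assert all(net.nodes == nets[0].nodes for net in nets)
        assert results.network(0.0).n_edges <= results.network(0.2).n_edges

    def test_summary_mentions_counts_and_calibration(self, small_fit):
        results, _ = small_fit
        text = results.summary()
        assert "bandwidth" in text and "DPI eps" in text
        for eps, (n_nodes, n_edges) in results.stats().items():
            assert f"{n_edges:>8d}" in text

    def test_unknown_epsilon_raises(self, small_fit):
        results, _ = small_fit
        with pytest.raises(KeyError):
            results.network(0.7)

    def test_tfs_only_mode_subsets_matrix(self):
        matrix, truth = generate_grn(SMALL_SPEC)
        model = TFNetworkModel(matrix, truth_tf_list(truth), mode="tfs_only")
        assert set(model.expression.gene_ids) == set(truth.tf_ids)

    def test_edge_decades_consistent_with_calibration(self, small_fit):
        from tfminet import p_decade

        results, _ = small_fit
        for e in results.base_network.edges:
            assert e.p_decade == p_decade(e.mi, results.calibration)

    def test_mode_validation(self):
        matrix, truth = generate_grn(SMALL_SPEC)
        with pytest.raises(ValidationError):
            TFNetworkModel(matrix, truth_tf_list(truth), mode="bogus")


class TestRunSimulate:
    def test_emits_complete_fixture_set(self, tmp_path):
        paths = run_simulate(SMALL_SPEC, tmp_path / "sim")
        for p in paths.values():
            assert p.is_file()
        matrix = load_expression(paths["matrix"])
        assert matrix.shape == (SMALL_SPEC.n_genes, SMALL_SPEC.n_samples)
        assert "seed: 2" in paths["spec"].read_text()

    def test_seed_changes_values_not_shapes(self, tmp_path):
        import dataclasses

        p1 = run_simulate(SMALL_SPEC, tmp_path / "a")
        p2 = run_simulate(dataclasses.replace(SMALL_SPEC, seed=9), tmp_path / "b")
        m1, m2 = load_expression(p1["matrix"]), load_expression(p2["matrix"])
        assert m1.shape == m2.shape
        assert not np.array_equal(m1.values, m2.values)


@pytest.fixture(scope="module")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return run_simulate(SMALL_SPEC, out)


class TestRunPipeline:
    def _config(self, sim_dir, **kw):
        base = dict(
            matrix=str(sim_dir["matrix"]),
            tf_list=str(sim_dir["tf_list"]),
            annotation=str(sim_dir["annotation"]),
            dpi_epsilons=(0.0, 0.1, 0.2),
            n_permutations=1000,
            seed=4,
        )
        base.update(kw)
        return RunConfig(**base)

    def test_writes_networks_with_nondecreasing_edge_counts(self, sim_dir, tmp_path):
        results = run_pipeline(self._config(sim_dir), tmp_path / "run")
        counts = [n_edges for _, n_edges in results.stats().values()]
        assert counts == sorted(counts)
        for eps in (0.0, 0.1, 0.2):
            assert (tmp_path / "run" / f"network_dpi{eps:.1f}.tsv").is_file()
            assert (tmp_path / "run" / f"network_dpi{eps:.1f}.adj").is_file()
        prov = (tmp_path / "run" / "provenance.txt").read_text()
        assert "calibration_slope" in prov and "seed\t4" in prov

    def test_rerun_is_byte_identical(self, sim_dir, tmp_path):
        run_pipeline(self._config(sim_dir), tmp_path / "r1")
        run_pipeline(self._config(sim_dir), tmp_path / "r2")
        for name in ["network_dpi0.0.tsv", "network_dpi0.2.tsv", "network_dpi0.0.adj"]:
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()

    def test_missing_input_fails_before_computation(self, sim_dir, tmp_path):
        cfg = self._config(sim_dir, tf_list=str(tmp_path / "nope.txt"))
        with pytest.raises(ValidationError, match="tf_list"):
            run_pipeline(cfg, tmp_path / "run")


@pytest.fixture(scope="module")
def workspace(tmp_path_factory):
    root = tmp_path_factory.mktemp("cli")
    runner = CliRunner()
    res = runner.invoke(
        cli_main,
        ["simulate", "--out-dir", str(root / "sim"), "--seed", "2",
         "--n-tf-hubs", "3", "--targets-per-hub", "2", "--n-paralog-groups", "0",
         "--paralog-group-size", "0", "--n-cascades", "1", "--n-background", "5",
         "--n-samples", "100"],
    )
    assert res.exit_code == 0, res.output
    res = runner.invoke(
        cli_main,
        ["infer", "--matrix", str(root / "sim" / "expression.tsv"),
         "--tf-list", str(root / "sim" / "tf_list.txt"),
         "--annotation", str(root / "sim" / "annotation.tsv"),
         "--dpi", "0.0", "--dpi", "0.2", "--n-permutations", "1000",
         "--seed", "3", "--out-dir", str(root / "run")],
    )
    assert res.exit_code == 0, res.output
    return root


class TestCli:
    def test_infer_prints_summary(self, workspace):
        assert (workspace / "run" / "summary.txt").read_text().startswith("TF-anchored")

    def test_neighbors_command(self, workspace):
        runner = CliRunner()
        table = workspace / "run" / "network_dpi0.0.tsv"
        hub = table.read_text().splitlines()[1].split("\t")[0]
        res = runner.invoke(cli_main, ["neighbors", str(table), hub])
        assert res.exit_code == 0, res.output
        assert res.output.startswith("partner\t")

    def test_overlap_command(self, workspace, tmp_path):
        a, b = tmp_path / "a.txt", tmp_path / "b.txt"
        a.write_text("g1\ng2\ng3\n")
        b.write_text("g2\n")
        res = CliRunner().invoke(cli_main, ["overlap", str(a), str(b)])
        assert res.exit_code == 0
        assert "percent\t33.3" in res.output

    def test_prune_and_export_round(self, workspace, tmp_path):
        runner = CliRunner()
        table = workspace / "run" / "network_dpi0.0.tsv"
        out = tmp_path / "pruned.tsv"
        res = runner.invoke(cli_main, ["prune", str(table), "--dpi", "0.2", "--out", str(out)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main, ["export", str(out), "--format", "adj", "--out", str(tmp_path / "x.adj")]
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "x.adj").is_file()

    def test_subnet_and_seeds_commands(self, workspace, tmp_path):
        runner = CliRunner()
        table = workspace / "run" / "network_dpi0.0.tsv"
        first_edge = table.read_text().splitlines()[1].split("\t")
        genes = tmp_path / "genes.txt"
        genes.write_text(f"{first_edge[0]}\n{first_edge[1]}\n")
        res = runner.invoke(
            cli_main,
            ["subnet", str(table), "--genes", str(genes), "--out", str(tmp_path / "sub.tsv")],
        )
        assert res.exit_code == 0, res.output
        assert "largest_fraction_percent" in res.output
        res = runner.invoke(
            cli_main,
            ["seeds", str(table), "--seeds", str(genes),
             "--tf-list", str(workspace / "sim" / "tf_list.txt"),
             "--out", str(tmp_path / "hood.tsv")],
        )
        assert res.exit_code == 0, res.output
        assert res.output.startswith("tf\t") or "tf\tn_seed_neighbors" in res.output

    def test_evidence_command(self, workspace, tmp_path):
        ev = tmp_path / "ev.txt"
        # every simulated TF counts as detected by one source
        ev.write_text((workspace / "sim" / "tf_list.txt").read_text())
        res = CliRunner().invoke(
            cli_main,
            ["evidence", str(workspace / "run" / "network_dpi0.0.tsv"),
             "--tf-list", str(workspace / "sim" / "tf_list.txt"),
             "--evidence", f"rt_pcr={ev}"],
        )
        assert res.exit_code == 0, res.output
        assert "percent\t100.0" in res.output
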