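"""Batch facade and command-line interface."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from synroutes import (
    ProcessConfig,
    RouteSpec,
    generate_route,
    helper,
    process_routes,
    read_node_edge_json,
    syngraph_equal,
    write_casp_tree,
)
from synroutes.cli import main as cli_main
from synroutes.exceptions import EmptyBatchError, UnknownFunctionalityError


@pytest.fixture
def route_files(tmp_path):
    """Two CASP-tree files from two pretend sources, three routes total."""
    specs = {
        "toolA": [RouteSpec(depth=2, seed=61), RouteSpec(depth=3, seed=62)],
        "toolB": [RouteSpec(depth=4, branch_points=((2, 1),), seed=63)],
    }
    input_map, originals = {}, {}
    for source, spec_list in specs.items():
        routes = [generate_route(s).route for s in spec_list]
        payload = [write_casp_tree(r).payload for r in routes]
        path = tmp_path / f"{source}.json"
        path.write_text(json.dumps(payload), encoding="utf-8")
        input_map[str(path)] = source
        originals[source] = routes
    return input_map, originals


class TestProcessRoutes:
    def test_defaults_write_bipartite_node_edge_json(self, route_files,
                                                     tmp_path):
        input_map, originals = route_files
        out = process_routes(ProcessConfig(
            input_map=input_map, output_dir=str(tmp_path / "out")))
        assert len(out.routes) == 3
        assert out.failures == {}
        routes_file = [p for p in out.written_files
                       if p.endswith("routes.json")]
        assert routes_file
        docs = json.loads(open(routes_file[0]).read())
        assert all(d["data_model"] == "bipartite" for d in docs)
        rebuilt = [read_node_edge_json(d) for d in docs]
        read_back_a0 = rebuilt[out.route_ids.index("toolA_0")]
        assert syngraph_equal(read_back_a0, originals["toolA"][0])

    def test_descriptor_functionality_writes_csv(self, route_files,
                                                 tmp_path):
        input_map, _ = route_files
        out = process_routes(ProcessConfig(
            input_map=input_map, functionalities=["compute_descriptors"],
            output_dir=str(tmp_path / "out")))
        assert isinstance(out.descriptors, pd.DataFrame)
        csv_path = [p for p in out.written_files
                    if p.endswith("descriptors.csv")][0]
        frame = pd.read_csv(csv_path)
        assert set(frame.columns) == {"route_id", "descriptor", "value"}
        steps = frame[(frame.route_id == "toolB_0")
                      & (frame.descriptor == "n_steps")].value.iloc[0]
        assert steps == 5

    def test_clustering_functionality_outputs(self, route_files, tmp_path):
        input_map, _ = route_files
        out = process_routes(ProcessConfig(
            input_map=input_map, functionalities=["clustering"],
            output_dir=str(tmp_path / "out")))
        assert out.clustering is not None
        assert len(out.clustering.labels) == 3
        assert out.distance_matrix is not None
        names = {p.rsplit("/", 1)[-1] for p in out.written_files}
        assert {"clusters.csv", "cluster_summary.csv"} <= names

    def test_unknown_functionality_fails_before_io(self, tmp_path):
        config = ProcessConfig(
            input_map={str(tmp_path / "missing.json"): "x"},
            functionalities=["clusterin"],  # typo
        )
        with pytest.raises(UnknownFunctionalityError):
            process_routes(config)

    def test_corrupt_file_isolated_from_batch(self, route_files, tmp_path):
        input_map, _ = route_files
        bad = tmp_path / "broken.json"
        bad.write_text("{not json", encoding="utf-8")
        with_bad = {**input_map, str(bad): "toolC"}
        out = process_routes(ProcessConfig(
            input_map=with_bad, functionalities=["compute_descriptors"],
            output_dir=str(tmp_path / "out")))
        assert str(bad) in out.failures
        assert len(out.routes) == 3  # others unaffected

    def test_all_files_failing_is_an_error(self, tmp_path):
        bad = tmp_path / "broken.json"
        bad.write_text("[]", encoding="utf-8")
        with pytest.raises(EmptyBatchError):
            process_routes(ProcessConfig(input_map={str(bad): "x"}))

    def test_dot_and_csv_output_formats(self, route_files, tmp_path):
        input_map, _ = route_files
        out = process_routes(ProcessConfig(
            input_map=input_map, output_format="dot_text",
            out_data_model="monopartite_reactions",
            output_dir=str(tmp_path / "dots")))
        assert sum(p.endswith(".dot") for p in out.written_files) == 3
        out2 = process_routes(ProcessConfig(
            input_map=input_map, output_format="csv",
            output_dir=str(tmp_path / "csv")))
        names = {p.rsplit("/", 1)[-1] for p in out2.written_files}
        assert {"nodes.csv", "edges.csv"} <= names


class TestHelper:
    def test_lists_defaults_and_registries(self):
        text = helper()
        assert "bipartite" in text
        for name in ("n_steps", "longest_linear_sequence", "n_branches",
                     "convergence", "avg_branching_factor"):
            assert name in text

    def test_reflects_custom_descriptor_registration(self):
        from synroutes import register_descriptor
        from synroutes.descriptors import _REGISTRY
        register_descriptor("my_custom_metric", lambda route: 0.0)
        try:
            assert "my_custom_metric" in helper()
        finally:
            _REGISTRY.pop("my_custom_metric", None)


class TestCli:
    def test_cli_matches_facade_output(self, route_files, tmp_path):
        input_map, _ = route_files
        facade_dir = tmp_path / "facade_out"
        cli_dir = tmp_path / "cli_out"
        process_routes(ProcessConfig(
            input_map=input_map, functionalities=["compute_descriptors"],
            output_dir=str(facade_dir)))
        args = ["process", "--out-dir", str(cli_dir),
                "--functionality", "compute_descriptors"]
        for path, source in input_map.items():
            args += ["--input", f"{path}:{source}"]
        result = CliRunner().invoke(cli_main, args)
        assert result.exit_code == 0, result.output
        facade_csv = (facade_dir / "descriptors.csv").read_text()
        cli_csv = (cli_dir / "descriptors.csv").read_text()
        assert facade_csv == cli_csv
        assert (cli_dir / "process.log").exists()

    def test_helper_command(self):
        result = CliRunner().invoke(cli_main, ["helper"])
        assert result.exit_code == 0
        assert "bipartite" in result.output

    def test_config_file_with_flag_override(self, route_files, tmp_path):
        input_map, _ = route_files
        cfg = tmp_path / "run.cfg"
        cfg.write_text("data_model=monopartite_reactions\n"
                       f"out_dir={tmp_path / 'cfg_out'}\n")
        args = ["process", "--config", str(cfg),
                "--data-model", "bipartite"]  # flag wins
        for path, source in input_map.items():
            args += ["--input", f"{path}:{source}"]
        result = CliRunner().invoke(cli_main, args)
        assert result.exit_code == 0, result.output
        docs = json.loads((tmp_path / "cfg_out" / "routes.json").read_text())
        assert all(d["data_model"] == "bipartite" for d in docs)
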