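"""High-level batch facade: read, convert, describe, compare, cluster.

:func:`process_routes` is the front door for application scientists: it
takes a mapping of route files to their source (CASP tool) labels, reads
every route, converts to the requested data model, writes the routes in the
requested output format, and runs the requested functionalities
(descriptor calculation, GED-based clustering) with sensible defaults.
Failures are captured per input file — one corrupt file never aborts the
batch — and every stage logs its counts.

:func:`helper` prints the catalog of registered formats, data models,
descriptors, GED and clustering methods with their defaults, mirroring the
library's extensible registries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import clustering as _clustering
from .chem import DEFAULT_POLICY, IdentityPolicy
from .descriptors import compute_descriptors, registered_descriptors
from .exceptions import (
    EmptyBatchError,
    SynRoutesError,
    UndefinedDescriptorError,
    UnknownFunctionalityError,
)
from .similarity import DEFAULT_GED_PARAMS, GED_METHODS, GedParams, \
    distance_matrix
from .syngraph import BIPARTITE, DATA_MODELS, SynGraph, convert_data_model
from .translate import (
    CASP_TREE_JSON,
    DOT_TEXT,
    NODE_EDGE_JSON,
    registered_formats,
    translate,
    write_dot,
    write_node_edge_json,
)

logger = logging.getLogger("synroutes")

COMPUTE_DESCRIPTORS = "compute_descriptors"
CLUSTERING = "clustering"
FUNCTIONALITIES = (COMPUTE_DESCRIPTORS, CLUSTERING)

CSV_FORMAT = "csv"  # routes flattened to node and edge tables
_OUTPUT_FORMATS = (NODE_EDGE_JSON, DOT_TEXT, CSV_FORMAT)


@dataclass
class ProcessConfig:
    """Configuration for one :func:`process_routes` batch."""

    input_map: dict                       # file path -> source (CASP) label
    input_format: str = CASP_TREE_JSON
    output_format: str = NODE_EDGE_JSON
    out_data_model: str = BIPARTITE
    functionalities: Sequence[str] = ()
    descriptor_names: Union[str, Sequence[str]] = "all"
    clustering_method: Optional[str] = None
    ged_method: str = "exact"
    ged_params: Optional[GedParams] = None
    parallelization: bool = False
    n_cpu: int = 1
    identity_policy: IdentityPolicy = DEFAULT_POLICY
    output_dir: str = "."


@dataclass
class ProcessOutput:
    """Attributes populated per requested functionality."""

    routes: list = field(default_factory=list)      # converted SynGraphs
    route_ids: list = field(default_factory=list)
    descriptors: Optional[pd.DataFrame] = None
    clustering: Optional[_clustering.ClusterResult] = None
    distance_matrix: Optional[object] = None
    written_files: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)    # file path -> reason


def process_routes(config: ProcessConfig) -> ProcessOutput:
    """Run the full batch pipeline described by ``config``.

    Raises :class:`UnknownFunctionalityError` before touching any file if a
    requested functionality is not registered, and :class:`EmptyBatchError`
    if every input file fails to load.
    """
    unknown = [f for f in config.functionalities if f not in FUNCTIONALITIES]
    if unknown:
        raise UnknownFunctionalityError(
            f"unknown functionalities {unknown}; available: "
            f"{list(FUNCTIONALITIES)}"
        )
    if config.output_format not in _OUTPUT_FORMATS:
        raise SynRoutesError(
            f"unknown output format {config.output_format!r}; available: "
            f"{list(_OUTPUT_FORMATS)}"
        )
    if config.out_data_model not in DATA_MODELS:
        raise SynRoutesError(
            f"unknown data model {config.out_data_model!r}; available: "
            f"{list(DATA_MODELS)}"
        )

    out = ProcessOutput()
    raw_routes: list[SynGraph] = []  # bipartite working copies
    for path, source in config.input_map.items():
        try:
            for k, g in enumerate(_read_route_file(path, config)):
                g.source_label = source
                raw_routes.append(g)
                out.route_ids.append(f"{source}_{k}")
        except (SynRoutesError, OSError, json.JSONDecodeError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            out.failures[str(path)] = f"{type(exc).__name__}: {exc}"
    if not raw_routes:
        raise EmptyBatchError(
            f"no route could be read from {list(config.input_map)}; "
            f"failures: {out.failures}"
        )
    logger.info("read %d routes from %d files (%d failed)",
                len(raw_routes), len(config.input_map), len(out.failures))

    out.routes = [convert_data_model(g, config.out_data_model)
                  for g in raw_routes]
    logger.info("converted routes to %s", config.out_data_model)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_routes(out, config, out_dir)

    if COMPUTE_DESCRIPTORS in config.functionalities:
        _run_descriptors(out, raw_routes, config, out_dir)
    if CLUSTERING in config.functionalities:
        _run_clustering(out, raw_routes, config, out_dir)
    return out


def _read_route_file(path, config: ProcessConfig) -> list[SynGraph]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    items = payload if isinstance(payload, list) else [payload]
    return [
        translate(config.input_format, item, "syngraph", BIPARTITE,
                  config.identity_policy)
        for item in items
    ]


def _write_routes(out: ProcessOutput, config: ProcessConfig,
                  out_dir: Path) -> None:
    if config.output_format == NODE_EDGE_JSON:
        docs = [write_node_edge_json(g).payload for g in out.routes]
        target = out_dir / "routes.json"
        target.write_text(json.dumps(docs, indent=2, sort_keys=True),
                          encoding="utf-8")
        out.written_files.append(str(target))
    elif config.output_format == DOT_TEXT:
        for rid, g in zip(out.route_ids, out.routes):
            target = out_dir / f"{rid}.dot"
            target.write_text(write_dot(g).payload, encoding="utf-8")
            out.written_files.append(str(target))
    else:  # csv: node and edge lists flattened to two tables
        node_rows, edge_rows = [], []
        for rid, g in zip(out.route_ids, out.routes):
            payload = write_node_edge_json(g).payload
            node_rows += [{"route_id": rid, **n} for n in payload["nodes"]]
            edge_rows += [{"route_id": rid, **e} for e in payload["edges"]]
        for name, rows in (("nodes.csv", node_rows), ("edges.csv", edge_rows)):
            target = out_dir / name
            pd.DataFrame(rows).to_csv(target, index=False)
            out.written_files.append(str(target))
    logger.info("wrote %d routes as %s", len(out.routes),
                config.output_format)


def _run_descriptors(out: ProcessOutput, raw_routes, config: ProcessConfig,
                     out_dir: Path) -> None:
    rows = []
    for rid, g in zip(out.route_ids, raw_routes):
        try:
            results = compute_descriptors(g, config.descriptor_names, rid)
        except UndefinedDescriptorError as exc:
            # all-or-nothing failed; retry one by one, recording the holes
            results = []
            names = registered_descriptors() \
                if config.descriptor_names == "all" \
                else list(config.descriptor_names)
            for name in names:
                try:
                    results += compute_descriptors(g, [name], rid)
                except UndefinedDescriptorError:
                    out.failures[f"{rid}:{name}"] = str(exc)
        rows += [
            {"route_id": r.route_id, "descriptor": r.descriptor_name,
             "value": r.value} for r in results
        ]
    out.descriptors = pd.DataFrame(rows)
    target = out_dir / "descriptors.csv"
    out.descriptors.to_csv(target, index=False)
    out.written_files.append(str(target))
    logger.info("computed %d descriptor values", len(rows))


def _run_clustering(out: ProcessOutput, raw_routes, config: ProcessConfig,
                    out_dir: Path) -> None:
    params = config.ged_params or DEFAULT_GED_PARAMS
    if config.ged_method != params.method:
        params = GedParams(
            insertion_cost=params.insertion_cost,
            deletion_cost=params.deletion_cost,
            fingerprint_params=params.fingerprint_params,
            use_roots=params.use_roots,
            method=config.ged_method,
            data_model=params.data_model,
        )
    dm = distance_matrix(raw_routes, params,
                         parallel=config.parallelization,
                         n_workers=config.n_cpu,
                         route_ids=out.route_ids)
    out.distance_matrix = dm
    logger.info("distance matrix over %d routes", len(dm.route_ids))
    result = _clustering.cluster_routes(dm, method=config.clustering_method)
    _clustering.cluster_summary(result, raw_routes)
    out.clustering = result
    for name, frame in (("clusters.csv", result.to_dataframe()),
                        ("cluster_summary.csv", result.summary)):
        target = out_dir / name
        frame.to_csv(target, index=False)
        out.written_files.append(str(target))
    logger.info("clustered into %d clusters (%s, silhouette=%.3f)",
                len(result.medoids), result.method_used, result.silhouette)


def helper() -> str:
    """Catalog of options and defaults for the facade arguments."""
    lines = [
        "process_routes options",
        "======================",
        "input_map            file path -> source label "
        "(e.g. {'routes.json': 'aizynthfinder'})",
        f"input_format         default {CASP_TREE_JSON!r}; readable formats:",
    ]
    fmts = registered_formats()
    for name, caps in fmts.items():
        if caps["read"]:
            lines.append(f"                       - {name}")
    lines.append(f"output_format        default {NODE_EDGE_JSON!r}; one of "
                 f"{list(_OUTPUT_FORMATS)}")
    lines.append(f"out_data_model       default {BIPARTITE!r}; one of "
                 f"{list(DATA_MODELS)}")
    lines.append(f"functionalities      subset of {list(FUNCTIONALITIES)}")
    lines.append("descriptor_names     default 'all'; registered descriptors:")
    for name in registered_descriptors():
        lines.append(f"                       - {name}")
    lines.append("clustering_method    default: agglomerative below "
                 f"{_clustering.AGGLOMERATIVE_MAX_ROUTES} routes, hdbscan "
                 "otherwise; one of "
                 f"{list(_clustering.CLUSTER_METHODS)}")
    lines.append(f"ged_method           default 'exact'; one of "
                 f"{list(GED_METHODS)}")
    lines.append("ged_params           GedParams(insertion_cost=1, "
                 "deletion_cost=1, Morgan/difference fingerprints, "
                 "tanimoto)")
    lines.append("parallelization      default False")
    lines.append("n_cpu                default 1")
    lines.append("identity_policy      default 'canonical-isomeric-smiles'; "
                 "also 'canonical-smiles-no-stereo', 'inchikey'")
    return "\n".join(lines)
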