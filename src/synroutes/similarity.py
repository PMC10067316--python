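"""Chemistry-aware graph edit distance between synthetic routes.

The distance between two routes is the cost of the optimal edit path
(node insertions, deletions and substitutions, with their induced edge
edits) transforming one graph into an isomorph of the other.  Chemical
information enters through the substitution cost: substituting one node for
another of the same kind costs ``1 - fingerprint_similarity`` (so uid-equal
nodes are free), while swapping a node for one of a different kind — or
inserting/deleting a node — costs one unit.  Edge insertions and deletions
cost one unit each; preserved edges are free.

The exact search is NetworkX's A*-based ``graph_edit_distance`` carrying
these bespoke cost functions; for single-root graphs the two roots are
pinned to each other (the ``roots`` constraint), which prunes the search
without changing the optimum for routes sharing a target position.  An
approximate anytime mode returns the first (upper-bound) value of the
optimizing generator for larger graphs.

By default route distances are computed on the monopartite-reactions
projection, where each node is one synthetic step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .chem import DEFAULT_FP_PARAMS, FingerprintParams, chemical_similarity
from .exceptions import InsufficientInputError, InvalidMatrixError, \
    ModelMismatchError
from .syngraph import MONOPARTITE_REACTIONS, SynGraph, convert_data_model, \
    roots_and_leaves

GED_EXACT = "exact"
GED_APPROXIMATE = "approximate"
GED_METHODS = (GED_EXACT, GED_APPROXIMATE)


@dataclass(frozen=True)
class GedParams:
    """Edit-cost configuration for route comparison."""

    insertion_cost: float = 1.0
    deletion_cost: float = 1.0
    fingerprint_params: FingerprintParams = DEFAULT_FP_PARAMS
    use_roots: bool = True
    method: str = GED_EXACT
    data_model: str = MONOPARTITE_REACTIONS

    def __post_init__(self) -> None:
        if self.insertion_cost < 0 or self.deletion_cost < 0:
            raise ValueError("edit costs must be non-negative")
        if self.method not in GED_METHODS:
            raise ValueError(f"unknown ged method {self.method!r}; "
                             f"choose one of {GED_METHODS}")


DEFAULT_GED_PARAMS = GedParams()


def node_substitution_cost(a, b, params: GedParams = DEFAULT_GED_PARAMS
                           ) -> float:
    """Cost of substituting chemical node ``a`` with ``b``.

    Same kind: ``1 - chemical_similarity`` (0 for uid-equal nodes);
    different kind: 1 (equivalent to a delete + insert of unit cost).
    """
    if a.kind != b.kind:
        return 1.0
    if a.uid == b.uid:
        return 0.0
    return 1.0 - chemical_similarity(a, b, params.fingerprint_params)


def ged(a: SynGraph, b: SynGraph,
        params: GedParams = DEFAULT_GED_PARAMS,
        _cost_cache: Optional[dict] = None) -> float:
    """Graph edit distance between two same-model SynGraphs.

    ``ged(g, g) == 0``; symmetric whenever insertion and deletion costs are
    equal.  With ``params.use_roots`` and two single-root graphs, the roots
    are matched to each other in the search.
    """
    if a.data_model != b.data_model:
        raise ModelMismatchError(
            f"cannot compare {a.data_model} with {b.data_model}"
        )
    cache = _cost_cache if _cost_cache is not None else {}

    def subst(attrs_a: dict, attrs_b: dict) -> float:
        na, nb = attrs_a["obj"], attrs_b["obj"]
        key = (na.kind, na.uid, nb.kind, nb.uid)
        cost = cache.get(key)
        if cost is None:
            cost = node_substitution_cost(na, nb, params)
            cache[key] = cache[(nb.kind, nb.uid, na.kind, na.uid)] = cost
        return cost

    ga, gb = a.as_networkx(), b.as_networkx()
    if params.method == GED_APPROXIMATE:
        # anytime mode (unrooted): first yield is a fast upper bound
        return float(next(nx.optimize_graph_edit_distance(
            ga, gb,
            node_subst_cost=subst,
            node_del_cost=lambda attrs: params.deletion_cost,
            node_ins_cost=lambda attrs: params.insertion_cost,
        )))

    roots = None
    root_cost = 0.0
    subst_fn = subst
    if params.use_roots:
        ra, _ = roots_and_leaves(a)
        rb, _ = roots_and_leaves(b)
        if len(ra) == 1 and len(rb) == 1:
            roots = (ra[0].uid, rb[0].uid)
            # Pinned roots are substituted unconditionally; folding their
            # substitution cost in as a constant afterwards keeps the
            # search's internal cost bound consistent for any cost value.
            root_cost = node_substitution_cost(ra[0], rb[0], params)

            def subst_fn(attrs_a: dict, attrs_b: dict) -> float:
                if attrs_a["obj"].uid == roots[0] and \
                        attrs_b["obj"].uid == roots[1]:
                    return 0.0
                return subst(attrs_a, attrs_b)

    value = nx.graph_edit_distance(
        ga, gb, roots=roots,
        node_subst_cost=subst_fn,
        node_del_cost=lambda attrs: params.deletion_cost,
        node_ins_cost=lambda attrs: params.insertion_cost,
    )
    return float(value) + root_cost


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise route distances."""

    route_ids: list[str]
    values: np.ndarray

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or \
                len(self.route_ids) != v.shape[0]:
            raise InvalidMatrixError("matrix shape does not match route ids")
        if not np.allclose(v, v.T):
            raise InvalidMatrixError("distance matrix must be symmetric")
        if np.any(v < 0):
            raise InvalidMatrixError("distances must be non-negative")
        if np.any(np.diag(v) != 0):
            raise InvalidMatrixError("diagonal must be zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.route_ids,
                            columns=self.route_ids)


def _pair_distance(graphs, i, j, params):
    return ged(graphs[i], graphs[j], params)


def distance_matrix(routes: Sequence[SynGraph],
                    params: GedParams = DEFAULT_GED_PARAMS,
                    parallel: bool = False, n_workers: int = 2,
                    route_ids: Optional[Sequence[str]] = None
                    ) -> DistanceMatrix:
    """Pairwise GED matrix over a route list.

    Routes are projected onto ``params.data_model`` first; the upper
    triangle is computed (in parallel over pairs when requested) and
    mirrored, so parallel and serial results are identical.
    """
    routes = list(routes)
    if len(routes) < 2:
        raise InsufficientInputError(
            f"need at least 2 routes for a distance matrix, got {len(routes)}"
        )
    if route_ids is None:
        route_ids = [
            r.source_label or f"route_{i}" for i, r in enumerate(routes)
        ]
    if len(set(route_ids)) != len(routes):
        route_ids = [f"{rid}#{i}" for i, rid in enumerate(route_ids)]

    graphs = [convert_data_model(r, params.data_model)
              if r.data_model != params.data_model else r for r in routes]
    # warm fingerprint caches once; the O(n^2) pair loop reuses them
    for g in graphs:
        for node in g.nodes():
            node.fingerprint(params.fingerprint_params)

    n = len(graphs)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if parallel:
        dists = Parallel(n_jobs=max(1, n_workers))(
            delayed(_pair_distance)(graphs, i, j, params) for i, j in pairs
        )
    else:
        cache: dict = {}
        dists = [ged(graphs[i], graphs[j], params, _cost_cache=cache)
                 for i, j in pairs]

    values = np.zeros((n, n))
    for (i, j), d in zip(pairs, dists):
        values[i, j] = values[j, i] = d
    dm = DistanceMatrix(list(route_ids), values)
    dm.validate()
    return dm
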