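"""Clustering of synthetic routes from a GED distance matrix.

Two methods are available, both operating on precomputed distances:

* ``agglomerative`` — hierarchical clustering (single linkage by default)
  where the number of clusters k is not user-supplied but optimized: every
  k in [2, n-1] is fitted and the k maximizing the silhouette score on the
  distance matrix wins (ties broken toward smaller k, i.e. parsimony).
* ``hdbscan`` — density-based clustering that needs no k and may label
  routes as noise (cluster −1).

When no method is given, agglomerative clustering is used for fewer than 15
routes and HDBSCAN otherwise.  Each cluster is summarized by its medoid —
the member route minimizing the summed intra-cluster distance — which serves
as the representative route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN, AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .descriptors import n_branches, n_steps
from .exceptions import AlignmentError, InsufficientInputError
from .similarity import DistanceMatrix

AGGLOMERATIVE = "agglomerative"
DENSITY = "hdbscan"
CLUSTER_METHODS = (AGGLOMERATIVE, DENSITY)
_ALIASES = {"density": DENSITY, "hdbscan": DENSITY,
            "agglomerative": AGGLOMERATIVE}

#: Below this route count the agglomerative path is the default.
AGGLOMERATIVE_MAX_ROUTES = 15


@dataclass
class ClusterResult:
    """Outcome of a route-clustering run."""

    labels: np.ndarray            # cluster id per route; −1 = noise
    route_ids: list[str]
    method_used: str
    silhouette: float             # nan when undefined (degenerate input)
    medoids: dict[int, str]       # cluster id -> representative route id
    degenerate: bool = False      # all routes equidistant: one trivial cluster
    summary: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"route_id": self.route_ids, "cluster": self.labels}
        )


def choose_method(n_routes: int, override: Optional[str] = None) -> str:
    """Default method selection rule (override wins when given)."""
    if n_routes < 3:
        raise InsufficientInputError(
            f"clustering needs at least 3 routes, got {n_routes}"
        )
    if override is not None:
        method = _ALIASES.get(override)
        if method is None:
            raise ValueError(f"unknown clustering method {override!r}; "
                             f"choose one of {sorted(_ALIASES)}")
        return method
    return AGGLOMERATIVE if n_routes < AGGLOMERATIVE_MAX_ROUTES else DENSITY


def _medoids(values: np.ndarray, labels: np.ndarray,
             route_ids: Sequence[str]) -> dict[int, str]:
    medoids: dict[int, str] = {}
    for cluster in sorted(set(labels)):
        if cluster == -1:
            continue
        members = np.flatnonzero(labels == cluster)
        intra = values[np.ix_(members, members)].sum(axis=1)
        medoids[int(cluster)] = route_ids[members[int(np.argmin(intra))]]
    return medoids


def cluster_routes(dm: DistanceMatrix, method: Optional[str] = None,
                   linkage: str = "single",
                   min_cluster_size: int = 2) -> ClusterResult:
    """Cluster routes from their distance matrix.

    The matrix is validated (symmetry, zero diagonal, non-negativity)
    before any fitting.  A matrix in which all routes are mutually
    equidistant (including all-zero) is degenerate: a single trivial
    cluster is returned and flagged rather than fitted.
    """
    dm.validate()
    n = len(dm.route_ids)
    method = choose_method(n, method)
    values = dm.values

    off_diag = values[~np.eye(n, dtype=bool)]
    if off_diag.size and np.allclose(off_diag, off_diag[0]):
        labels = np.zeros(n, dtype=int)
        return ClusterResult(
            labels=labels, route_ids=list(dm.route_ids),
            method_used=method, silhouette=float("nan"),
            medoids=_medoids(values, labels, dm.route_ids), degenerate=True,
        )

    if method == AGGLOMERATIVE:
        best_k, best_score, best_labels = None, -np.inf, None
        for k in range(2, n):
            model = AgglomerativeClustering(
                n_clusters=k, metric="precomputed", linkage=linkage
            )
            labels = model.fit_predict(values)
            score = silhouette_score(values, labels, metric="precomputed")
            if score > best_score:  # strict: ties keep the smaller k
                best_k, best_score, best_labels = k, score, labels
        labels, silhouette = best_labels, float(best_score)
    else:
        model = HDBSCAN(metric="precomputed",
                        min_cluster_size=min_cluster_size, copy=True)
        labels = model.fit_predict(values.copy())
        clustered = labels >= 0
        if len(set(labels[clustered])) >= 2:
            silhouette = float(silhouette_score(
                values[np.ix_(clustered, clustered)], labels[clustered],
                metric="precomputed",
            ))
        else:
            silhouette = float("nan")

    return ClusterResult(
        labels=np.asarray(labels, dtype=int), route_ids=list(dm.route_ids),
        method_used=method, silhouette=silhouette,
        medoids=_medoids(values, np.asarray(labels), dm.route_ids),
    )


def cluster_summary(result: ClusterResult, routes: Sequence) -> pd.DataFrame:
    """Per-cluster route count and mean n_steps / n_branches.

    The noise cluster (label −1, density method) is reported as its own
    row.  ``routes`` must align index-wise with ``result.labels``.
    """
    if len(routes) != len(result.labels):
        raise AlignmentError(
            f"{len(result.labels)} labels but {len(routes)} routes"
        )
    rows = pd.DataFrame({
        "cluster": result.labels,
        "n_steps": [n_steps(r) for r in routes],
        "n_branches": [n_branches(r) for r in routes],
    })
    summary = (
        rows.groupby("cluster")
        .agg(n_routes=("n_steps", "size"),
             mean_n_steps=("n_steps", "mean"),
             mean_n_branches=("n_branches", "mean"))
        .reset_index()
        .sort_values("cluster", ignore_index=True)
    )
    result.summary = summary
    return summary
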