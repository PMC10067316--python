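"""Route-level descriptors.

Every descriptor is computed on the monopartite-reactions projection of a
single-root route, whatever representation the caller holds; conversion
happens internally, so descriptor values are invariant to the input data
model.  The module is a factory: descriptors are looked up by name in a
registry and new calculators can be registered without modifying existing
code.

Implemented descriptors (reaction-node counts unless stated otherwise):

``n_steps``
    Number of unique chemical-equation nodes — the overall route size.
``longest_linear_sequence``
    Maximum number of reactions on any starting-material -> target path.
``n_branches``
    Number of departures from linearity: sum over reaction nodes of
    ``max(0, indegree - 1)``; 0 for a linear route, 1 per binary
    convergence.
``convergence``
    longest_linear_sequence / n_steps; 1 for linear routes, smaller for
    more convergent ones.
``avg_branching_factor``
    (non-root nodes) / (non-leaf nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Union

import networkx as nx

from .exceptions import (
    NotARouteError,
    UndefinedDescriptorError,
    UnknownDescriptorError,
)
from .syngraph import MONOPARTITE_REACTIONS, SynGraph, convert_data_model


@dataclass(frozen=True)
class RouteDescriptorResult:
    route_id: str
    descriptor_name: str
    value: float


def _reaction_projection(route: SynGraph) -> nx.DiGraph:
    """Monopartite-reactions projection as a NetworkX DiGraph.

    Raises :class:`NotARouteError` if the projection is empty or has more
    than one root (the input is not a single-target route).
    """
    proj = convert_data_model(route, MONOPARTITE_REACTIONS)
    g = proj.as_networkx()
    if g.number_of_nodes() == 0:
        raise NotARouteError("route contains no chemical equations")
    roots = [n for n in g if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise NotARouteError(
            f"descriptors are defined on single-root routes, found "
            f"{len(roots)} roots"
        )
    if not nx.is_directed_acyclic_graph(g):
        raise NotARouteError("route contains a cycle")
    return g


def n_steps(route: SynGraph) -> int:
    """Number of unique reaction nodes."""
    return _reaction_projection(route).number_of_nodes()


def longest_linear_sequence(route: SynGraph) -> int:
    """Reactions on the longest starting-material -> target path."""
    g = _reaction_projection(route)
    return nx.dag_longest_path_length(g) + 1  # path length counts edges


def n_branches(route: SynGraph, literal_parent_count: bool = False) -> int:
    """Departures from linearity.

    With ``literal_parent_count=True`` the alternative convention is used:
    count every reaction node feeding a convergence point (i.e. a node whose
    child is also the child of other nodes), which yields 2 per binary
    convergence instead of 1.
    """
    g = _reaction_projection(route)
    if literal_parent_count:
        return sum(d for _, d in g.in_degree() if d >= 2)
    return sum(max(0, d - 1) for _, d in g.in_degree())


def convergence(route: SynGraph) -> float:
    """longest_linear_sequence / n_steps (1.0 for a linear route)."""
    g = _reaction_projection(route)
    return (nx.dag_longest_path_length(g) + 1) / g.number_of_nodes()


def avg_branching_factor(route: SynGraph) -> float:
    """(non-root nodes) / (non-leaf nodes) in the reaction projection."""
    g = _reaction_projection(route)
    non_leaf = sum(1 for _, d in g.in_degree() if d >= 1)
    if non_leaf == 0:
        raise UndefinedDescriptorError(
            "average branching factor is undefined for a single-reaction "
            "route (no non-leaf nodes)"
        )
    return (g.number_of_nodes() - 1) / non_leaf


_REGISTRY: dict[str, Callable[[SynGraph], float]] = {
    "n_steps": n_steps,
    "longest_linear_sequence": longest_linear_sequence,
    "n_branches": n_branches,
    "convergence": convergence,
    "avg_branching_factor": avg_branching_factor,
}


def registered_descriptors() -> list[str]:
    return sorted(_REGISTRY)


def register_descriptor(name: str, fn: Callable[[SynGraph], float]) -> None:
    """Add a named descriptor calculator to the factory."""
    _REGISTRY[name] = fn


def compute_descriptors(
    route: SynGraph,
    names: Union[str, Iterable[str]] = "all",
    route_id: str = "",
) -> list[RouteDescriptorResult]:
    """Compute the requested descriptors (default: all registered ones)."""
    if names == "all":
        names = registered_descriptors()
    else:
        names = list(names)
        unknown = [n for n in names if n not in _REGISTRY]
        if unknown:
            raise UnknownDescriptorError(
                f"unknown descriptor(s) {unknown}; registered: "
                f"{registered_descriptors()}"
            )
    return [
        RouteDescriptorResult(route_id, name, _REGISTRY[name](route))
        for name in names
    ]
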