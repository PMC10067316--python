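"""SynGraph: the central route/network data model.

A SynGraph is an adjacency mapping ``parent -> set of children`` over
chemical value-object nodes (:class:`~synroutes.chem.Molecule` and
:class:`~synroutes.chem.ChemicalEquation`).  Edges are implicit, directed
parent -> child along the *synthetic* direction (precursors flow toward the
target), so the target compound of a route is the unique sink ("root",
out-degree 0) and starting materials are sources ("leaves", in-degree 0).
Every node appears as a key — possibly with an empty child set — so the
mapping is total and roots/leaves are well defined.

Three data models are supported:

``bipartite``
    Molecule and ChemicalEquation nodes; edges map role relationships
    (reactant molecule -> reaction, reaction -> product molecule).
``monopartite_reactions``
    ChemicalEquation nodes only; an edge R1 -> R2 means some product of R1
    is a reactant of R2 (the intermediate is implicit).
``monopartite_molecules``
    Molecule nodes only; an edge M1 -> M2 means some reaction consumes M1
    and produces M2 (the reaction is implicit — this model is lossy).

Because nodes are value objects (equality on structure-derived uids), graph
equality, merging, and subset testing reduce to dictionary arithmetic; no
isomorphism search is involved.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .chem import CHEMICAL_EQUATION, MOLECULE, ChemicalEquation, Molecule
from .exceptions import (
    AmbiguousTargetError,
    CyclicInputError,
    EmptyGraphError,
    LossyConversionError,
    ModelMismatchError,
    NotARouteError,
)

BIPARTITE = "bipartite"
MONOPARTITE_MOLECULES = "monopartite_molecules"
MONOPARTITE_REACTIONS = "monopartite_reactions"

DATA_MODELS = (BIPARTITE, MONOPARTITE_MOLECULES, MONOPARTITE_REACTIONS)


class SynGraph:
    """Directed graph of chemical value objects as a dictionary of sets."""

    def __init__(self, data_model: str = BIPARTITE, source_label: str = ""):
        if data_model not in DATA_MODELS:
            raise ValueError(
                f"unknown data model {data_model!r}; choose one of {DATA_MODELS}"
            )
        self.data_model = data_model
        self.source_label = source_label
        self._adjacency: dict = {}

    # -- construction --------------------------------------------------------
    def _check_node(self, node) -> None:
        kind = getattr(node, "kind", None)
        if self.data_model == BIPARTITE:
            if kind not in (MOLECULE, CHEMICAL_EQUATION):
                raise TypeError(f"not a chemical node: {node!r}")
        elif self.data_model == MONOPARTITE_MOLECULES:
            if kind != MOLECULE:
                raise TypeError(f"monopartite_molecules accepts Molecule nodes "
                                f"only, got {node!r}")
        else:
            if kind != CHEMICAL_EQUATION:
                raise TypeError(f"monopartite_reactions accepts "
                                f"ChemicalEquation nodes only, got {node!r}")

    def add_node(self, node) -> None:
        self._check_node(node)
        self._adjacency.setdefault(node, set())

    def add_edge(self, parent, child) -> None:
        """Add ``parent -> child``; both endpoints become keys."""
        self._check_node(parent)
        self._check_node(child)
        if parent == child:
            raise ValueError(f"self-loop on {parent!r}")
        if self.data_model == BIPARTITE and parent.kind == child.kind:
            raise ValueError(
                f"bipartite edges must connect Molecule and ChemicalEquation, "
                f"got two {parent.kind} nodes"
            )
        self._adjacency.setdefault(parent, set()).add(child)
        self._adjacency.setdefault(child, set())

    # -- inspection ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._adjacency)

    def __contains__(self, node) -> bool:
        return node in self._adjacency

    def __iter__(self):
        return iter(self._adjacency)

    def nodes(self) -> list:
        """All nodes, sorted by uid for deterministic iteration."""
        return sorted(self._adjacency, key=lambda n: (n.kind, n.uid))

    def children(self, node) -> set:
        return set(self._adjacency[node])

    def edges(self) -> list[tuple]:
        return sorted(
            ((p, c) for p, cs in self._adjacency.items() for c in cs),
            key=lambda e: (e[0].uid, e[1].uid),
        )

    def parents_map(self) -> dict:
        """Reverse adjacency: node -> set of parents."""
        rev: dict = {n: set() for n in self._adjacency}
        for p, cs in self._adjacency.items():
            for c in cs:
                rev[c].add(p)
        return rev

    def as_networkx(self) -> nx.DiGraph:
        """NetworkX view keyed by uid, node objects under the ``obj`` attr."""
        g = nx.DiGraph()
        for n in self.nodes():
            g.add_node(n.uid, obj=n, kind=n.kind)
        for p, c in self.edges():
            g.add_edge(p.uid, c.uid)
        return g

    def copy(self) -> "SynGraph":
        out = SynGraph.__new__(type(self))
        out.data_model = self.data_model
        out.source_label = self.source_label
        out._adjacency = {p: set(cs) for p, cs in self._adjacency.items()}
        return out

    def __repr__(self) -> str:
        return (f"{type(self).__name__}({self.data_model}, "
                f"{len(self)} nodes, {sum(map(len, self._adjacency.values()))}"
                f" edges)")

    # equality delegates to the dictionary comparison; differing data models
    # simply compare unequal here (syngraph_equal raises instead).
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SynGraph):
            return NotImplemented
        return (self.data_model == other.data_model
                and self._adjacency == other._adjacency)

    __hash__ = None  # mutable container


class SynRoute(SynGraph):
    """A SynGraph with exactly one root: a single-target synthetic route."""

    @classmethod
    def from_syngraph(cls, g: SynGraph) -> "SynRoute":
        route = cls(g.data_model, g.source_label)
        route._adjacency = {p: set(cs) for p, cs in g._adjacency.items()}
        route.validate()
        return route

    def validate(self) -> None:
        if not self._adjacency:
            raise EmptyGraphError("a route cannot be empty")
        roots, _ = roots_and_leaves(self)
        if len(roots) != 1:
            raise NotARouteError(
                f"a route needs exactly one root, found {len(roots)}"
            )
        if not nx.is_directed_acyclic_graph(self.as_networkx()):
            raise CyclicInputError("route contains a cycle")

    @property
    def root(self):
        return roots_and_leaves(self)[0][0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def roots_and_leaves(g: SynGraph) -> tuple[list, list]:
    """Roots (out-degree 0, the targets) and leaves (in-degree 0, the
    starting materials), each sorted by uid."""
    if len(g) == 0:
        raise EmptyGraphError("empty graph has no roots or leaves")
    rev = g.parents_map()
    roots = sorted((n for n in g if not g.children(n)), key=lambda n: n.uid)
    leaves = sorted((n for n in g if not rev[n]), key=lambda n: n.uid)
    return roots, leaves


def syngraph_equal(a: SynGraph, b: SynGraph) -> bool:
    """Dictionary equality under node uid equality.

    Raises :class:`ModelMismatchError` when the two graphs use different
    data models (they are not comparable, rather than unequal).
    """
    if a.data_model != b.data_model:
        raise ModelMismatchError(
            f"cannot compare {a.data_model} with {b.data_model}"
        )
    return a._adjacency == b._adjacency


def merge(graphs: Iterable[SynGraph]) -> SynGraph:
    """Union of SynGraphs: key-wise union of the adjacency mappings.

    uid-equal nodes collapse onto a single node, which is what makes merging
    routes from different CASP sources into a synthetic tree meaningful.
    """
    graphs = list(graphs)
    if not graphs:
        raise EmptyGraphError("nothing to merge")
    model = graphs[0].data_model
    for g in graphs[1:]:
        if g.data_model != model:
            raise ModelMismatchError(
                f"cannot merge {model} with {g.data_model}"
            )
    labels = sorted({g.source_label for g in graphs if g.source_label})
    out = SynGraph(model, source_label="+".join(labels))
    for g in graphs:
        for p, cs in g._adjacency.items():
            out._adjacency.setdefault(p, set()).update(cs)
            for c in cs:
                out._adjacency.setdefault(c, set())
    return out


def is_subset(candidate: SynGraph, reference: SynGraph) -> bool:
    """Proper-subset test on the adjacency mappings (no isomorphism search).

    True iff every node and every parent->child relation of ``candidate``
    exists in ``reference`` and the two graphs are not equal.
    """
    if candidate.data_model != reference.data_model:
        raise ModelMismatchError(
            f"cannot compare {candidate.data_model} with {reference.data_model}"
        )
    if candidate._adjacency == reference._adjacency:
        return False
    for p, cs in candidate._adjacency.items():
        if p not in reference._adjacency:
            return False
        if not cs <= reference._adjacency[p]:
            return False
    return True


def convert_data_model(g: SynGraph, target: str) -> SynGraph:
    """Project ``g`` onto another data model.

    The bipartite model carries full information and converts to either
    monopartite model; ``monopartite_reactions`` reconstructs the bipartite
    form from its ChemicalEquation role maps; ``monopartite_molecules`` keeps
    reactions only implicitly, so converting *from* it is refused.
    """
    if target not in DATA_MODELS:
        raise ValueError(f"unknown data model {target!r}")
    if g.data_model == target:
        return g.copy()
    if g.data_model == MONOPARTITE_MOLECULES:
        raise LossyConversionError(
            "monopartite_molecules holds reactions only implicitly and "
            "cannot be converted to other data models"
        )
    if g.data_model == MONOPARTITE_REACTIONS:
        bip = _reactions_to_bipartite(g)
        if target == BIPARTITE:
            return bip
        return convert_data_model(bip, target)
    # bipartite source
    if target == MONOPARTITE_REACTIONS:
        return _bipartite_to_reactions(g)
    return _bipartite_to_molecules(g)


def _bipartite_to_reactions(g: SynGraph) -> SynGraph:
    out = SynGraph(MONOPARTITE_REACTIONS, g.source_label)
    for n in g:
        if n.kind == CHEMICAL_EQUATION:
            out.add_node(n)
    for r1 in g:
        if r1.kind != CHEMICAL_EQUATION:
            continue
        for mol in g.children(r1):  # product molecules of r1
            for r2 in g.children(mol):  # reactions consuming them
                out.add_edge(r1, r2)
    return out


def _bipartite_to_molecules(g: SynGraph) -> SynGraph:
    out = SynGraph(MONOPARTITE_MOLECULES, g.source_label)
    for n in g:
        if n.kind == MOLECULE:
            out.add_node(n)
    for m1 in g:
        if m1.kind != MOLECULE:
            continue
        for ce in g.children(m1):  # reactions consuming m1
            for m2 in g.children(ce):  # their products
                out.add_edge(m1, m2)
    return out


def _reactions_to_bipartite(g: SynGraph) -> SynGraph:
    out = SynGraph(BIPARTITE, g.source_label)
    for ce in g:
        out.add_node(ce)
        for uid in ce.reactants:
            out.add_edge(ce.molecules[uid], ce)
        for uid in ce.products:
            out.add_edge(ce, ce.molecules[uid])
    return out


def extract_routes(tree: SynGraph) -> list[SynRoute]:
    """Enumerate the distinct single-root routes contained in a SynTree.

    At every convergence point — a molecule produced by two or more
    reactions — exactly one producing reaction is selected, and the
    necessary-and-sufficient closure down to the starting materials is
    taken.  The returned routes are pairwise non-equal.

    Raises
    ------
    AmbiguousTargetError   if the tree has more than one root.
    CyclicInputError       if the tree contains a cycle.
    """
    if tree.data_model == MONOPARTITE_MOLECULES:
        raise LossyConversionError(
            "route extraction needs explicit reactions; convert from "
            "bipartite or monopartite_reactions input"
        )
    bip = tree if tree.data_model == BIPARTITE else \
        convert_data_model(tree, BIPARTITE)

    if not nx.is_directed_acyclic_graph(bip.as_networkx()):
        raise CyclicInputError("route extraction is defined on acyclic input")
    roots, _ = roots_and_leaves(bip)
    if len(roots) != 1:
        raise AmbiguousTargetError(
            f"expected a single target molecule, found {len(roots)} roots"
        )
    target = roots[0]
    if target.kind != MOLECULE:
        raise AmbiguousTargetError("the root of a synthetic tree must be a "
                                   "molecule (the target compound)")

    rev = bip.parents_map()
    memo: dict = {}

    def reaction_sets(mol) -> list[frozenset]:
        """All minimal reaction sets that deliver ``mol`` from leaves."""
        if mol in memo:
            return memo[mol]
        producers = sorted(rev[mol], key=lambda n: n.uid)
        if not producers:
            memo[mol] = [frozenset()]
            return memo[mol]
        options: list[frozenset] = []
        for ce in producers:
            partial = [frozenset([ce])]
            for reactant in sorted(rev[ce], key=lambda n: n.uid):
                partial = [s | t for s in partial
                           for t in reaction_sets(reactant)]
            options.extend(partial)
        memo[mol] = options
        return options

    routes: list[SynRoute] = []
    seen: set[frozenset] = set()
    for ce_set in reaction_sets(target):
        signature = frozenset(ce.uid for ce in ce_set)
        if signature in seen:
            continue
        seen.add(signature)
        routes.append(_closure_route(bip, rev, ce_set, target))
    return routes


def _closure_route(bip: SynGraph, rev: dict, ce_set: frozenset,
                   target) -> SynRoute:
    """Bipartite route induced by a reaction selection.

    Molecules enter the route when they feed a selected reaction or are the
    target; product edges point only at included molecules, so the target
    stays the unique root.
    """
    route = SynGraph(BIPARTITE, bip.source_label)
    included_mols = {target}
    for ce in ce_set:
        included_mols.update(m for m in rev[ce] if m.kind == MOLECULE)
    for ce in ce_set:
        route.add_node(ce)
        for m in rev[ce]:
            route.add_edge(m, ce)
        for m in bip.children(ce):
            if m in included_mols:
                route.add_edge(ce, m)
    if not ce_set:  # degenerate: a bare target molecule
        route.add_node(target)
    return SynRoute.from_syngraph(route)
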