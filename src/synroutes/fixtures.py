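"""Seeded synthetic-route generator with known ground truth.

Stands in for CASP output so every layer of the toolkit is testable without
downloads.  Routes are built from a small alphabet of concatenation-safe
SMILES fragments: a toy reaction joins its reactants' SMILES strings into a
single product string, which is always structurally valid (every fragment
starts and ends with an atom that accepts one more single bond) even though
the chemistry is not meant to be mechanistically sensible — the identity and
graph layers never inspect mechanism.

Because descriptors and route extraction depend on node deduplication by
uid, the generator guarantees that every product molecule is unique in its
route (collisions are resolved by deterministically appending further
fragments), so the by-construction descriptor values are exact ground truth:

* ``n_steps``  = main-chain depth + sum of branch depths
* ``longest_linear_sequence`` = max over root paths (see
  :func:`generate_route`)
* ``n_branches`` = number of branch attachment points

All randomness flows through an explicit ``random.Random(seed)``; no global
state is touched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .chem import DEFAULT_POLICY, IdentityPolicy, build_chemical_equation, \
    canonicalize_molecule
from .exceptions import SpecError
from .similarity import node_substitution_cost, DEFAULT_GED_PARAMS, GedParams
from .syngraph import BIPARTITE, SynGraph, SynRoute

#: 20 small fragments, pairwise distinct as molecules; each starts and ends
#: with an atom that tolerates an extra single bond, so any concatenation of
#: fragments parses.
DEFAULT_ALPHABET: tuple[str, ...] = (
    "C", "N", "O", "CC", "CO", "CN", "CS", "CCC", "CCO", "CCN",
    "CCS", "COC", "CNC", "CCCC", "CCCO", "CCCN", "CCCS", "CNCC",
    "COCO", "CCOC",
)


@dataclass(frozen=True)
class RouteSpec:
    """Recipe for one synthetic route.

    ``depth`` is the number of reactions on the main chain; each entry of
    ``branch_points`` is ``(position, branch_depth)`` attaching a side chain
    of ``branch_depth`` reactions to the main-chain reaction at 1-based
    ``position`` (positions start at 2: a side chain into the first step
    would not depart from linearity).
    """

    depth: int
    branch_points: tuple = ()
    seed: int = 0
    molecule_alphabet: tuple = DEFAULT_ALPHABET

    def validate(self) -> None:
        if self.depth < 1:
            raise SpecError(f"depth must be >= 1, got {self.depth}")
        for pos, bdepth in self.branch_points:
            if not 2 <= pos <= self.depth:
                raise SpecError(
                    f"branch position {pos} outside [2, depth={self.depth}]"
                )
            if bdepth < 1:
                raise SpecError(f"branch depth must be >= 1, got {bdepth}")
        if not self.molecule_alphabet:
            raise SpecError("molecule alphabet is empty")


@dataclass
class GeneratedRoute:
    route: SynRoute                  # bipartite
    expected: dict                   # by-construction descriptor values


@dataclass
class PerturbedRoute:
    route: SynRoute
    ged_bound: float                 # cost of the constructed edit path


@dataclass
class GeneratedTree:
    tree: SynGraph                   # bipartite SynTree
    n_routes: int                    # by-construction extractable routes


class _Builder:
    """Accumulates unique toy molecules and reactions for one fixture.

    Tracks uids of every molecule placed so far so that (a) a freshly drawn
    starting material can never coincide with a synthesized product — which
    would silently turn a leaf into an intermediate and lengthen paths — and
    (b) no two reactions can share a product uid and merge under dedup.
    """

    def __init__(self, rng: random.Random, alphabet: Sequence[str],
                 policy: IdentityPolicy):
        self.rng = rng
        self.alphabet = list(alphabet)
        self.policy = policy
        self.product_uids: set[str] = set()
        self.all_uids: set[str] = set()
        self.graph = SynGraph(BIPARTITE)

    def _uid(self, smiles: str) -> str:
        return canonicalize_molecule(smiles, self.policy).uid

    def leaf(self) -> str:
        frag = self.rng.choice(self.alphabet)
        while self._uid(frag) in self.product_uids:
            frag += self.rng.choice(self.alphabet)
        self.all_uids.add(self._uid(frag))
        return frag

    def reaction(self, reactant_smiles: list[str]) -> tuple:
        """Create reactants -> concat product; returns (ce, product_smiles).

        The product is made unique among all molecules of this fixture by
        appending further fragments on collision (deterministic under the
        seeded PRNG), so uid dedup can never merge two generated steps.
        """
        reactants = list(reactant_smiles)
        while True:
            product = "".join(reactants)
            uid = self._uid(product)
            if uid not in self.all_uids:
                break
            reactants.append(self.leaf())
        self.product_uids.add(uid)
        self.all_uids.add(uid)
        ce = build_chemical_equation(
            f"{'.'.join(reactants)}>>{product}", self.policy
        )
        product_mol = ce.molecules[ce.products[0]]
        for r_uid in ce.reactants:
            self.graph.add_edge(ce.molecules[r_uid], ce)
        self.graph.add_edge(ce, product_mol)
        return ce, product

    def chain(self, length: int, extra_reactants: Optional[dict] = None
              ) -> tuple[list, str]:
        """Linear chain of ``length`` reactions; returns (ces, final product).

        ``extra_reactants`` maps 1-based chain position -> list of extra
        reactant SMILES joined into that step (used for branch attachment).
        """
        extra_reactants = extra_reactants or {}
        ces = []
        current: Optional[str] = None
        for i in range(1, length + 1):
            reactants = [current] if current else [self.leaf()]
            reactants.append(self.leaf())
            reactants.extend(extra_reactants.get(i, []))
            ce, current = self.reaction(reactants)
            ces.append(ce)
        return ces, current


def generate_route(
    spec: RouteSpec, policy: IdentityPolicy = DEFAULT_POLICY
) -> GeneratedRoute:
    """Build one bipartite route with by-construction descriptor values.

    Ground truth, writing ``d`` for the depth and ``(p_b, d_b)`` for the
    branches: ``n_steps = d + sum(d_b)``;
    ``longest_linear_sequence = max(d, max_b(d_b + d - p_b + 1))``;
    ``n_branches = len(branch_points)``;
    ``convergence = lls / n_steps``;
    ``avg_branching_factor = (n_steps - 1) / ((d - 1) + sum(d_b - 1))``
    (None when the denominator is zero, i.e. a single-reaction route).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    builder = _Builder(rng, spec.molecule_alphabet, policy)

    extra: dict[int, list[str]] = {}
    for pos, bdepth in spec.branch_points:
        _, branch_product = builder.chain(bdepth)
        extra.setdefault(pos, []).append(branch_product)
    builder.chain(spec.depth, extra_reactants=extra)

    depth = spec.depth
    branch_depths = [bd for _, bd in spec.branch_points]
    steps = depth + sum(branch_depths)
    lls = max([depth] + [bd + depth - pos + 1
                         for pos, bd in spec.branch_points])
    # reactions with at least one producing predecessor: main-chain steps
    # 2..depth plus the non-initial steps of every side chain
    non_leaf = (depth - 1) + sum(bd - 1 for bd in branch_depths)
    expected = {
        "n_steps": steps,
        "longest_linear_sequence": lls,
        "n_branches": len(spec.branch_points),
        "convergence": lls / steps,
        "avg_branching_factor": (steps - 1) / non_leaf if non_leaf else None,
    }
    return GeneratedRoute(SynRoute.from_syngraph(builder.graph), expected)


def perturb_route(route: SynRoute, edits: int, seed: int = 0,
                  params: GedParams = DEFAULT_GED_PARAMS,
                  alphabet: Sequence[str] = DEFAULT_ALPHABET
                  ) -> PerturbedRoute:
    """Apply ``edits`` known modifications; record the edit-path cost.

    Each edit either substitutes one reactant of a randomly chosen reaction
    (a single node substitution in the monopartite-reactions projection,
    costing ``1 - reaction_similarity``) or prepends a new reaction under a
    starting material (one node plus its edges).  The summed cost of this
    constructed path upper-bounds the true GED between the projections of
    the original and perturbed routes.
    """
    rng = random.Random(seed)
    ces = [n for n in route.nodes() if n.kind == "chemical_equation"]
    if edits > len(ces):
        raise SpecError(
            f"{edits} edits requested but the route has only {len(ces)} "
            f"reactions"
        )
    policy = ces[0].policy if ces else DEFAULT_POLICY
    current = route.copy()
    bound = 0.0
    for _ in range(edits):
        rev = current.parents_map()
        ces = sorted((n for n in current if n.kind == "chemical_equation"),
                     key=lambda n: n.uid)
        if rng.random() < 0.5:
            bound += _swap_reactant(current, rev, rng, ces, alphabet, policy,
                                    params)
        else:
            bound += _prepend_reaction(current, rev, rng, alphabet, policy)
    return PerturbedRoute(SynRoute.from_syngraph(current), bound)


def _swap_reactant(g, rev, rng, ces, alphabet, policy, params) -> float:
    """Replace one starting-material reactant of one reaction.

    Restricted to leaf reactants so the monopartite-reactions projection
    changes by exactly one node substitution (no producer edge is touched);
    the replacement fragment is grown until its uid is new to the graph so
    no accidental merge creates extra edges.
    """
    existing_uids = {n.uid for n in g}

    def leaf_reactants(ce):
        return [u for u in ce.reactants
                if ce.molecules[u] in g and not rev[ce.molecules[u]]]

    candidates = [ce for ce in ces if leaf_reactants(ce)]
    old_ce = rng.choice(candidates)
    removed_uid = rng.choice(sorted(leaf_reactants(old_ce)))
    removed_mol = old_ce.molecules[removed_uid]
    replacement = rng.choice(alphabet)
    while canonicalize_molecule(replacement, policy).uid in existing_uids:
        replacement += rng.choice(alphabet)
    reactant_forms = [old_ce.molecules[u].canonical_form
                      for u in old_ce.reactants if u != removed_uid]
    reactant_forms.append(replacement)
    product_forms = [old_ce.molecules[u].canonical_form
                     for u in old_ce.products]
    new_ce = build_chemical_equation(
        f"{'.'.join(reactant_forms)}>>{'.'.join(product_forms)}", policy
    )

    children = g.children(old_ce)
    parents = set(rev[old_ce])
    del g._adjacency[old_ce]
    new_mol = canonicalize_molecule(replacement, policy)
    for p in parents:
        g._adjacency[p].discard(old_ce)
        if p != removed_mol:
            g.add_edge(p, new_ce)
    if removed_mol in g and not g.children(removed_mol):
        del g._adjacency[removed_mol]
    g.add_edge(new_mol, new_ce)
    for c in children:
        g.add_edge(new_ce, c)
    return node_substitution_cost(old_ce, new_ce, params)


def _prepend_reaction(g, rev, rng, alphabet, policy) -> float:
    """Add a reaction producing a current starting material.

    In the monopartite-reactions projection this inserts one node plus one
    edge per reaction consuming that starting material.
    """
    leaves = sorted(
        (n for n in g if n.kind == "molecule" and not rev[n]),
        key=lambda n: n.uid,
    )
    target = rng.choice(leaves)
    existing_uids = {n.uid for n in g}

    def fresh_fragment() -> str:
        frag = rng.choice(alphabet)
        while canonicalize_molecule(frag, policy).uid in existing_uids:
            frag += rng.choice(alphabet)
        existing_uids.add(canonicalize_molecule(frag, policy).uid)
        return frag

    reactants = [fresh_fragment(), fresh_fragment()]
    new_ce = build_chemical_equation(
        f"{'.'.join(reactants)}>>{target.canonical_form}", policy
    )
    for r_uid in new_ce.reactants:
        g.add_edge(new_ce.molecules[r_uid], new_ce)
    g.add_edge(new_ce, target)
    n_consumers = len(g.children(target))
    return 1.0 + float(n_consumers)


def generate_tree(n_alternatives_per_convergence: Sequence[int],
                  seed: int = 0,
                  policy: IdentityPolicy = DEFAULT_POLICY) -> GeneratedTree:
    """Build a SynTree whose extractable-route count is known exactly.

    A backbone of intermediates is laid from the target down to a starting
    material; the intermediate above level ``i`` can be produced by
    ``n_alternatives_per_convergence[i]`` alternative reactions (each pairing
    the lower intermediate with a distinct co-reactant), so
    ``extract_routes`` yields exactly the product of the entries.
    """
    alternatives = list(n_alternatives_per_convergence)
    if not alternatives or any(n < 1 for n in alternatives):
        raise SpecError("need a non-empty list of counts >= 1")
    rng = random.Random(seed)
    builder = _Builder(rng, DEFAULT_ALPHABET, policy)

    # unique backbone molecules: target = b_0, ..., b_k (a leaf)
    def uid_of(s: str) -> str:
        return canonicalize_molecule(s, policy).uid

    backbone, backbone_uids = [], set()
    acc = ""
    for _ in range(len(alternatives) + 1):
        acc += rng.choice(builder.alphabet)
        while uid_of(acc) in backbone_uids:
            acc += rng.choice(builder.alphabet)
        backbone_uids.add(uid_of(acc))
        backbone.append(acc)

    g = builder.graph
    n_routes = 1
    for level, n_alt in enumerate(alternatives):
        product, precursor = backbone[level], backbone[level + 1]
        partner_uids: set[str] = set()
        for _ in range(n_alt):
            partner = rng.choice(builder.alphabet)
            while uid_of(partner) in partner_uids | backbone_uids:
                partner += rng.choice(builder.alphabet)
            partner_uids.add(uid_of(partner))
            ce = build_chemical_equation(
                f"{precursor}.{partner}>>{product}", policy
            )
            for r_uid in ce.reactants:
                g.add_edge(ce.molecules[r_uid], ce)
            g.add_edge(ce, ce.molecules[ce.products[0]])
        n_routes *= n_alt
    return GeneratedTree(g, n_routes)
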