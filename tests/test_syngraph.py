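"""Graph data model: roots/leaves, equality, merge algebra, subset,
data-model conversion, route extraction."""

import random

import pytest

from synroutes import (
    BIPARTITE,
    MONOPARTITE_MOLECULES,
    MONOPARTITE_REACTIONS,
    IdentityPolicy,
    RouteSpec,
    SynGraph,
    build_chemical_equation,
    convert_data_model,
    extract_routes,
    generate_route,
    generate_tree,
    is_subset,
    merge,
    roots_and_leaves,
    syngraph_equal,
)
from synroutes.chem import CANONICAL_SMILES_NO_STEREO
from synroutes.exceptions import (
    AmbiguousTargetError,
    CyclicInputError,
    EmptyGraphError,
    LossyConversionError,
    ModelMismatchError,
)
from .conftest import as_reactions, reaction_chain


def random_routes(n, seed, max_depth=4):
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        depth = rng.randint(1, max_depth)
        branches = ()
        if depth >= 2 and rng.random() < 0.5:
            branches = ((rng.randint(2, depth), rng.randint(1, 2)),)
        out.append(generate_route(
            RouteSpec(depth=depth, branch_points=branches,
                      seed=rng.randrange(10**6))
        ).route)
    return out


class TestRootsAndLeaves:
    def test_linear_chain_has_one_root_one_leaf(self):
        g, ces = reaction_chain("C>>CC", "CC.O>>CCO", "CCO.C>>CCOC")
        roots, leaves = roots_and_leaves(g)
        assert roots == [ces[2]]
        assert leaves == [ces[0]]

    def test_convergent_route_by_degree_count(self, y_route):
        g = as_reactions(y_route)
        roots, leaves = roots_and_leaves(g)
        assert len(roots) == 1 and len(leaves) == 2

    def test_empty_graph_refused(self):
        with pytest.raises(EmptyGraphError):
            roots_and_leaves(SynGraph(BIPARTITE))


class TestEquality:
    def test_rebuild_from_permuted_input_is_equal(self, linear3):
        doc_edges = linear3.edges()
        rebuilt = SynGraph(BIPARTITE)
        for p, c in reversed(doc_edges):
            rebuilt.add_edge(p, c)
        assert syngraph_equal(linear3, rebuilt)

    def test_reagent_differences_do_not_split_routes(self):
        a, b = SynGraph(MONOPARTITE_REACTIONS), SynGraph(MONOPARTITE_REACTIONS)
        a.add_node(build_chemical_equation("CCO.CC(=O)O>>CC(=O)OCC.O"))
        b.add_node(build_chemical_equation("CCO.CC(=O)O>[H+]>CC(=O)OCC.O"))
        assert syngraph_equal(a, b)

    def test_stereo_difference_depends_on_identity_policy(self):
        strict_pair, relaxed_pair = [], []
        for policy in (IdentityPolicy(),
                       IdentityPolicy(CANONICAL_SMILES_NO_STEREO)):
            graphs = []
            for smiles in ("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O"):
                g = SynGraph(MONOPARTITE_REACTIONS)
                g.add_node(build_chemical_equation(f"CC(N)=O.C>>{smiles}",
                                                   policy))
                graphs.append(g)
            (strict_pair if policy.policy_name != CANONICAL_SMILES_NO_STEREO
             else relaxed_pair).extend(graphs)
        assert not syngraph_equal(*strict_pair)
        assert syngraph_equal(*relaxed_pair)

    def test_model_mismatch_is_an_error_not_false(self, linear3):
        with pytest.raises(ModelMismatchError):
            syngraph_equal(linear3, as_reactions(linear3))


class TestMerge:
    def test_idempotent(self, linear3):
        assert syngraph_equal(merge([linear3, linear3]), linear3)

    def test_shared_root_reaction_union_counts(self):
        """Two 3-step routes sharing their final reaction merge to 5 steps."""
        shared = "CCO.CC(=O)O>>CC(=O)OCC"
        a, _ = reaction_chain("C>>CC", "CC.O>>CCO", shared)
        b, _ = reaction_chain("CC(C)=O>>CC(C)O", "CC(C)O>>CC(=O)O", shared)
        merged = merge([a, b])
        assert len(merged.nodes()) == 5
        assert is_subset(a, merged) and is_subset(b, merged)

    def test_commutative_associative_on_random_triples(self):
        rng = random.Random(5)
        for trial in range(10):
            x, y, z = random_routes(3, seed=rng.randrange(10**6))
            assert syngraph_equal(merge([x, y]), merge([y, x]))
            assert syngraph_equal(merge([merge([x, y]), z]),
                                  merge([x, merge([y, z])]))

    def test_empty_and_mismatched_inputs_rejected(self, linear3):
        with pytest.raises(EmptyGraphError):
            merge([])
        with pytest.raises(ModelMismatchError):
            merge([linear3, as_reactions(linear3)])


class TestIsSubset:
    def test_truncated_branch_is_subset(self, y_route):
        g = as_reactions(y_route)
        roots, leaves = roots_and_leaves(g)
        truncated = SynGraph(MONOPARTITE_REACTIONS)
        for p, c in g.edges():
            if p != leaves[0]:
                truncated.add_edge(p, c)
        assert is_subset(truncated, g)
        assert not is_subset(g, truncated)

    def test_proper_subset_excludes_equality(self, linear3):
        assert not is_subset(linear3, linear3)

    def test_disjoint_routes_are_not_subsets(self):
        a = generate_route(RouteSpec(depth=2, seed=100)).route
        b = generate_route(RouteSpec(depth=2, seed=200)).route
        assert not is_subset(a, b)

    def test_subset_of_merge(self):
        for seed in range(10):
            x, y = random_routes(2, seed=seed)
            m = merge([x, y])
            if len(m.nodes()) > len(x.nodes()):
                assert is_subset(x, m)


class TestConvertDataModel:
    def test_bipartite_chain_projects_to_reaction_chain(self):
        ce1 = build_chemical_equation("CCO.CC(=O)O>>CC(=O)OCC")
        ce2 = build_chemical_equation("CC(=O)OCC.N>>CC(=O)NCC")
        g = SynGraph(BIPARTITE)
        for ce in (ce1, ce2):
            for u in ce.reactants:
                g.add_edge(ce.molecules[u], ce)
            for u in ce.products:
                g.add_edge(ce, ce.molecules[u])
        mpr = convert_data_model(g, MONOPARTITE_REACTIONS)
        assert mpr.edges() == [(ce1, ce2)]

    def test_molecule_projection_follows_intermediates(self):
        """M1 -> M2 -> M3 when R1 makes M2 from M1 and R2 makes M3 from M2."""
        ce1 = build_chemical_equation("CCO>>CC=O")
        ce2 = build_chemical_equation("CC=O>>CC(=O)O")
        g = SynGraph(BIPARTITE)
        for ce in (ce1, ce2):
            for u in ce.reactants:
                g.add_edge(ce.molecules[u], ce)
            for u in ce.products:
                g.add_edge(ce, ce.molecules[u])
        mpm = convert_data_model(g, MONOPARTITE_MOLECULES)
        forms = [(p.canonical_form, c.canonical_form) for p, c in mpm.edges()]
        assert forms == [("CC=O", "CC(=O)O"), ("CCO", "CC=O")]

    def test_reaction_round_trip_preserves_structure(self):
        for seed in range(10):
            route = random_routes(1, seed=seed)[0]
            mpr = convert_data_model(route, MONOPARTITE_REACTIONS)
            back = convert_data_model(mpr, BIPARTITE)
            assert syngraph_equal(back, route)

    def test_molecule_model_is_a_dead_end(self, linear3):
        mpm = convert_data_model(linear3, MONOPARTITE_MOLECULES)
        with pytest.raises(LossyConversionError):
            convert_data_model(mpm, BIPARTITE)

    def test_descriptor_projection_independent_of_start(self, y_route):
        from synroutes import n_branches, n_steps
        mpr = convert_data_model(y_route, MONOPARTITE_REACTIONS)
        assert n_steps(y_route) == n_steps(mpr)
        assert n_branches(y_route) == n_branches(mpr)


class TestExtractRoutes:
    def test_linear_tree_yields_itself(self, linear3):
        routes = extract_routes(linear3)
        assert len(routes) == 1
        assert syngraph_equal(routes[0], linear3)

    @pytest.mark.parametrize("alternatives, expected", [
        ([2], 2),
        ([2, 2], 4),
        ([1, 1, 1], 1),
        ([3, 2], 6),
    ])
    def test_route_count_is_product_of_alternatives(self, alternatives,
                                                    expected):
        gen = generate_tree(alternatives, seed=9)
        routes = extract_routes(gen.tree)
        assert len(routes) == expected == gen.n_routes
        for i, a in enumerate(routes):
            for b in routes[i + 1:]:
                assert not syngraph_equal(a, b)

    def test_multiple_roots_rejected(self):
        g = SynGraph(BIPARTITE)
        ce = build_chemical_equation("CCO.CC(=O)O>>CC(=O)OCC.O")
        for u in ce.reactants:
            g.add_edge(ce.molecules[u], ce)
        for u in ce.products:
            g.add_edge(ce, ce.molecules[u])  # two product roots
        with pytest.raises(AmbiguousTargetError):
            extract_routes(g)

    def test_cycle_rejected(self):
        g = SynGraph(BIPARTITE)
        ce1 = build_chemical_equation("CCO>>CC=O")
        ce2 = build_chemical_equation("CC=O>>CCO")
        m_ethanol = ce1.molecules[ce1.reactants[0]]
        m_aldehyde = ce1.molecules[ce1.products[0]]
        g.add_edge(m_ethanol, ce1)
        g.add_edge(ce1, m_aldehyde)
        g.add_edge(m_aldehyde, ce2)
        g.add_edge(ce2, m_ethanol)
        with pytest.raises(CyclicInputError):
            extract_routes(g)
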