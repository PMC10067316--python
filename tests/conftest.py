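import pytest

from synroutes import (
    MONOPARTITE_REACTIONS,
    RouteSpec,
    SynGraph,
    build_chemical_equation,
    convert_data_model,
    generate_route,
)


@pytest.fixture
def linear3():
    """Linear 3-reaction bipartite route."""
    return generate_route(RouteSpec(depth=3, seed=11)).route


@pytest.fixture
def y_route():
    """Two branches converging into the final step: {R1->R3, R2->R3}."""
    return generate_route(RouteSpec(depth=2, branch_points=((2, 1),),
                                    seed=12)).route


def reaction_chain(*reaction_smiles):
    """Monopartite-reactions chain built from explicit reaction SMILES."""
    g = SynGraph(MONOPARTITE_REACTIONS)
    ces = [build_chemical_equation(s) for s in reaction_smiles]
    for ce in ces:
        g.add_node(ce)
    for a, b in zip(ces, ces[1:]):
        g.add_edge(a, b)
    return g, ces


def as_reactions(route):
    return convert_data_model(route, MONOPARTITE_REACTIONS)
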