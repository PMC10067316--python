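"""Translation between route data formats, with SynGraph as the hub.

Two orthogonal transformations exist in the toolkit: *translation* between
data formats (CASP tree JSON, node/edge-list JSON, DOT text) and *conversion*
between data models (bipartite / monopartite).  Every translation pipeline
passes through SynGraph — the only representation that converts between data
models — so adding one new reader or writer connects a new format to every
existing one.

The format registry is extensible: :func:`register_format` adds a
reader/writer pair without touching existing entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Callable, Optional

from .chem import (
    CHEMICAL_EQUATION,
    MOLECULE,
    DEFAULT_POLICY,
    IdentityPolicy,
    build_chemical_equation,
    canonicalize_molecule,
)
from .exceptions import DanglingEdgeError, DialectError, UnknownFormatError
from .syngraph import BIPARTITE, SynGraph, convert_data_model

CASP_TREE_JSON = "casp_tree_json"
NODE_EDGE_JSON = "node_edge_json"
DOT_TEXT = "dot_text"
SYNGRAPH = "syngraph"  # the in-memory hub, addressable as an output format


@dataclass
class RouteDocument:
    """A route serialized in a registered external format."""

    format_name: str
    payload: Any

    def dumps(self) -> str:
        """Render the payload as text (JSON for dict payloads)."""
        if isinstance(self.payload, str):
            return self.payload
        return json.dumps(self.payload, indent=2, sort_keys=True)


def _payload_of(doc) -> Any:
    payload = doc.payload if isinstance(doc, RouteDocument) else doc
    if isinstance(payload, str):
        payload = json.loads(payload)
    return payload


# ---------------------------------------------------------------------------
# CASP nested-tree dialect
# ---------------------------------------------------------------------------

def read_casp_tree(doc, policy: IdentityPolicy = DEFAULT_POLICY) -> SynGraph:
    """Read a CASP-style nested route tree into a bipartite SynGraph.

    The dialect alternates ``mol`` and ``reaction`` nodes; each node carries
    a ``smiles`` string and a ``children`` list (extra keys are tolerated).
    The tree root is the target molecule and tree children are precursors,
    so graph edges run child -> parent: precursor molecule -> reaction ->
    product molecule, i.e. the synthetic direction.

    A reaction node's own reaction SMILES (if its ``smiles`` contains
    ``>``) is preferred over reconstruction from the neighbouring molecule
    nodes, preserving reagent information for non-identity layers.
    """
    tree = _payload_of(doc)
    if not isinstance(tree, dict):
        raise DialectError("casp_tree_json payload must be a JSON object")
    if _node_type(tree) != "mol":
        raise DialectError("the root of a route tree must be a mol node "
                           "(the target compound)")
    g = SynGraph(BIPARTITE)
    _walk_mol(tree, None, g, policy)
    return g


def _node_type(node: dict) -> str:
    try:
        return str(node["type"]).lower()
    except (KeyError, TypeError):
        raise DialectError(f"tree node lacks a 'type' key: {node!r}") from None


def _walk_mol(node: dict, consuming_reaction, g: SynGraph,
              policy: IdentityPolicy):
    if _node_type(node) != "mol":
        raise DialectError(
            f"expected a mol node, got {node.get('type')!r} "
            f"(mol and reaction nodes must alternate)"
        )
    mol = canonicalize_molecule(node["smiles"], policy)
    g.add_node(mol)
    if consuming_reaction is not None:
        g.add_edge(mol, consuming_reaction)
    for child in node.get("children", []):
        _walk_reaction(child, mol, g, policy)
    return mol


def _walk_reaction(node: dict, product, g: SynGraph, policy: IdentityPolicy):
    if _node_type(node) != "reaction":
        raise DialectError(
            f"expected a reaction node, got {node.get('type')!r} "
            f"(mol and reaction nodes must alternate)"
        )
    children = node.get("children", [])
    smiles = node.get("smiles", "")
    if ">" not in smiles:
        precursors = [c["smiles"] for c in children]
        if not precursors:
            raise DialectError("reaction node with neither a reaction SMILES "
                               "nor precursor children")
        smiles = f"{'.'.join(precursors)}>>{product.canonical_form}"
    ce = build_chemical_equation(smiles, policy)
    g.add_node(ce)
    g.add_edge(ce, product)
    for child in children:
        _walk_mol(child, ce, g, policy)


def write_casp_tree(g: SynGraph) -> RouteDocument:
    """Serialize a bipartite route back into the nested-tree dialect.

    Only tree-shaped bipartite routes are expressible: every molecule must
    have at most one producing reaction (a nested tree cannot represent
    convergence alternatives).
    """
    from .syngraph import roots_and_leaves  # local: avoid import cycle noise

    if g.data_model != BIPARTITE:
        raise DialectError("casp_tree_json can only express bipartite routes")
    roots, _ = roots_and_leaves(g)
    if len(roots) != 1 or roots[0].kind != MOLECULE:
        raise DialectError("casp_tree_json needs a single target molecule")
    rev = g.parents_map()
    for node in g:
        if node.kind == MOLECULE and len(rev[node]) > 1:
            raise DialectError(
                "molecule with multiple producing reactions cannot be "
                "nested as a tree"
            )

    def mol_subtree(mol) -> dict:
        return {
            "type": "mol",
            "smiles": mol.canonical_form,
            "children": [reaction_subtree(ce) for ce in
                         sorted(rev[mol], key=lambda n: n.uid)],
        }

    def reaction_subtree(ce) -> dict:
        return {
            "type": "reaction",
            "smiles": ce.smiles,
            "children": [mol_subtree(m) for m in
                         sorted(rev[ce], key=lambda n: n.uid)],
        }

    return RouteDocument(CASP_TREE_JSON, mol_subtree(roots[0]))


# ---------------------------------------------------------------------------
# node/edge-list JSON dialect
# ---------------------------------------------------------------------------

def write_node_edge_json(g: SynGraph) -> RouteDocument:
    """Serialize a SynGraph as sorted node and edge dictionaries."""
    nodes = [
        {
            "uid": n.uid,
            "kind": n.kind,
            "structure": n.canonical_form if n.kind == MOLECULE else n.smiles,
        }
        for n in g.nodes()
    ]
    edges = [
        {"source": p.uid, "target": c.uid} for p, c in g.edges()
    ]
    payload = {
        "data_model": g.data_model,
        "identity_policy": g.nodes()[0].policy.policy_name if len(g) else
        DEFAULT_POLICY.policy_name,
        "source": g.source_label,
        "nodes": nodes,
        "edges": edges,
    }
    return RouteDocument(NODE_EDGE_JSON, payload)


def read_node_edge_json(doc, policy: Optional[IdentityPolicy] = None) -> SynGraph:
    """Rebuild a SynGraph from a node/edge document.

    Node chemistry is re-canonicalized from the stored structure strings
    under the document's identity policy, so read∘write is the identity up
    to :func:`~synroutes.syngraph.syngraph_equal`.
    """
    payload = _payload_of(doc)
    if policy is None:
        policy = IdentityPolicy(
            payload.get("identity_policy", DEFAULT_POLICY.policy_name)
        )
    g = SynGraph(payload.get("data_model", BIPARTITE),
                 payload.get("source", ""))
    by_uid: dict = {}
    for entry in payload.get("nodes", []):
        if entry["kind"] == MOLECULE:
            node = canonicalize_molecule(entry["structure"], policy)
        elif entry["kind"] == CHEMICAL_EQUATION:
            node = build_chemical_equation(entry["structure"], policy)
        else:
            raise DialectError(f"unknown node kind {entry['kind']!r}")
        by_uid[entry["uid"]] = node
        g.add_node(node)
    for edge in payload.get("edges", []):
        for end in ("source", "target"):
            if edge[end] not in by_uid:
                raise DanglingEdgeError(
                    f"edge references unknown node uid {edge[end]!r}"
                )
        g.add_edge(by_uid[edge["source"]], by_uid[edge["target"]])
    return g


# ---------------------------------------------------------------------------
# DOT (Graphviz) export — presentation only, no read-back
# ---------------------------------------------------------------------------

def write_dot(g: SynGraph) -> RouteDocument:
    """Deterministic DOT digraph; molecules drawn as ellipses, reactions as
    boxes."""
    def quote(s: str) -> str:
        return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'

    lines = ["digraph syngraph {", "  rankdir=LR;"]
    for n in g.nodes():
        shape = "ellipse" if n.kind == MOLECULE else "box"
        label = n.canonical_form if n.kind == MOLECULE else n.smiles
        lines.append(f"  {quote(n.uid)} [shape={shape}, label={quote(label)}];")
    for p, c in g.edges():
        lines.append(f"  {quote(p.uid)} -> {quote(c.uid)};")
    lines.append("}")
    return RouteDocument(DOT_TEXT, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# registry and the hub pipeline
# ---------------------------------------------------------------------------

@dataclass
class _FormatEntry:
    reader: Optional[Callable] = None
    writer: Optional[Callable] = None


_REGISTRY: dict[str, _FormatEntry] = {
    CASP_TREE_JSON: _FormatEntry(reader=read_casp_tree,
                                 writer=write_casp_tree),
    NODE_EDGE_JSON: _FormatEntry(reader=read_node_edge_json,
                                 writer=write_node_edge_json),
    DOT_TEXT: _FormatEntry(writer=write_dot),
}


def registered_formats() -> dict[str, dict[str, bool]]:
    """Registered format names with their read/write capabilities."""
    return {
        name: {"read": e.reader is not None, "write": e.writer is not None}
        for name, e in sorted(_REGISTRY.items())
    }


def register_format(name: str, reader: Optional[Callable] = None,
                    writer: Optional[Callable] = None) -> None:
    """Register a new format; it becomes reachable from every other format
    through the SynGraph hub."""
    entry = _REGISTRY.setdefault(name, _FormatEntry())
    if reader is not None:
        entry.reader = reader
    if writer is not None:
        entry.writer = writer


def _lookup(name: str, direction: str) -> Callable:
    entry = _REGISTRY.get(name)
    fn = getattr(entry, direction, None) if entry else None
    if fn is None:
        available = sorted(
            n for n, e in _REGISTRY.items()
            if getattr(e, direction) is not None
        )
        raise UnknownFormatError(
            f"no registered {direction} for format {name!r}; "
            f"available: {available}"
        )
    return fn


def translate(input_format: str, payload, output_format: str,
              out_data_model: str = BIPARTITE,
              policy: IdentityPolicy = DEFAULT_POLICY):
    """Full pipeline: read(input) -> SynGraph -> convert -> write(output).

    ``output_format='syngraph'`` returns the converted SynGraph itself.
    """
    if input_format == SYNGRAPH:
        g = payload
    else:
        g = _lookup(input_format, "reader")(payload, policy)
    g = convert_data_model(g, out_data_model)
    if output_format == SYNGRAPH:
        return g
    return _lookup(output_format, "writer")(g)
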