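# Methods

## Data model

A synthetic route is stored as a `SynGraph`: a dictionary mapping each node
to the set of its children, with edges implicit and directed along the
synthetic direction (starting materials → target). The target is therefore
the unique sink ("root") of a route and starting materials are sources
("leaves"). Every node is a key, possibly with an empty child set, so the
mapping is total and degree queries need no search. Three data models are
supported — bipartite (molecule and reaction nodes joined by role edges),
monopartite reactions, monopartite molecules — and the bipartite and
reaction-only forms are mutually convertible. The molecule-only form keeps
reactions implicit, so conversion *out* of it is refused rather than
guessed.

Nodes are value objects. A molecule's identity string is derived from its
structure under a selectable policy: canonical isomeric SMILES (default),
canonical SMILES without stereochemistry (stereoisomers collapse), or
InChIKey (additionally collapses most tautomer pairs). A chemical
equation's identity hashes the sorted reactant and product uids only.
Consequences worth spelling out:

* routes that differ only in reagents, catalysts or conditions are *equal*;
* relaxing the identity policy can merge nodes but never split a pair that
  was equal under the stricter policy;
* graph equality, union (merge) and proper-subset testing reduce to
  dictionary comparisons under uid equality, avoiding isomorphism
  algorithms entirely.

Role attribution when building an equation from reaction SMILES: every
agent-block molecule is a reagent, and any molecule whose uid appears among
both reactants and products is reassigned to reagent (it is a spectator at
this identity layer). Without atom mapping — deliberately out of scope — a
consumed molecule that also appears unchanged on the product side cannot be
told apart from a true spectator; the verbatim-presence rule is the
documented convention. Stoichiometric multiplicities are recorded but
excluded from identity.

## Route extraction

A synthetic tree (union of routes sharing one target) may contain
*convergence points*: molecules produced by two or more reactions.
`extract_routes` enumerates all distinct routes by selecting exactly one
producing reaction at every convergence point reached from the target and
closing down to the starting materials; the route count equals the product
of the alternatives over reachable convergence points. Cyclic input and
multi-root input are refused — route extraction is defined on acyclic
single-target trees only.

## Descriptors

All descriptors are computed on the monopartite-reactions projection, so
their values are independent of the representation the caller holds.
For a route with reaction nodes *V*:

| descriptor | definition | default |
|---|---|---|
| `n_steps` | unique reaction nodes | — |
| `longest_linear_sequence` | max reactions on any leaf→root path | — |
| `n_branches` | Σ<sub>v∈V</sub> max(0, indeg(v) − 1) | — |
| `convergence` | LLS / n_steps ∈ (0, 1] | — |
| `avg_branching_factor` | (non-root nodes)/(non-leaf nodes) | undefined for 1 step |

Two conventions exist for counting branches: counting *departures from
linearity* (one per binary convergence; zero for linear routes) versus
counting every parent node feeding a convergence (two per binary
convergence). The first is the default because it matches the intuitive
"number of times the route departs from linearity"; the literal
parent-count is available via `n_branches(route, literal_parent_count=True)`.
On tree-shaped routes the default convention equals (number of leaf→root
paths − 1), which the tests verify by explicit path enumeration.

## Graph edit distance

The distance between two routes is the minimum-cost edit path transforming
one graph into an isomorph of the other. Costs: node insertion and
deletion 1 each; node substitution `1 − similarity(a, b)` for same-kind
nodes (hence 0 for uid-equal nodes) and 1 for cross-kind swaps; edge
insertion and deletion 1 each, preserved edges free. Edge edits at unit
cost are the common GED convention and match the NetworkX defaults; note
this means "appending one reaction" costs 2 (node + edge), not 1.

Similarity uses Morgan (circular) fingerprints, radius 2, 2048 bits, for
molecules and atom-pair difference fingerprints for reactions, compared
with Tanimoto similarity (Dice selectable). Reaction fingerprints are
computed from the reagent-free identity SMILES, so the substitution cost
honours the identity layer. Values are clamped to [0, 1]; fingerprints are
cached per node, which matters in the O(n²) distance-matrix loop.

The exact search is NetworkX's A*-based `graph_edit_distance` with these
cost functions. For two single-root graphs the roots are pinned to each
other (`roots=`), a substantial prune that is natural for routes: both
targets occupy the same position. Implementation note: the roots are
pinned at zero substitution cost and the true root-pair cost is added as a
constant afterwards — equivalent mathematically, and it keeps the search's
internal pruning bound (which omits the pinned pair's cost) consistent for
any cost value. An anytime mode (`method="approximate"`, the first yield
of the optimizing generator, unrooted) provides a fast upper bound for
graphs too large for the exact search.

Distance matrices compute the upper triangle and mirror it; the parallel
path (joblib over pairs) evaluates the same pure function pairwise and is
bit-identical to the serial path. GED is computed on the
monopartite-reactions projection by default (one node per synthetic step);
the data model is selectable through `GedParams`.

## Clustering

Routes are clustered from the precomputed GED matrix. Agglomerative
clustering (single linkage by default) needs the cluster count k, which is
not asked of the user: every k in [2, n−1] is fitted and the k maximizing
the silhouette score on the distance matrix is kept, ties broken toward
smaller k (parsimony). HDBSCAN needs no k and may emit a noise label −1,
which summaries report as its own row. With no method specified,
agglomerative is used below 15 routes and HDBSCAN from 15 up. At least 3
routes are required (silhouette needs 2 ≤ k < n). A matrix in which all
routes are mutually equidistant (including all-zero) is flagged as
degenerate and returned as a single trivial cluster with silhouette NaN
rather than fitted. Each cluster is represented by its medoid, the member
minimizing the summed intra-cluster distance.

## Synthetic route generator

The generator emulates the *shape* of CASP output — seeded, reproducible
route trees of controlled depth and branching over valid structures — not
its chemistry. Toy reactions concatenate the SMILES of their reactants
into the product string; every fragment in the 20-entry alphabet starts
and ends with an atom that tolerates one extra single bond, so every
concatenation parses. Product uniqueness within a fixture is enforced by
deterministically appending further fragments on uid collision, and fresh
starting materials are re-drawn if they would coincide with a synthesized
product; both guarantees are what make the by-construction descriptor
values (`n_steps = depth + Σ branch depths`, etc.) exact ground truth.
Branch attachment positions start at main-chain step 2, since a side chain
into the first step would not depart from linearity.

What passing tests on generated routes do **not** show: behaviour on real
CASP output with mapped atoms, reagent annotations, stereochemically rich
intermediates, by-products, or failed/partial routes. The translation layer
tolerates extra JSON keys and prefers a reaction node's own reaction SMILES
(preserving reagents), but chemical plausibility of the fixtures is
explicitly a non-goal — the identity and graph layers never inspect
mechanism.

`perturb_route` applies known edits (substituting a starting-material
reactant, or prepending a reaction below a leaf) and records the cost of
the constructed edit path — including the induced edge edits — as an upper
bound on the true GED, which tests then verify.

## Numerical and scale choices

* Deterministic iteration everywhere user-visible: nodes sorted by uid for
  serialization, DOT output byte-stable, seeded `random.Random` threaded
  explicitly through the generators (no global state).
* Exhaustive GED oracle checks run on all pairs of 50 generated graphs of
  ≤ 4 reaction nodes — small enough for brute-force enumeration over all
  injective node mappings, large enough to exercise insertions, deletions,
  substitutions and edge effects together. Descriptor ground truth is
  checked on 200 seeded specs, identity-layer stability on 100 randomized
  rewritings, round-trips on 100 fixtures, merge algebra on 100 triples,
  planted-partition recovery on 100 seeded two-block matrices.
* The acceptance script processes 12 routes from 3 simulated sources —
  enough for a non-trivial distance matrix (66 pairs) and clustering while
  keeping the exact GED search comfortably fast.

## Known limitations

* No atom mapping: role attribution cannot detect a reagent that is
  consumed and regenerated across steps, and reaction fingerprints are
  unmapped.
* GED values depend on fingerprint settings; no numeric parity with other
  route-distance implementations (e.g. tree-edit-distance approaches) is
  claimed.
* Cyclic reaction networks are refused by route extraction rather than
  handled.
* The exact GED search scales poorly beyond ~10-node graphs; use the
  anytime mode or coarser data models there.
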