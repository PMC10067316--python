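# synroutes

A Python toolkit to represent, interconvert, describe, compare and cluster
**synthetic chemical routes** — the multi-step reaction plans produced by
Computer-Aided Synthesis Planning (CASP) tools or extracted from reaction
networks.

Different CASP tools emit routes in mutually incompatible formats and graph
models, which makes comparing, merging and ranking their predictions
painful. `synroutes` addresses this with a single hub data structure, the
**SynGraph**: an adjacency mapping `parent → {children}` whose nodes are
chemical *value objects*,

* a **Molecule** is identified by a structure-derived string (canonical
  isomeric SMILES by default; no-stereo SMILES or InChIKey selectable), so
  any two writings of the same structure collapse onto one node;
* a **ChemicalEquation** is identified by a hash of
  `sorted(reactant uids) >> sorted(product uids)` — reagents, conditions and
  procedures are deliberately outside the identity, so the same
  transformation run with different catalysts is one node.

Edges follow the synthetic direction (starting materials → target), so the
target compound is the unique sink of a route. Three data models are
interconvertible: bipartite (molecules + reactions), monopartite reactions
only, and monopartite molecules only (lossy). Because nodes are value
objects, route equality, merging (union), and sub-route testing are plain
dictionary arithmetic — no isomorphism search.

On top of the data model the toolkit provides:

* **Translation** between formats (CASP nested-tree JSON, node/edge-list
  JSON, Graphviz DOT) through the SynGraph hub, orthogonal to data-model
  conversion; the format registry is user-extensible.
* **Route descriptors** on the reaction-only projection: number of steps
  *N*, longest linear sequence *LLS* (max reactions on any
  starting-material → target path), number of branches
  Σ<sub>nodes</sub> max(0, indeg−1), convergence = *LLS*/*N*, and average
  branching factor (non-root nodes / non-leaf nodes). The descriptor
  factory is extensible by name.
* **Chemistry-aware graph edit distance (GED)**: node insertion/deletion
  cost 1, substitution cost `1 − similarity` using Morgan fingerprints for
  molecules and reaction difference fingerprints with Tanimoto similarity,
  exact A* search with the route roots pinned; parallel distance-matrix
  computation.
* **Clustering** from the GED matrix: agglomerative (single linkage) with
  the cluster count chosen by maximizing the silhouette score, or HDBSCAN
  for larger batches (≥ 15 routes by default), with per-cluster medoid
  representatives.
* A **`process_routes` facade** and a `routes` CLI that run the whole
  pipeline over batches of route files, plus a seeded **synthetic route
  generator** with by-construction ground truth for every descriptor.

## Worked example

```python
from synroutes import (RouteSpec, generate_route, compute_descriptors,
                       distance_matrix, cluster_routes, cluster_summary)

routes = [generate_route(RouteSpec(depth=d, branch_points=b, seed=s)).route
          for d, b, s in [(3, (), 1), (3, (), 2), (4, ((2, 2),), 3),
                          (4, ((3, 1),), 4), (2, (), 5), (5, ((4, 2),), 6)]]

for r in compute_descriptors(routes[2], "all", route_id="route_2"):
    print(f"{r.descriptor_name:24s} {r.value:.3f}")

dm = distance_matrix(routes)
result = cluster_routes(dm)
print("silhouette:", round(result.silhouette, 3))
print(cluster_summary(result, routes).to_string(index=False))
```

prints

```
avg_branching_factor     1.250
convergence              0.833
longest_linear_sequence  5.000
n_branches               1.000
n_steps                  6.000
silhouette: 0.266
 cluster  n_routes  mean_n_steps  mean_n_branches
       0         3      2.666667              0.0
       1         1      7.000000              1.0
       2         1      6.000000              1.0
       3         1      5.000000              1.0
```

`route_2` has six reactions of which five lie on its longest branch: one
binary convergence, hence convergence 5/6 ≈ 0.83. The clustering groups the
three short linear routes together (cluster 0, mean 2.7 steps, no branches)
and leaves each longer branched route on its own; the modest silhouette
reflects that the singleton clusters are not tightly packed.

The same pipeline runs from the shell:

```bash
routes process --input routesA.json:aizynthfinder --input routesB.json:askcos \
    --functionality compute_descriptors --functionality clustering
routes helper   # lists every option and its default
```

which writes `routes.json` (bipartite node/edge lists by default),
`descriptors.csv`, `clusters.csv`, `cluster_summary.csv` and a process log.

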