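"""Independent brute-force graph edit distance for small graphs.

Enumerates every injective partial mapping between the node sets of two
SynGraphs and scores it directly from the edit-operation definition:
substitution cost for mapped pairs, unit deletion/insertion for unmapped
nodes, and one unit per edge that is not preserved by the mapping (edge
substitutions are free).  Intractable beyond a handful of nodes, but exact —
which is the point: it shares no code with the search under test.
"""

import itertools
from math import inf

from synroutes.similarity import DEFAULT_GED_PARAMS, node_substitution_cost


def brute_force_ged(a, b, params=DEFAULT_GED_PARAMS, pin_roots=False):
    na, nb = a.nodes(), b.nodes()
    ea = {(p.uid, c.uid) for p, c in a.edges()}
    eb = {(p.uid, c.uid) for p, c in b.edges()}

    root_a = root_b = None
    if pin_roots:
        roots_a = [n for n in na if not a.children(n)]
        roots_b = [n for n in nb if not b.children(n)]
        assert len(roots_a) == 1 and len(roots_b) == 1
        root_a, root_b = na.index(roots_a[0]), nb.index(roots_b[0])

    best = inf
    for k in range(min(len(na), len(nb)) + 1):
        for picked_a in itertools.combinations(range(len(na)), k):
            for picked_b in itertools.permutations(range(len(nb)), k):
                mapping = dict(zip(picked_a, picked_b))
                if pin_roots and mapping.get(root_a) != root_b:
                    continue
                cost = (len(na) - k) * params.deletion_cost \
                    + (len(nb) - k) * params.insertion_cost
                for i, j in mapping.items():
                    cost += node_substitution_cost(na[i], nb[j], params)
                uid_map = {na[i].uid: nb[j].uid for i, j in mapping.items()}
                for u, v in ea:
                    if (uid_map.get(u), uid_map.get(v)) not in eb:
                        cost += 1.0  # edge deleted
                inv = {v: u for u, v in uid_map.items()}
                for u, v in eb:
                    if (inv.get(u), inv.get(v)) not in ea:
                        cost += 1.0  # edge inserted
                best = min(best, cost)
    return best
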