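"""From-definition agglomerative Ward oracle for cross-checking clustering.

Implements Ward's minimum-variance agglomeration directly through the
Lance-Williams recurrence on pairwise distances,

    d(u+v, s)^2 = [ (|s|+|u|) d(u,s)^2 + (|s|+|v|) d(v,s)^2
                    - |s| d(u,v)^2 ] / (|s|+|u|+|v|),

merging the closest pair at every step and stopping once the next merge
height would exceed the cut (Ward heights are monotone, so this equals
cutting the full dendrogram at that height).  Independent of scipy's
nearest-neighbor-chain implementation.
"""

from __future__ import annotations

from typing import FrozenSet, Set

import numpy as np


def ward_partition(dist: np.ndarray, cut: float) -> Set[FrozenSet[int]]:
    n = dist.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    d2 = {
        (i, j): float(dist[i, j]) ** 2 for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(members) > 1:
        (u, v), best = min(
            (
                ((a, b), d2[(min(a, b), max(a, b))])
                for a in members
                for b in members
                if a < b
            ),
            key=lambda kv: kv[1],
        )
        if np.sqrt(best) > cut:
            break
        nu, nv = len(members[u]), len(members[v])
        merged = members[u] | members[v]
        new_d2 = {}
        for s in members:
            if s in (u, v):
                continue
            ns = len(members[s])
            dus = d2[(min(u, s), max(u, s))]
            dvs = d2[(min(v, s), max(v, s))]
            new_d2[s] = (
                (ns + nu) * dus + (ns + nv) * dvs - ns * best
            ) / (ns + nu + nv)
        del members[u], members[v]
        d2 = {
            (a, b): val
            for (a, b), val in d2.items()
            if a not in (u, v) and b not in (u, v)
        }
        members[next_id] = merged
        for s, val in new_d2.items():
            d2[(min(next_id, s), max(next_id, s))] = val
        next_id += 1
    return {fs for fs in members.values()}
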