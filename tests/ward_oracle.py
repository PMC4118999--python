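"""Independent brute-force Ward oracle for linkage validation.

Re-evaluates the Ward merge criterion from cluster centroids in exact
rational arithmetic at every agglomeration step, instead of updating a
distance matrix with the Lance-Williams recurrence.  For points in
Euclidean space the Ward cost of merging clusters A and B is

    cost(A, B) = 2 |A| |B| / (|A| + |B|) * ||centroid(A) - centroid(B)||^2

which equals the inter-cluster value the Lance-Williams ward recurrence
produces when started from squared Euclidean distances.  For 0/1 vectors
the squared Euclidean distance *is* the Hamming distance, so this oracle
checks the pipeline's ward.D-on-Hamming behavior directly.

Ties are broken by the lexicographically smallest cluster-id pair, the
same contract the implementation states; with exact arithmetic there is
no tolerance to choose.
"""

from fractions import Fraction

import numpy as np


def brute_force_ward(points: np.ndarray):
    """Return merges [(a, b, height, size), ...] with exact heights.

    Cluster ids follow the same scheme as the implementation: leaves are
    0..n-1, the t-th merge creates id n+t.
    """
    n, d = points.shape
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    exact = [[Fraction(int(v)) if float(v).is_integer() else Fraction(v) for v in row] for row in points.tolist()]
    for _ in range(n - 1):
        best = None
        ids = sorted(members)
        for ii in range(len(ids)):
            for jj in range(ii + 1, len(ids)):
                a, b = ids[ii], ids[jj]
                ma, mb = members[a], members[b]
                ca = [sum(exact[p][k] for p in ma) / len(ma) for k in range(d)]
                cb = [sum(exact[p][k] for p in mb) / len(mb) for k in range(d)]
                dist2 = sum((ca[k] - cb[k]) ** 2 for k in range(d))
                cost = Fraction(2 * len(ma) * len(mb), len(ma) + len(mb)) * dist2
                if best is None or cost < best[0] or (cost == best[0] and (a, b) < best[1]):
                    best = (cost, (a, b))
        cost, (a, b) = best
        members[next_id] = members.pop(a) + members.pop(b)
        merges.append((a, b, float(cost), len(members[next_id])))
        next_id += 1
    return merges
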