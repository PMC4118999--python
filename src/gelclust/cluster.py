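"""Hierarchical clustering of gels and partition comparison.

Gels are binary presence/absence vectors; the distance between two gels is
the Hamming distance (number of differing bits).  Agglomeration uses
Ward's method via the Lance-Williams recurrence applied to the input
distances as given (the classic "ward.D" convention of R's hclust; the
squared-distance "ward.D2" variant is available by flag).  Partitions are
compared with the Hubert-Arabie adjusted Rand index, and cluster validity
is assessed with silhouette widths plus a label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Partition",
    "PartitionComparison",
    "hamming_distance",
    "hamming_matrix",
    "ward_linkage",
    "cut_tree",
    "silhouette",
    "adjusted_rand_index",
    "permutation_validity_test",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class Dendrogram:
    """Merge sequence from agglomerative clustering.

    ``merges[t] = (a, b, height, size)`` joins clusters ``a`` and ``b``
    into a new cluster with id ``n_leaves + t``; leaves are 0..n-1 in
    ``sample_ids`` order.
    """

    sample_ids: list[str]
    merges: list[tuple[int, int, float, int]]
    variant: str = "ward.D"

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


@dataclass
class Partition:
    """Cluster labels (1..k) over a fixed sample ordering."""

    sample_ids: list[str]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("labels must align with sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        uniq = sorted(set(self.labels))
        if uniq != list(range(1, len(uniq) + 1)):
            # renumber to 1..k in order of first appearance
            seen: dict[int, int] = {}
            relab = []
            for lab in self.labels:
                if lab not in seen:
                    seen[lab] = len(seen) + 1
                relab.append(seen[lab])
            self.labels = relab

    @property
    def k(self) -> int:
        return len(set(self.labels))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, self.labels))

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    @classmethod
    def from_clusters(cls, clusters: dict[int, list[str]]) -> "Partition":
        pairs = [(s, lab) for lab in sorted(clusters) for s in clusters[lab]]
        ids = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        return cls(ids, labels)


@dataclass
class PartitionComparison:
    contingency: pd.DataFrame
    adjusted_rand: float
    adjusted_rand_2dp: float = field(init=False)

    def __post_init__(self) -> None:
        self.adjusted_rand_2dp = round(self.adjusted_rand, 2)


def hamming_distance(u, v) -> int:
    """Number of positions at which two equal-length binary vectors differ."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return int(np.count_nonzero(u != v))


def hamming_matrix(binary: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Hamming distances between the rows of a binary matrix."""
    x = binary.to_numpy()
    # |u - v| summed is the bit-difference count for 0/1 entries
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix([str(i) for i in binary.index], d)


def ward_linkage(d: DistanceMatrix, variant: str = "ward.D") -> Dendrogram:
    """Agglomerate by Ward's minimum-variance criterion.

    The Lance-Williams update
    ``D(ij,k) = [(ni+nk) D(i,k) + (nj+nk) D(j,k) - nk D(i,j)] / (ni+nj+nk)``
    is applied to the input distances as given (``ward.D``) or to their
    squares with square-root merge heights (``ward.D2``).  Ties in the
    minimum inter-cluster distance (within 1e-9 relative) are broken by
    the lexicographically smallest cluster-id pair, so the merge sequence
    is deterministic across platforms.
    """
    if variant not in ("ward.D", "ward.D2"):
        raise ValueError("variant must be 'ward.D' or 'ward.D2'")
    n = len(d.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    work = d.values.copy()
    if variant == "ward.D2":
        work = work**2
    # active clusters: id -> (row index in work, size)
    dist = {
        (i, j): work[i, j] for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        # find minimal pair with near-tie lexicographic tie-break
        dmin = min(dist[key] for key in _pairs(active))
        tol = max(1e-9 * abs(dmin), 1e-12)
        best = min(k for k in _pairs(active) if dist[k] <= dmin + tol)
        i, j = best
        ni, nj = sizes[i], sizes[j]
        height = dist[(i, j)]
        if variant == "ward.D2":
            height = float(np.sqrt(height))
        merges.append((i, j, float(height), ni + nj))
        # Lance-Williams update against every other active cluster
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[_key(i, k)]
            djk = dist[_key(j, k)]
            dij = dist[(i, j)]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            dist[_key(next_id, k)] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        sizes[next_id] = ni + nj
        next_id += 1
    return Dendrogram(sample_ids=list(d.sample_ids), merges=merges, variant=variant)


def _key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def _pairs(active: list[int]):
    s = sorted(active)
    for ii in range(len(s)):
        for jj in range(ii + 1, len(s)):
            yield (s[ii], s[jj])


def cut_tree(dend: Dendrogram, k: int) -> Partition:
    """Cut the dendrogram into k clusters by undoing the last k-1 merges.

    Labels are 1..k in order of first sample appearance.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + len(dend.merges)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t, (a, b, _h, _s) in enumerate(dend.merges[: n - k]):
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    labels = []
    seen: dict[int, int] = {}
    for r in roots:
        if r not in seen:
            seen[r] = len(seen) + 1
        labels.append(seen[r])
    return Partition(list(dend.sample_ids), labels)


def silhouette(d: DistanceMatrix, p: Partition):
    """Silhouette widths s(i) = (b - a) / max(a, b) from a distance matrix.

    ``a`` is the mean distance to the sample's own cluster, ``b`` the
    smallest mean distance to any other cluster; singleton clusters get
    width 0 by convention.  Returns ``(per_sample_widths, mean_width)``.
    """
    if p.k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if list(d.sample_ids) != list(p.sample_ids):
        raise ValueError("distance matrix and partition sample sets differ")
    labels = np.asarray(p.labels)
    dm = d.values
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = dm[i, own].sum() / (n_own - 1)
        b = min(
            dm[i, labels == lab].mean()
            for lab in np.unique(labels)
            if lab != labels[i]
        )
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths, float(widths.mean())


def adjusted_rand_index(p1: Partition, p2: Partition) -> PartitionComparison:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Computed from the pair-count contingency table; 1 means identical
    partitions, ~0 chance-level agreement.  The comparison object carries
    the full-precision value and its 2-decimal rounding.
    """
    s1, s2 = set(p1.sample_ids), set(p2.sample_ids)
    if s1 != s2:
        raise ValueError(
            "partitions cover different samples; "
            f"only in first: {sorted(s1 - s2)}; only in second: {sorted(s2 - s1)}"
        )
    d2 = p2.as_dict()
    labels2 = [d2[s] for s in p1.sample_ids]
    ct = pd.crosstab(
        pd.Series(p1.labels, name="partition_1"),
        pd.Series(labels2, name="partition_2"),
    )
    nij = ct.to_numpy()
    n = nij.sum()
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in nij.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in nij.sum(axis=0))
    expected = sum_a * sum_b / comb(int(n), 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # both partitions trivial
        ari = 1.0
    else:
        ari = (sum_ij - expected) / (max_index - expected)
    return PartitionComparison(contingency=ct, adjusted_rand=float(ari))


def permutation_validity_test(
    d: DistanceMatrix, p: Partition, n_perm: int = 999, seed: int = 0
):
    """Permutation p-value for the observed mean silhouette width.

    Cluster labels are shuffled over the samples (preserving cluster
    sizes) ``n_perm`` times; p = (1 + #{permuted mean >= observed}) /
    (n_perm + 1).  Seeded and reproducible.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    _w, observed = silhouette(d, p)
    rng = np.random.default_rng(seed)
    labels = np.asarray(p.labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _pw, mean_w = silhouette(d, Partition(list(p.sample_ids), perm.tolist()))
        if mean_w >= observed:
            count += 1
    p_value = (1 + count) / (n_perm + 1)
    return p_value, observed


def to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string.

    Branch lengths are parent-minus-child merge heights (leaves at
    height 0), adequate for visualization of the merge structure.
    """
    n = dend.n_leaves
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: dend.sample_ids[i] for i in range(n)}
    for t, (a, b, h, _s) in enumerate(dend.merges):
        new = n + t
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[new] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[new] = h
    return nodes[n + len(dend.merges) - 1] + ";"
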