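"""Time-wise consensus over per-segment clusterings and agglomerative grouping.

Per-segment crisp labelings are reduced to a normalized dissimilarity

    delta_ij = (1/N_s) * #{segments s : label_i(s) != label_j(s)}

(cluster identity is irrelevant — only co-membership within a segment
counts).  The dissimilarity is a pseudo-metric (each per-segment term is the
discrete partition metric), and is grouped by agglomerative hierarchical
clustering with "average" or "complete" linkage.

The agglomeration is implemented here with deterministic tie-breaking
(equal-height merges join the lexicographically smallest cluster-id pair);
an external reference implementation is used only as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UsageError

LINKAGE_METHODS = ("average", "complete")


@dataclass
class SegmentLabeling:
    """Per-segment crisp labels: (N_s, N_alpha) integer matrix with values 1..k."""

    labels: np.ndarray
    k: int
    q_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise UsageError("segment labels must be (N_s, N_alpha)")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise UsageError("segment labels must lie in 1..k")

    @property
    def n_segments(self) -> int:
        return self.labels.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.labels.shape[1]


@dataclass
class ConsensusMatrix:
    """Normalized dissimilarity and its dual similarity (1 - delta)."""

    delta: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise UsageError("delta must be square")
        self.delta = d

    @property
    def similarity(self) -> np.ndarray:
        return 1.0 - self.delta

    @property
    def n(self) -> int:
        return self.delta.shape[0]


@dataclass
class Dendrogram:
    """Merge table of an agglomerative clustering.

    Leaves are 0..n-1; the cluster created by merge step t gets id n + t.
    Each merge is (left_id, right_id, height, size) with left_id < right_id.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)
    method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_linkage_matrix(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix."""
        return np.array([[m[0], m[1], m[2], m[3]] for m in self.merges], dtype=float)


@dataclass
class GroupPartition:
    """Partition into groups numbered 1..n_groups by descending size."""

    group_of: np.ndarray
    n_groups: int
    linkage_method: str = "average"
    cut_point: float | None = None

    def __post_init__(self) -> None:
        self.group_of = np.asarray(self.group_of, dtype=int)
        if self.group_of.min() < 1 or self.group_of.max() > self.n_groups:
            raise UsageError("group indices must lie in 1..n_groups")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.group_of, minlength=self.n_groups + 1)[1:]

    def members(self, group: int) -> set[int]:
        return set(np.flatnonzero(self.group_of == group).tolist())

    def as_sets(self) -> list[set[int]]:
        return [self.members(g) for g in range(1, self.n_groups + 1)]


def dissimilarity_matrix(seg_labeling: SegmentLabeling) -> ConsensusMatrix:
    """Fraction of segments in which two atoms are NOT co-clustered."""
    labels = seg_labeling.labels
    n_s, n = labels.shape
    if n_s < 1:
        raise UsageError("need at least one segment")
    differ = np.zeros((n, n))
    for s in range(n_s):
        row = labels[s]
        differ += row[:, None] != row[None, :]
    delta = differ / n_s
    np.fill_diagonal(delta, 0.0)
    return ConsensusMatrix(delta, n_s)


def _check_delta(delta: np.ndarray) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise UsageError("delta must be square")
    if not np.allclose(delta, delta.T, atol=1e-9):
        raise UsageError("delta must be symmetric")
    return delta


def agglomerate(delta: np.ndarray, method: str = "average") -> Dendrogram:
    """Agglomerative hierarchical clustering on delta as the pairwise distance.

    Lance–Williams updates for "average" (size-weighted mean) and "complete"
    (maximum); both linkages are monotone, so merge heights never decrease.
    """
    if method not in LINKAGE_METHODS:
        raise UsageError(f"method must be one of {LINKAGE_METHODS}")
    delta = _check_delta(delta)
    n = delta.shape[0]
    if n < 2:
        raise UsageError("agglomeration needs at least 2 atoms")
    total = 2 * n - 1
    # dist[i, j] for i < j among active cluster ids; inf elsewhere
    dist = np.full((total, total), np.inf)
    iu = np.triu_indices(n, k=1)
    dist[iu] = delta[iu]
    size = np.zeros(total, dtype=int)
    size[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        flat = np.argmin(dist)  # row-major => lexicographically smallest (i, j) tie-break
        i, j = divmod(int(flat), total)
        h = float(dist[i, j])
        new = n + step
        si, sj = size[i], size[j]
        ids = np.flatnonzero(active)
        ids = ids[(ids != i) & (ids != j)]
        for w in ids:
            dw_i = dist[min(i, w), max(i, w)]
            dw_j = dist[min(j, w), max(j, w)]
            if method == "average":
                d_new = (si * dw_i + sj * dw_j) / (si + sj)
            else:
                d_new = max(dw_i, dw_j)
            dist[w, new] = d_new  # w < new always
        dist[i, :] = dist[:, i] = np.inf
        dist[j, :] = dist[:, j] = np.inf
        active[i] = active[j] = False
        active[new] = True
        size[new] = si + sj
        merges.append((i, j, h, int(si + sj)))
    return Dendrogram(n_leaves=n, merges=merges, method=method)


def cut_groups(dendrogram: Dendrogram, n_groups: int) -> GroupPartition:
    """Partition into exactly ``n_groups`` by discarding the top merges.

    Groups are renumbered by descending size; ties broken by the smallest
    contained atom index.
    """
    n = dendrogram.n_leaves
    if not 1 <= n_groups <= n:
        raise UsageError(f"n_groups must lie in 1..{n}")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - n_groups):
        left, right, _, _ = dendrogram.merges[t]
        new = n + t
        parent[find(left)] = new
        parent[find(right)] = new
    roots = [find(i) for i in range(n)]
    groups: dict[int, list[int]] = {}
    for atom, r in enumerate(roots):
        groups.setdefault(r, []).append(atom)
    ordered = sorted(groups.values(), key=lambda mem: (-len(mem), min(mem)))
    group_of = np.zeros(n, dtype=int)
    for g, mem in enumerate(ordered, start=1):
        group_of[mem] = g
    cut = None
    if 1 < n_groups < n:
        cut = cut_point_value(dendrogram, n_groups)
    return GroupPartition(group_of, n_groups, dendrogram.method, cut)


def cut_point_value(dendrogram: Dendrogram, n_groups: int) -> float:
    """Median of the two merge heights straddling the cut into n_groups."""
    n = dendrogram.n_leaves
    if not 1 < n_groups < n:
        raise UsageError("cut point defined only for 1 < n_groups < n_leaves")
    h = dendrogram.heights
    below = h[n - 1 - n_groups]  # last merge still applied
    above = h[n - n_groups]  # first merge discarded
    return float(0.5 * (below + above))


def circular_edges(
    delta: np.ndarray,
    delta_th: float,
    residue_numbers: Sequence[int] | None = None,
) -> list[tuple[int, int]]:
    """Unordered pairs with delta_ij <= threshold (circular-plot connections)."""
    if not 0.0 <= delta_th <= 1.0:
        raise UsageError("delta_th must lie in [0, 1]")
    delta = _check_delta(delta)
    n = delta.shape[0]
    if residue_numbers is None:
        names = list(range(n))
    else:
        names = list(residue_numbers)
        if len(names) != n:
            raise UsageError("residue_numbers length must match delta")
    ii, jj = np.triu_indices(n, k=1)
    keep = delta[ii, jj] <= delta_th
    return [(names[i], names[j]) for i, j in zip(ii[keep], jj[keep])]
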