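"""Crisp decomposition of atoms into k clusters on a distance-variability matrix.

The target function is the within-cluster sum of pairwise distance
variabilities,

    q(c) = sum_m sum_{i,j in cluster m} D_ij = tr(c^T D c),

minimised over crisp (0/1) membership matrices c with exactly one cluster
per atom.  Optimal memberships for this target are crisp, so the search
space is label vectors and the optimiser uses single-atom moves: a fast
random descent followed by exhaustive single-move sweeps until a verified
local optimum, restarted ``n_trials`` times from random labelings.

A brute-force global optimiser over all set partitions into at most k
blocks is provided as an oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError

_EPS = 1e-12  # strict-improvement threshold guarding against fp cycling


@dataclass
class CrispLabeling:
    """Result of a crisp clustering run; labels are 1-based (1..k)."""

    labels: np.ndarray
    k: int
    q: float
    n_trials: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise UsageError("labels must be a 1-D array")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise UsageError("labels must lie in 1..k")

    @property
    def n_nonempty(self) -> int:
        return len(np.unique(self.labels))


def _check_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise UsageError("D must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-9):
        raise UsageError("D must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise UsageError("D must have a zero diagonal")
    return d


def target_q(d: np.ndarray, labels: np.ndarray) -> float:
    """q = tr(c^T D c): both (i, j) and (j, i) count, diagonal contributes 0."""
    d = _check_matrix(d)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (d.shape[0],):
        raise UsageError("labels length must match matrix size")
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        total += float(d[np.ix_(idx, idx)].sum())
    return total


def cluster_row_sums(d: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """A[i, m-1] = sum of D_ij over atoms j currently in cluster m."""
    n = d.shape[0]
    a = np.zeros((n, k))
    for m in range(1, k + 1):
        idx = np.flatnonzero(labels == m)
        if idx.size:
            a[:, m - 1] = d[:, idx].sum(axis=1)
    return a


def delta_q_move(
    d: np.ndarray,
    labels: np.ndarray,
    atom: int,
    new_cluster: int,
    cluster_sums: np.ndarray | None = None,
) -> float:
    """Exact change in q if ``atom`` moves to ``new_cluster``.

    Equals 2 * (sum_{j in new} D_ij - sum_{j in old, j != i} D_ij); the
    ``cluster_sums`` cache (see :func:`cluster_row_sums`) makes this O(1).
    """
    labels = np.asarray(labels, dtype=int)
    n = d.shape[0]
    if not 0 <= atom < n:
        raise UsageError(f"atom index {atom} out of range")
    k = cluster_sums.shape[1] if cluster_sums is not None else int(labels.max())
    if not 1 <= new_cluster <= k:
        raise UsageError(f"cluster {new_cluster} out of range 1..{k}")
    old = int(labels[atom])
    if new_cluster == old:
        raise UsageError("new_cluster must differ from the current label")
    if cluster_sums is None:
        cluster_sums = cluster_row_sums(d, labels, k)
    # D has a zero diagonal, so the old-cluster sum needs no j != i correction
    return 2.0 * (cluster_sums[atom, new_cluster - 1] - cluster_sums[atom, old - 1])


def _apply_move(d: np.ndarray, labels: np.ndarray, a: np.ndarray, atom: int, new: int) -> None:
    old = int(labels[atom])
    a[:, old - 1] -= d[:, atom]
    a[:, new - 1] += d[:, atom]
    labels[atom] = new


def _sweep_to_local_optimum(d: np.ndarray, labels: np.ndarray, a: np.ndarray, k: int) -> None:
    """Repeated exhaustive single-atom sweeps until no move improves q."""
    n = d.shape[0]
    improved = True
    while improved:
        improved = False
        for i in range(n):
            cur = int(labels[i])
            best = int(np.argmin(a[i])) + 1
            if best != cur and 2.0 * (a[i, best - 1] - a[i, cur - 1]) < -_EPS:
                _apply_move(d, labels, a, i, best)
                improved = True


def _one_trial(d: np.ndarray, k: int, rng: np.random.Generator, stall_limit: int) -> tuple[np.ndarray, float]:
    n = d.shape[0]
    labels = rng.integers(1, k + 1, size=n)
    a = cluster_row_sums(d, labels, k)
    rejected = 0
    while rejected < stall_limit:
        i = int(rng.integers(n))
        new = int(rng.integers(1, k + 1))
        if new == labels[i]:
            rejected += 1
            continue
        if 2.0 * (a[i, new - 1] - a[i, labels[i] - 1]) < -_EPS:
            _apply_move(d, labels, a, i, new)
            rejected = 0
        else:
            rejected += 1
    _sweep_to_local_optimum(d, labels, a, k)
    return labels, target_q(d, labels)


def optimize_labels(
    d: np.ndarray,
    k: int,
    n_trials: int = 100,
    seed: int | None = None,
    stall_factor: int = 50,
) -> CrispLabeling:
    """Best labeling over ``n_trials`` independent restarts (ties: first found).

    Each restart starts from uniform random labels, performs a greedy random
    single-atom-move descent until ``stall_factor * n`` consecutive
    rejections, then exhaustive sweeps to a verified single-move local
    optimum.  Clusters may end up empty; labels stay in 1..k.
    """
    d = _check_matrix(d)
    n = d.shape[0]
    if k < 1:
        raise UsageError("k must be >= 1")
    if k > n:
        raise UsageError(f"k = {k} exceeds the number of atoms ({n})")
    if n_trials < 1:
        raise UsageError("n_trials must be >= 1")
    if k == 1:
        labels = np.ones(n, dtype=int)
        return CrispLabeling(labels, 1, target_q(d, labels), n_trials, seed)
    ss = np.random.SeedSequence(seed)
    best_labels, best_q = None, np.inf
    for child in ss.spawn(n_trials):
        rng = np.random.default_rng(child)
        labels, q = _one_trial(d, k, rng, stall_factor * n)
        if q < best_q - _EPS:
            best_labels, best_q = labels, q
    return CrispLabeling(best_labels, k, best_q, n_trials, seed)


def _restricted_growth_strings(n: int, max_blocks: int):
    """All canonical label vectors for set partitions into <= max_blocks blocks."""
    a = np.zeros(n, dtype=int)

    def rec(i: int, mx: int):
        if i == n:
            yield a.copy()
            return
        for v in range(min(mx + 1, max_blocks - 1) + 1):
            a[i] = v
            yield from rec(i + 1, max(mx, v))

    yield from rec(1, 0) if n > 1 else rec(n, 0)


def brute_force_labels(d: np.ndarray, k: int, max_atoms: int = 12) -> CrispLabeling:
    """Global optimum of the target by enumerating set partitions (oracle).

    Clusters are unlabeled, so only canonical partitions into at most k
    non-empty blocks are enumerated.  Guarded to small instances.
    """
    d = _check_matrix(d)
    n = d.shape[0]
    if n > max_atoms:
        raise UsageError(f"brute force limited to {max_atoms} atoms (got {n})")
    if k < 1:
        raise UsageError("k must be >= 1")
    if k > n:
        raise UsageError(f"k = {k} exceeds the number of atoms ({n})")
    best_labels, best_q = None, np.inf
    for rgs in _restricted_growth_strings(n, k):
        labels = rgs + 1
        q = target_q(d, labels)
        if q < best_q - _EPS:
            best_labels, best_q = labels.copy(), q
    return CrispLabeling(best_labels, k, best_q, n_trials=0, seed=None)


def fuzzy_target_q(d: np.ndarray, memberships: np.ndarray) -> float:
    """tr(c^T D c) for an arbitrary row-stochastic membership matrix.

    Used to check that fractional memberships never beat the crisp optimum.
    """
    d = _check_matrix(d)
    c = np.asarray(memberships, dtype=float)
    if c.ndim != 2 or c.shape[0] != d.shape[0]:
        raise UsageError("membership matrix must be (n, k)")
    if np.any(c < -1e-12) or not np.allclose(c.sum(axis=1), 1.0, atol=1e-9):
        raise UsageError("membership rows must lie on the probability simplex")
    return float(np.trace(c.T @ d @ c))
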