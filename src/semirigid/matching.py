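"""Cross-trajectory group matching, disparity scores and stable kernels.

Group labels produced by agglomerative clustering are arbitrary per
trajectory, so groups of trajectory B are matched onto a reference A by
solving the assignment problem on the pairwise symmetric-difference loss
(Hungarian algorithm).  The total loss of the optimal full assignment is
the clustering disparity between the two trajectories.  Matching several
trajectories to a common reference allows intersecting same-index groups
into stable kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .consensus import GroupPartition
from .errors import UsageError


@dataclass
class MatchResult:
    """Optimal assignment of groups of B onto reference A.

    ``permutation[j] = i`` means group j+1 of B is matched to group i+1 of A
    (both 0-based internally).
    """

    permutation: np.ndarray
    loss_matrix: np.ndarray
    pair_losses: np.ndarray  # per matched pair, indexed by reference group
    total_disparity: int

    @property
    def n_groups(self) -> int:
        return self.permutation.size


@dataclass
class KernelSet:
    """Per-group intersections of matched partitions (pairwise disjoint)."""

    kernels: list[set[int]]
    n_atoms: int

    @property
    def coverage(self) -> float:
        return sum(len(k) for k in self.kernels) / self.n_atoms

    def kernel_labels(self) -> np.ndarray:
        """Per-atom kernel index (1..N_G), 0 for atoms outside every kernel."""
        lab = np.zeros(self.n_atoms, dtype=int)
        for m, kern in enumerate(self.kernels, start=1):
            for a in kern:
                lab[a] = m
        return lab


def symmetric_difference_loss(set_a: Iterable[int], set_b: Iterable[int]) -> int:
    """|(A u B) \\ (A n B)| — atoms contained in exactly one of the groups."""
    return len(set(set_a) ^ set(set_b))


def loss_matrix(partition_a: GroupPartition, partition_b: GroupPartition) -> np.ndarray:
    """Entry (i, j): symmetric-difference loss between group i+1 of A and j+1 of B."""
    if partition_a.n_groups != partition_b.n_groups:
        raise UsageError(
            "partitions must have the same group count "
            f"({partition_a.n_groups} vs {partition_b.n_groups})"
        )
    sets_a = partition_a.as_sets()
    sets_b = partition_b.as_sets()
    ng = partition_a.n_groups
    loss = np.zeros((ng, ng), dtype=int)
    for i in range(ng):
        for j in range(ng):
            loss[i, j] = symmetric_difference_loss(sets_a[i], sets_b[j])
    return loss


def _lexicographically_smallest_optimum(loss: np.ndarray, optimal_cost: int) -> np.ndarray:
    """Among all minimum-cost full assignments pick the lexicographically
    smallest permutation (reference group i -> column perm[i])."""
    ng = loss.shape[0]
    perm = np.full(ng, -1)
    rows = list(range(ng))
    cols = list(range(ng))
    remaining_cost = optimal_cost
    for i in rows:
        for j in sorted(cols):
            sub_rows = [r for r in rows if r > i]
            sub_cols = [c for c in cols if c != j]
            sub = loss[np.ix_(sub_rows, sub_cols)] if sub_rows else np.zeros((0, 0))
            tail = float(sub[linear_sum_assignment(sub)].sum()) if sub_rows else 0.0
            if abs(float(loss[i, j]) + tail - remaining_cost) < 1e-9:
                perm[i] = j
                remaining_cost -= float(loss[i, j])
                cols.remove(j)
                break
    return perm


def match_pairs(loss: np.ndarray) -> MatchResult:
    """Minimum-total-loss bijection between reference groups and other groups.

    Ties between optimal assignments are broken deterministically by taking
    the lexicographically smallest row->column permutation.
    """
    loss = np.asarray(loss)
    if loss.ndim != 2 or loss.shape[0] != loss.shape[1]:
        raise UsageError("loss matrix must be square")
    row, col = linear_sum_assignment(loss)
    optimal_cost = float(loss[row, col].sum())
    row_to_col = _lexicographically_smallest_optimum(loss, optimal_cost)
    # permutation maps group j of B -> group of A, i.e. invert row->col
    perm = np.empty_like(row_to_col)
    perm[row_to_col] = np.arange(loss.shape[0])
    pair_losses = loss[np.arange(loss.shape[0]), row_to_col]
    if abs(optimal_cost - round(optimal_cost)) < 1e-9:
        optimal_cost = int(round(optimal_cost))
    return MatchResult(
        permutation=perm,
        loss_matrix=loss,
        pair_losses=np.asarray(pair_losses),
        total_disparity=optimal_cost,
    )


def relabel_to_reference(partition_b: GroupPartition, match: MatchResult) -> GroupPartition:
    """Renumber B's groups so same-index groups correspond to the reference."""
    new_of = np.array([match.permutation[g - 1] + 1 for g in partition_b.group_of])
    return GroupPartition(new_of, partition_b.n_groups, partition_b.linkage_method,
                          partition_b.cut_point)


def match_to_reference(
    reference: GroupPartition, others: Sequence[GroupPartition]
) -> tuple[list[MatchResult], list[GroupPartition]]:
    """Match each partition pairwise onto the reference and relabel it."""
    matches, relabeled = [], []
    for other in others:
        m = match_pairs(loss_matrix(reference, other))
        matches.append(m)
        relabeled.append(relabel_to_reference(other, m))
    return matches, relabeled


def stable_kernels(matched_partitions: Sequence[GroupPartition]) -> KernelSet:
    """Per-group intersection across all (already relabeled) partitions."""
    if not matched_partitions:
        raise UsageError("need at least one partition")
    ng = matched_partitions[0].n_groups
    if any(p.n_groups != ng for p in matched_partitions):
        raise UsageError("all partitions must share the same group count")
    n_atoms = matched_partitions[0].group_of.size
    if any(p.group_of.size != n_atoms for p in matched_partitions):
        raise UsageError("all partitions must cover the same atom list")
    kernels = []
    for m in range(1, ng + 1):
        kern = matched_partitions[0].members(m)
        for p in matched_partitions[1:]:
            kern &= p.members(m)
        kernels.append(kern)
    return KernelSet(kernels, n_atoms)


def disparity_multi(
    reference: GroupPartition, others: Sequence[GroupPartition]
) -> int:
    """Atoms not assigned to the same group index in every trajectory.

    Others are first matched pairwise to the reference; equals
    N_alpha - sum of kernel sizes.
    """
    _, relabeled = match_to_reference(reference, others)
    kernels = stable_kernels([reference, *relabeled])
    return reference.group_of.size - sum(len(k) for k in kernels.kernels)
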