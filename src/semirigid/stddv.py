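"""Distance-variability (STDDV) matrices and trajectory segmentation.

The STDDV entry for an atom pair is the Bessel-corrected sample standard
deviation of their Euclidean distance time series over a frame window:

    D_ij = sqrt( N_f/(N_f - 1) * mean( (d_ij - mean d_ij)^2 ) )

i.e. ``np.std(..., ddof=1)``.  Distances are invariant under rigid-body
fitting, so STDDV matrices do not depend on whether the trajectory was
superposed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UsageError
from .traj_io import Trajectory


@dataclass(frozen=True)
class SegmentationScheme:
    """Exact partition of N_t frames into N_s segments of N_f frames."""

    n_total: int
    n_segments: int

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise UsageError("segment count must be >= 1")
        if self.n_total % self.n_segments != 0:
            raise UsageError(
                f"{self.n_total} frames are not divisible into {self.n_segments} "
                "equal segments; trim the trajectory first"
            )
        if self.frames_per_segment < 2:
            raise UsageError("each segment needs at least 2 frames")

    @property
    def frames_per_segment(self) -> int:
        return self.n_total // self.n_segments


@dataclass
class DistanceVariabilityMatrix:
    """Symmetric non-negative matrix of pairwise distance standard deviations."""

    matrix: np.ndarray  # (n_sel, n_sel), nm
    frame_range: tuple[int, int]  # half-open
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise UsageError("STDDV matrix must be square")
        if m.shape[0] != len(self.atom_indices):
            raise UsageError("matrix size does not match atom selection")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def stddv_matrix(
    traj: Trajectory,
    calpha_sel: Sequence[int],
    frame_range: tuple[int, int] | None = None,
) -> DistanceVariabilityMatrix:
    """STDDV over ``frame_range`` (half-open; default: the whole trajectory).

    Whole-trajectory mode corresponds to setting the window length equal to
    the total frame count.
    """
    sel = np.asarray(calpha_sel, dtype=int)
    if sel.size == 0:
        raise UsageError("empty atom selection")
    if frame_range is None:
        frame_range = (0, traj.n_frames)
    start, end = frame_range
    if not (0 <= start < end <= traj.n_frames):
        raise UsageError(f"invalid frame range {frame_range}")
    if end - start < 2:
        raise UsageError("STDDV needs at least 2 frames")
    x = traj.coords[start:end, sel, :]  # (F, n, 3)
    diff = x[:, :, None, :] - x[:, None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))  # (F, n, n)
    d = np.std(dist, axis=0, ddof=1)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceVariabilityMatrix(d, (start, end), tuple(int(i) for i in sel))


def segment_ranges(scheme: SegmentationScheme) -> list[tuple[int, int]]:
    """Contiguous, disjoint, exhaustive half-open frame ranges."""
    nf = scheme.frames_per_segment
    return [(s * nf, (s + 1) * nf) for s in range(scheme.n_segments)]


def segment_stddv_matrices(
    traj: Trajectory, calpha_sel: Sequence[int], scheme: SegmentationScheme
) -> list[DistanceVariabilityMatrix]:
    if scheme.n_total != traj.n_frames:
        raise UsageError("segmentation scheme does not match trajectory length")
    return [stddv_matrix(traj, calpha_sel, rng) for rng in segment_ranges(scheme)]
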