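"""Least-squares rigid-body superposition (Kabsch) of trajectory frames.

Every frame is fitted onto a reference frame using only a fit selection
(typically the backbone atoms within beta-strands and alpha-helices); the
resulting rotation/translation is then applied to all atoms.  The fit is
unweighted and the rotation is constrained to be proper (det = +1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UsageError
from .traj_io import Trajectory


@dataclass(frozen=True)
class FitSelection:
    """Atom indices used for superposition."""

    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.atom_indices) == 0:
            raise UsageError("fit selection must not be empty")

    @property
    def n_bb(self) -> int:
        return len(self.atom_indices)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t mapping mobile onto reference.

    Applying ``x @ R.T + t`` to the mobile coordinates minimises the RMSD to
    the reference.  Raises for fewer than 3 atoms or (near-)collinear input,
    where the rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise UsageError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise UsageError("superposition needs at least 3 atoms")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise UsageError("degenerate (collinear) fit selection")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    return rot, trans


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (uniform-weight) root-mean-square deviation in nm."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise UsageError("coordinate arrays must have equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fit_trajectory(traj: Trajectory, fit_sel: FitSelection | Sequence[int], ref_frame: int = 0) -> Trajectory:
    """Superpose every frame onto ``ref_frame`` over the fit selection.

    The transform is computed on the fit-selection atoms only and applied to
    all atoms of the frame.
    """
    if not isinstance(fit_sel, FitSelection):
        fit_sel = FitSelection(tuple(fit_sel))
    if not 0 <= ref_frame < traj.n_frames:
        raise UsageError(f"ref_frame {ref_frame} out of range")
    sel = np.asarray(fit_sel.atom_indices, dtype=int)
    if sel.max() >= traj.n_atoms:
        raise UsageError("fit selection index out of range")
    ref = traj.coords[ref_frame, sel]
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        rot, trans = kabsch_superpose(traj.coords[f, sel], ref)
        out[f] = apply_transform(traj.coords[f], rot, trans)
    return Trajectory(coords=out, dt_frame=traj.dt_frame, atoms=traj.atoms)


def fit_rmsd_profile(traj: Trajectory, fit_sel: FitSelection | Sequence[int], ref_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (nm) over the fit selection after superposition."""
    if not isinstance(fit_sel, FitSelection):
        fit_sel = FitSelection(tuple(fit_sel))
    fitted = fit_trajectory(traj, fit_sel, ref_frame)
    sel = np.asarray(fit_sel.atom_indices, dtype=int)
    ref = fitted.coords[ref_frame, sel]
    return np.array([rmsd(fitted.coords[f, sel], ref) for f in range(traj.n_frames)])
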