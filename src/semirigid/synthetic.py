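"""Synthetic trajectories with planted semi-rigid domains.

Each domain is a compact set of atoms (uniform in a 1 nm sphere) around
well-separated centers.  Per frame, every domain performs an independent
small-step rigid-body random walk (axis-angle rotation about its centroid
plus a Gaussian translation step, both scaled by the motion amplitude),
while each atom is additionally jittered by i.i.d. Gaussian noise.  Atoms
listed in a switch event change their governing domain mid-trajectory,
continuously re-anchored at the switch frame so there is no teleport.

With zero jitter, within-domain distances are exactly preserved and
between-domain distances fluctuate — the separation the clustering method
exploits.  All randomness flows from a single integer seed through
numpy SeedSequence spawning (template / motion / jitter streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .traj_io import AtomRecord, Trajectory

DOMAIN_SPACING_NM = 5.0  # centers on a line, >= 4 nm apart
TEMPLATE_RADIUS_NM = 1.0


@dataclass(frozen=True)
class SwitchEvent:
    """Atoms that defect from one domain's motion to another at a frame."""

    atoms: tuple[int, ...]
    switch_frame: int
    source_domain: int
    target_domain: int


@dataclass
class PlantedSpec:
    n_domains: int = 3
    atoms_per_domain: int = 30
    domain_motion_amplitude: float = 0.3  # nm translation step / rad rotation step
    atom_jitter_sigma: float = 0.02  # nm
    n_frames: int = 2500
    dt_frame: float = 20.0  # ps
    switch_spec: tuple[SwitchEvent, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1 or self.atoms_per_domain < 1:
            raise UsageError("need at least one domain with at least one atom")
        if self.domain_motion_amplitude < 0 or self.atom_jitter_sigma < 0:
            raise UsageError("amplitudes must be non-negative")
        if self.n_frames < 2:
            raise UsageError("need at least 2 frames")
        seen: set[int] = set()
        for ev in self.switch_spec:
            if not 0 < ev.switch_frame < self.n_frames:
                raise UsageError(f"switch frame {ev.switch_frame} out of range")
            if not (0 <= ev.source_domain < self.n_domains and 0 <= ev.target_domain < self.n_domains):
                raise UsageError("switch domains out of range")
            overlap = seen.intersection(ev.atoms)
            if overlap:
                raise UsageError(f"atoms {sorted(overlap)} appear in multiple switch events")
            seen.update(ev.atoms)

    @property
    def n_atoms(self) -> int:
        return self.n_domains * self.atoms_per_domain


@dataclass
class PlantedTruth:
    """Ground-truth domain index per atom (initial assignment) and switches."""

    true_label: np.ndarray  # 1-based domain index per atom
    switches: tuple[SwitchEvent, ...] = field(default_factory=tuple)


def _random_rotation_step(rng: np.random.Generator, angle_sigma: float) -> np.ndarray:
    """Proper rotation by an angle ~ N(0, sigma) about a uniform random axis."""
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return np.eye(3)
    axis = axis / norm
    angle = rng.normal(0.0, angle_sigma) if angle_sigma > 0 else 0.0
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return pts * r[:, None]


def generate_planted_trajectory(spec: PlantedSpec) -> tuple[Trajectory, PlantedTruth]:
    """Simulate the planted-domain motion model; reproducible from spec.seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_template, rng_motion, rng_jitter = (np.random.default_rng(c) for c in ss.spawn(3))

    n_at = spec.n_atoms
    domain_of = np.repeat(np.arange(spec.n_domains), spec.atoms_per_domain)
    centers = np.zeros((spec.n_domains, 3))
    centers[:, 0] = DOMAIN_SPACING_NM * np.arange(spec.n_domains)
    local = _uniform_in_sphere(rng_template, n_at, TEMPLATE_RADIUS_NM)

    # per-domain rigid state
    rot = [np.eye(3) for _ in range(spec.n_domains)]
    cen = centers.copy()
    governing = domain_of.copy()
    switch_at: dict[int, list[SwitchEvent]] = {}
    for ev in spec.switch_spec:
        switch_at.setdefault(ev.switch_frame, []).append(ev)

    coords = np.empty((spec.n_frames, n_at, 3))
    amp = spec.domain_motion_amplitude
    for f in range(spec.n_frames):
        if f > 0:
            for d in range(spec.n_domains):
                step_rot = _random_rotation_step(rng_motion, amp)
                rot[d] = step_rot @ rot[d]
                cen[d] = cen[d] + rng_motion.normal(0.0, amp if amp > 0 else 0.0, size=3)
        for ev in switch_at.get(f, ()):
            for atom in ev.atoms:
                if governing[atom] != ev.source_domain:
                    raise UsageError(
                        f"atom {atom} is governed by domain {governing[atom]}, "
                        f"not {ev.source_domain}, at frame {f}"
                    )
                # re-anchor local coordinate in the target domain's frame
                pos = rot[ev.source_domain] @ local[atom] + cen[ev.source_domain]
                local[atom] = rot[ev.target_domain].T @ (pos - cen[ev.target_domain])
                governing[atom] = ev.target_domain
        for d in range(spec.n_domains):
            idx = np.flatnonzero(governing == d)
            if idx.size:
                coords[f, idx] = local[idx] @ rot[d].T + cen[d]
        if spec.atom_jitter_sigma > 0:
            coords[f] += rng_jitter.normal(0.0, spec.atom_jitter_sigma, size=(n_at, 3))

    atoms = tuple(
        AtomRecord(i, "CA", i + 1, i + 1, "A") for i in range(n_at)
    )
    traj = Trajectory(coords=coords, dt_frame=spec.dt_frame, atoms=atoms)
    truth = PlantedTruth(true_label=domain_of + 1, switches=spec.switch_spec)
    return traj, truth


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Standard pair-counting adjusted Rand index between two labelings."""
    from sklearn.metrics import adjusted_rand_score

    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or labels_a.ndim != 1:
        raise UsageError("labelings must be 1-D and of equal length")
    return float(adjusted_rand_score(labels_a, labels_b))
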