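"""End-to-end orchestration: segments -> spatial clusters -> consensus ->
groups -> cross-trajectory kernels, plus the VMD Tcl export.

Default parameters follow the reference protocol: discard the first 100 ns,
N_s = 500 segments, k = 7 spatial clusters, 100000 optimisation trials per
segment, "average" linkage and N_G = 24 groups.  Each segment's search is
seeded independently from the master seed, so results do not depend on
execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .consensus import (
    ConsensusMatrix,
    Dendrogram,
    GroupPartition,
    SegmentLabeling,
    agglomerate,
    cut_groups,
    dissimilarity_matrix,
)
from .errors import UsageError
from .matching import KernelSet, MatchResult, match_to_reference, stable_kernels
from .spatial import CrispLabeling, optimize_labels
from .stddv import SegmentationScheme, segment_ranges, stddv_matrix
from .traj_io import AtomRecord, Trajectory, calpha_predicate, select_atoms, trim_frames

logger = logging.getLogger("semirigid")

#: reference MD protocol constants recorded in every manifest
PRODUCTION_NS = 600.0
REPLICATE_COUNT = 3
SAVE_INTERVAL_PS = 20.0


@dataclass
class PipelineConfig:
    discard_time_ps: float = 100_000.0  # first 100 ns
    n_segments: int = 500
    k: int = 7
    n_trials: int = 100_000
    linkage: str = "average"
    n_groups: int = 24
    delta_thresholds: tuple[float, ...] = (0.04, 0.1)
    seed: int = 0
    # reference protocol bookkeeping (recorded in the manifest)
    production_ns: float = PRODUCTION_NS
    n_replicates: int = REPLICATE_COUNT
    save_interval_ps: float = SAVE_INTERVAL_PS

    def manifest(self) -> dict:
        m = asdict(self)
        m["total_simulated_us"] = self.production_ns * self.n_replicates / 1000.0
        return m


@dataclass
class TrajectoryResult:
    segment_labeling: SegmentLabeling
    consensus: ConsensusMatrix
    dendrogram: Dendrogram
    partition: GroupPartition
    edges: dict[float, list[tuple[int, int]]]
    whole_labeling: CrispLabeling | None = None


@dataclass
class PipelineResult:
    per_trajectory: list[TrajectoryResult]
    residue_numbers: list[int]
    matches: list[MatchResult] = field(default_factory=list)
    relabeled: list[GroupPartition] = field(default_factory=list)
    kernels: KernelSet | None = None
    manifest: dict = field(default_factory=dict)


def _segment_seed(master: int, traj_idx: int, segment_idx: int) -> int:
    """Stable per-segment seed, independent of execution order."""
    child = np.random.SeedSequence(entropy=master, spawn_key=(traj_idx, segment_idx))
    return int(child.generate_state(1, dtype=np.uint64)[0])


def cluster_segments(
    traj: Trajectory,
    calpha_sel: Sequence[int],
    n_segments: int,
    k: int,
    n_trials: int,
    seed: int,
    traj_idx: int = 0,
) -> SegmentLabeling:
    """Per-segment STDDV + crisp clustering over an exact frame partition."""
    scheme = SegmentationScheme(traj.n_frames, n_segments)
    labels = np.empty((n_segments, len(calpha_sel)), dtype=int)
    qs = np.empty(n_segments)
    for s, rng in enumerate(segment_ranges(scheme)):
        dvm = stddv_matrix(traj, calpha_sel, rng)
        res = optimize_labels(dvm.matrix, k, n_trials, _segment_seed(seed, traj_idx, s))
        labels[s] = res.labels
        qs[s] = res.q
    return SegmentLabeling(labels, k, qs)


def analyze_trajectory(
    traj: Trajectory, config: PipelineConfig, traj_idx: int = 0, whole: bool = False
) -> TrajectoryResult:
    """Run the single-trajectory part of the pipeline."""
    if config.discard_time_ps > 0:
        traj = trim_frames(traj, config.discard_time_ps)
    calpha_sel = select_atoms(traj, calpha_predicate)
    seg = cluster_segments(
        traj, calpha_sel, config.n_segments, config.k, config.n_trials, config.seed, traj_idx
    )
    cons = dissimilarity_matrix(seg)
    dendro = agglomerate(cons.delta, config.linkage)
    part = cut_groups(dendro, config.n_groups)
    resnums = traj.residue_numbers()[calpha_sel]
    from .consensus import circular_edges

    edges = {
        th: circular_edges(cons.delta, th, resnums) for th in config.delta_thresholds
    }
    whole_lab = None
    if whole:
        dvm = stddv_matrix(traj, calpha_sel)
        whole_lab = optimize_labels(
            dvm.matrix, config.k, config.n_trials, _segment_seed(config.seed, traj_idx, 2**32 - 1)
        )
    return TrajectoryResult(seg, cons, dendro, part, edges, whole_lab)


def run_pipeline(
    trajectories: Sequence[Trajectory], config: PipelineConfig | None = None, whole: bool = False
) -> PipelineResult:
    """Full pipeline over one or more replicate trajectories.

    The first trajectory serves as the matching reference.  With a single
    input, matching and kernel extraction are skipped (with a warning).
    """
    if not trajectories:
        raise UsageError("need at least one trajectory")
    config = config or PipelineConfig()
    ref_atoms = _calpha_signature(trajectories[0])
    for t in trajectories[1:]:
        if _calpha_signature(t) != ref_atoms:
            raise UsageError("all trajectories must share an identical C-alpha atom list")
    per_traj = [
        analyze_trajectory(t, config, traj_idx=i, whole=whole)
        for i, t in enumerate(trajectories)
    ]
    residue_numbers = [r for r, _ in ref_atoms]
    result = PipelineResult(per_traj, residue_numbers, manifest=config.manifest())
    if len(per_traj) == 1:
        logger.warning("single trajectory input: skipping cross-trajectory matching/kernels")
        return result
    reference = per_traj[0].partition
    others = [r.partition for r in per_traj[1:]]
    matches, relabeled = match_to_reference(reference, others)
    result.matches = matches
    result.relabeled = [reference, *relabeled]
    result.kernels = stable_kernels(result.relabeled)
    return result


def _calpha_signature(traj: Trajectory) -> list[tuple[int, str]]:
    sel = select_atoms(traj, calpha_predicate)
    return [(int(traj.atoms[i].residue_number), traj.atoms[i].atom_name) for i in sel]


# ---------------------------------------------------------------------------
# VMD export

# VMD ColorID palette cycled over groups; 8 (white) is reserved as neutral
_VMD_COLOR_IDS = [0, 1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15, 16,
                  17, 18, 19, 20, 21, 22, 23, 24]
_NEUTRAL_COLOR_ID = 8


def export_tcl(labels: Sequence[int], atom_records: Sequence[AtomRecord]) -> str:
    """Tcl script coloring residues by group/kernel membership in VMD.

    ``labels`` holds one group index per atom record (0 = in no kernel,
    colored neutrally).  Selections address residues via their PDB ResID.
    """
    labels = list(labels)
    if len(labels) != len(atom_records):
        raise UsageError("labels must cover all atom records")
    by_group: dict[int, list[int]] = {}
    for lab, rec in zip(labels, atom_records):
        by_group.setdefault(int(lab), []).append(rec.residue_id)
    lines = [
        "# semirigid domain coloring",
        "mol delrep 0 top",
        "mol representation NewCartoon",
        f"mol color ColorID {_NEUTRAL_COLOR_ID}",
        "mol selection {all}",
        "mol addrep top",
    ]
    for group in sorted(g for g in by_group if g > 0):
        resids = sorted(set(by_group[group]))
        if not resids:
            continue
        color = _VMD_COLOR_IDS[(group - 1) % len(_VMD_COLOR_IDS)]
        sel = " ".join(str(r) for r in resids)
        lines += [
            f"# group {group}",
            "mol representation NewCartoon",
            f"mol color ColorID {color}",
            f"mol selection {{resid {sel}}}",
            "mol addrep top",
        ]
    return "\n".join(lines) + "\n"
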