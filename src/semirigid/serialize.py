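"""Plain-text persistence for matrices, dendrograms, groups and matches.

Matrices go to TSV with a residue-number header row/column (and optionally
to an .npz container for fast reload); labelings and partitions go to JSON
keyed by 1-based continuous residue number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .consensus import Dendrogram, GroupPartition
from .errors import FormatError


def write_matrix_tsv(matrix: np.ndarray, residue_numbers: Sequence[int], path: str | Path) -> None:
    matrix = np.asarray(matrix)
    names = [str(r) for r in residue_numbers]
    with open(path, "w") as fh:
        fh.write("res\t" + "\t".join(names) + "\n")
        for name, row in zip(names, matrix):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[int]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "res":
            raise FormatError(f"{path} is not a matrix TSV (missing 'res' header)")
        names = [int(x) for x in header[1:]]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(x) for x in parts[1:]])
    m = np.array(rows)
    if m.shape != (len(names), len(names)):
        raise FormatError(f"matrix in {path} is not square against its header")
    return m, names


def write_matrix_npz(matrix: np.ndarray, residue_numbers: Sequence[int], path: str | Path) -> None:
    """Binary container: arrays 'matrix' and 'residue_numbers'."""
    np.savez_compressed(path, matrix=np.asarray(matrix),
                        residue_numbers=np.asarray(list(residue_numbers)))


def read_matrix_npz(path: str | Path) -> tuple[np.ndarray, list[int]]:
    with np.load(path) as data:
        return data["matrix"], data["residue_numbers"].tolist()


def write_labels_json(labels: Sequence[int], residue_numbers: Sequence[int], path: str | Path,
                      meta: dict | None = None) -> None:
    payload = {
        "labels": {str(r): int(l) for r, l in zip(residue_numbers, labels)},
        **(meta or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_labels_json(path: str | Path) -> tuple[np.ndarray, list[int], dict]:
    payload = json.loads(Path(path).read_text())
    items = sorted(((int(r), int(l)) for r, l in payload["labels"].items()))
    residues = [r for r, _ in items]
    labels = np.array([l for _, l in items], dtype=int)
    meta = {k: v for k, v in payload.items() if k != "labels"}
    return labels, residues, meta


def write_dendrogram_tsv(dendrogram: Dendrogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("left\tright\theight\tsize\n")
        for left, right, height, size in dendrogram.merges:
            fh.write(f"{left}\t{right}\t{height:.17g}\t{size}\n")


def read_dendrogram_tsv(path: str | Path, method: str = "average") -> Dendrogram:
    merges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("left\t"):
            raise FormatError(f"{path} is not a dendrogram TSV")
        for line in fh:
            left, right, height, size = line.split("\t")
            merges.append((int(left), int(right), float(height), int(size)))
    return Dendrogram(n_leaves=len(merges) + 1, merges=merges, method=method)


def write_groups_json(partition: GroupPartition, residue_numbers: Sequence[int],
                      path: str | Path) -> None:
    payload = {
        "n_groups": partition.n_groups,
        "linkage_method": partition.linkage_method,
        "cut_point": partition.cut_point,
        "group_of": {str(r): int(g) for r, g in zip(residue_numbers, partition.group_of)},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_groups_json(path: str | Path) -> tuple[GroupPartition, list[int]]:
    payload = json.loads(Path(path).read_text())
    items = sorted(((int(r), int(g)) for r, g in payload["group_of"].items()))
    residues = [r for r, _ in items]
    group_of = np.array([g for _, g in items], dtype=int)
    part = GroupPartition(group_of, int(payload["n_groups"]),
                          payload.get("linkage_method", "average"),
                          payload.get("cut_point"))
    return part, residues


def write_edges_tsv(edges: Sequence[tuple[int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue_i\tresidue_j\n")
        for i, j in edges:
            fh.write(f"{i}\t{j}\n")
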