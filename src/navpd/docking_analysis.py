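"""Docking-pose clustering and representative selection.

Poses from (possibly several) independent docking runs share the receptor
frame, so pose–pose RMSD is computed without superposition.  Clustering is
energy-ordered greedy leader clustering with a 2 Å cutoff, the scheme used by
classic docking packages: walking the poses from best to worst energy, a pose
joins the first cluster whose founding seed lies within the cutoff, otherwise
it founds a new cluster.  Clusters are reported largest-first (C1, C2, …).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_model import coordinate_rmsd

__all__ = ["Pose", "PoseCluster", "BestSelection", "pose_rmsd", "cluster_poses", "select_best"]

DEFAULT_CLUSTER_CUTOFF = 2.0


@dataclass
class Pose:
    """One docked ligand conformation with its docking/binding score."""

    pose_id: str
    run_id: str
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates, Å
    energy: float  # kcal/mol

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError(f"pose {self.pose_id!r}: coords must be (n>=1, 3)")
        if not math.isfinite(self.energy):
            raise ValueError(f"pose {self.pose_id!r}: non-finite energy")


def pose_rmsd(a: Pose, b: Pose) -> float:
    """No-fit RMSD between two poses (same atom count and ordering required)."""
    if a.coords.shape != b.coords.shape:
        raise ValueError(f"pose atom mismatch: {a.coords.shape} vs {b.coords.shape}")
    return coordinate_rmsd(a.coords, b.coords)


@dataclass
class PoseCluster:
    """A cluster of poses with its founding seed and summary statistics."""

    members: list[Pose]
    seed: Pose
    label: str = ""

    @property
    def nc(self) -> int:
        return len(self.members)

    @property
    def avg_energy(self) -> float:
        return float(np.mean([p.energy for p in self.members]))

    @property
    def min_energy(self) -> float:
        return float(min(p.energy for p in self.members))

    @property
    def representative(self) -> Pose:
        return min(self.members, key=lambda p: (p.energy, p.pose_id))


def cluster_poses(poses: Sequence[Pose], cutoff: float = DEFAULT_CLUSTER_CUTOFF
                  ) -> list[PoseCluster]:
    """Energy-ordered leader clustering of a pose set (deterministic)."""
    if not poses:
        raise ValueError("no poses to cluster")
    ordered = sorted(poses, key=lambda p: (p.energy, p.pose_id))
    clusters: list[PoseCluster] = []
    for p in ordered:
        for cl in clusters:
            if pose_rmsd(p, cl.seed) <= cutoff:
                cl.members.append(p)
                break
        else:
            clusters.append(PoseCluster([p], p))
    clusters.sort(key=lambda c: (-c.nc, c.min_energy, c.seed.pose_id))
    for i, cl in enumerate(clusters, start=1):
        cl.label = f"C{i}"
    return clusters


@dataclass
class BestSelection:
    best_cluster: PoseCluster
    best_pose: Pose
    best_pose_in_best_cluster: bool


def select_best(clusters: Sequence[PoseCluster]) -> BestSelection:
    """Lowest-average-energy cluster and the globally lowest-energy pose."""
    if not clusters:
        raise ValueError("no clusters")
    best_cluster = min(clusters, key=lambda c: (c.avg_energy, c.min_energy, c.label))
    best_pose = min((p for c in clusters for p in c.members),
                    key=lambda p: (p.energy, p.pose_id))
    in_best = any(p is best_pose for p in best_cluster.members)
    return BestSelection(best_cluster, best_pose, in_best)
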