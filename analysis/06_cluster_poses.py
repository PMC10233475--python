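"""Cluster synthetic docking poses (2 Å no-fit RMSD, energy-ordered leader
clustering) and select the best cluster and pose, as in the docking
validation step."""

from pathlib import Path

import numpy as np
import pandas as pd

from navpd.docking_analysis import cluster_poses, select_best
from navpd.synthetic import SyntheticSpec, gen_poses

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = SyntheticSpec(seed=seed)
    poses = gen_poses(np.zeros(3), spec)
    clusters = cluster_poses(poses, cutoff=2.0)
    best = select_best(clusters)

    rows = [{"cluster": c.label, "Nc": c.nc,
             "avg_kcal_mol": round(c.avg_energy, 2),
             "min_kcal_mol": round(c.min_energy, 2),
             "representative": c.representative.pose_id}
            for c in clusters]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "pose_clusters.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\n{len(poses)} poses ({spec.n_pose_clusters} planted clusters + "
          f"{spec.n_pose_outliers} outliers) → {len(clusters)} clusters; "
          f"best cluster {best.best_cluster.label}, best pose "
          f"{best.best_pose.pose_id} ({best.best_pose.energy:.2f} kcal/mol), "
          f"best pose in best cluster: {best.best_pose_in_best_cluster}")


if __name__ == "__main__":
    main()
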