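"""Trajectory stability metrics on the synthetic equilibration: Cα RMSD with
and without the flexible hairpin turns ("P-loop" proxies), fit vs no-fit,
per-residue RMSF, and the per-frame gate-diameter series."""

from pathlib import Path

import pandas as pd

from navpd.ensemble_analysis import Selection, gate_series, rmsd_series, rmsf
from navpd.pore_geometry import classify_state
from navpd.synthetic import SyntheticSpec, gen_bundle, gen_trajectory

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = SyntheticSpec(seed=seed)
    bundle = gen_bundle(spec)
    traj = gen_trajectory(bundle.model, spec)

    n = spec.residues_per_helix
    loops = [(f"D{d}", n - 1, n + 2) for d in range(1, spec.n_domains + 1)]
    selections = {
        "calpha_all": Selection.calpha(),
        "calpha_no_loops": Selection.calpha(exclude_ranges=loops),
    }
    series = {"time_ns": traj.frame_times}
    for name, sel in selections.items():
        series[f"rmsd_fit_{name}_A"] = rmsd_series(traj, bundle.model, sel, fit=True)
        series[f"rmsd_nofit_{name}_A"] = rmsd_series(traj, bundle.model, sel, fit=False)
    gates = gate_series(traj, bundle.gate)
    series["gate_diameter_A"] = gates.values
    df = pd.DataFrame(series)
    df.to_csv(RESULTS / "trajectory_metrics.tsv", sep="\t", index=False, float_format="%.4f")

    fluct = rmsf(traj)
    rdf = pd.DataFrame([{"domain": d, "resindex": i, "rmsf_A": round(v, 4)}
                        for (d, i), v in sorted(fluct.items())])
    rdf.to_csv(RESULTS / "rmsf.tsv", sep="\t", index=False)

    loop_mask = rdf.resindex.between(n - 1, n + 2)
    print(f"{traj.n_frames} frames; mean fitted Cα RMSD "
          f"{df.rmsd_fit_calpha_all_A.mean():.2f} Å "
          f"(without turns {df.rmsd_fit_calpha_no_loops_A.mean():.2f} Å)")
    print(f"RMSF: turns {rdf[loop_mask].rmsf_A.mean():.2f} Å vs helices "
          f"{rdf[~loop_mask].rmsf_A.mean():.2f} Å")
    print(f"gate diameter range {gates.min:.2f}–{gates.max:.2f} Å → "
          f"{classify_state(gates.max, bundle.gate.ion_diameter)} throughout")


if __name__ == "__main__":
    main()
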