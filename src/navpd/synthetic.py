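"""Seeded generators for every input the pipeline consumes, with known ground truth.

The generators stand in for the real study inputs — template-based domain
model ensembles, evolutionary-coupling score tables, MD trajectories, docking
decoys and MM-GBSA frame dumps — at desk scale and with planted ground truth,
so every stage of the pipeline is testable offline.

The structural substrate is a pseudo-C4 tetramer of four-helix-hairpin
"domains": each domain is two idealised α-helices (rise 1.5 Å/residue, helix
radius 2.3 Å, 100° twist) joined by a turn, with the inner helices lining a
central pore around the z axis.  The bundle radius is solved numerically so
the designated gate residues sit at a requested gate diameter; with the
default 3.5 Å target the assembly is closed by the 7.8 Å hydrated-Na⁺ rule.

All generators are pure functions of the spec: a fixed seed yields
byte-identical output.  Randomness flows through one explicit NumPy generator
per call, seeded from ``(spec.seed, per-generator tag)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .contact_analysis import ContactMap, ECRecord, ECSet, Scope, compute_contact_map
from .docking_analysis import Pose
from .energetics import EnergyComponents, FrameEnergyTable, ResidueDecomposition
from .errors import SyntheticSpecError
from .model_selection import CandidateModel
from .pore_geometry import GateSpec, gate_diameter
from .structure_model import Atom, Residue, StructureModel, Trajectory

__all__ = [
    "SyntheticSpec",
    "SyntheticBundle",
    "CandidateSet",
    "gen_bundle",
    "gen_ec",
    "gen_candidates",
    "gen_trajectory",
    "gen_poses",
    "gen_energy_frames",
]

# rng stream tags, one per generator
_TAG_EC, _TAG_CAND, _TAG_TRAJ, _TAG_POSE, _TAG_ENERGY = 11, 13, 17, 19, 23

# Table-style per-component means used as the default MM-GBSA generator centre
# (electrostatic, van der Waals, GB polar, nonpolar surface), kcal/mol.
PILSICAINIDE_MEANS = (-14.38, -5.52, 19.41, -1.79)
BISPHENOL_A_MEANS = (-28.96, -1.75, 9.8324, -3.87)
MEXILETINE_MEANS = (-23.30, -14.36, 14.83, -3.85)

# Default planted key residues (strong binders below the −2.0 kcal/mol rule).
DEFAULT_KEY_RESIDUES = (
    (("D1", 121), -3.0035),
    (("D3", 416), -2.001),
    (("D4", 463), -2.202),
    (("D4", 512), -3.29),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the synthetic study, with the study-condition defaults."""

    seed: int = 1
    # geometry
    n_domains: int = 4
    helices_per_domain: int = 2
    residues_per_helix: int = 15
    gate_diameter_target: float = 3.5  # Å; < 7.8 ⇒ closed by construction
    pore_radius_target: float | None = None
    helix_separation: float = 8.0  # Å between the two helix axes of a domain
    # EC generation
    contact_tpr: float = 0.7
    ec_noise_sd: float = 0.03
    # candidate ensembles
    n_candidates: int = 20
    noise_levels: tuple[float, ...] = (0.0, 0.3, 0.6, 1.0, 1.5)
    energy_intercept: float = -260.0
    energy_slope: float = 40.0  # per Å of coordinate noise; > 0 so less noise ⇒ lower energy
    energy_jitter_sd: float = 0.5
    # trajectory
    n_frames: int = 20
    helix_jitter_sd: float = 0.2
    loop_jitter_sd: float = 0.8
    drift_step_sd: float = 0.15
    # docking poses
    n_poses: int = 30
    n_pose_clusters: int = 3
    n_pose_outliers: int = 3
    pose_jitter_sd: float = 0.2
    # MM-GBSA frames
    n_energy_frames: int = 3000
    mmgbsa_means: tuple[float, float, float, float] = PILSICAINIDE_MEANS
    mmgbsa_sds: tuple[float, float, float, float] = (3.0, 2.0, 2.5, 0.5)
    key_residue_energies: tuple = DEFAULT_KEY_RESIDUES
    n_background_residues: int = 40

    def __post_init__(self) -> None:
        if self.n_domains < 1 or self.helices_per_domain < 1 or self.residues_per_helix < 2:
            raise SyntheticSpecError("all structural counts must be >= 1 (helix length >= 2)")
        if not 0.0 <= self.contact_tpr <= 1.0:
            raise SyntheticSpecError("contact_tpr must lie in [0, 1]")
        if self.gate_diameter_target <= 0:
            raise SyntheticSpecError("gate_diameter_target must be positive")
        if self.pore_radius_target is not None and (
                self.pore_radius_target > self.gate_diameter_target):
            raise SyntheticSpecError(
                "pore_radius_target conflicts with gate_diameter_target")
        if self.energy_slope <= 0:
            raise SyntheticSpecError("energy_slope must be positive")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


@dataclass
class SyntheticBundle:
    """The generated tetramer plus its ground truth."""

    model: StructureModel
    intra_maps: dict[str, ContactMap]
    inter_map: ContactMap
    gate: GateSpec
    inner_radius: float  # solved pore placement radius, Å


# ---------------------------------------------------------------------------
# structural bundle
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = math.radians(100.0)


def _helix_residue_atoms(k: int, n: int, descending: bool) -> list[tuple[str, str, np.ndarray]]:
    """Atoms of residue k (0-based) of an ideal helix in its local frame."""
    z = ((n - 1 - k) if descending else k) * _HELIX_RISE
    theta = k * _HELIX_TWIST

    def on_helix(ang: float, dz: float, radial: float = _HELIX_RADIUS) -> np.ndarray:
        return np.array([radial * math.cos(ang), radial * math.sin(ang), z + dz])

    return [
        ("N", "N", on_helix(theta - 0.7, -0.6)),
        ("CA", "C", on_helix(theta, 0.0)),
        ("C", "C", on_helix(theta + 0.7, 0.6)),
        ("O", "O", on_helix(theta + 0.7, 0.6, _HELIX_RADIUS + 1.2)),
        ("CB", "C", on_helix(theta, 0.0, _HELIX_RADIUS + 1.5)),
        ("H", "H", on_helix(theta - 0.7, -1.2)),
    ]


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _build_tetramer(spec: SyntheticSpec, inner_radius: float) -> StructureModel:
    n = spec.residues_per_helix
    residues: list[Residue] = []
    for d in range(spec.n_domains):
        dom = f"D{d + 1}"
        rot = _rot_z(2.0 * math.pi * d / spec.n_domains)
        # helix axis offsets along the domain's radial direction (+x locally):
        # the last helix is the inner (pore-lining) one, carrying the gate residue.
        seq = 1
        for h in range(spec.helices_per_domain):
            inner = h == spec.helices_per_domain - 1
            offset = np.array([inner_radius + (0.0 if inner else spec.helix_separation), 0.0, 0.0])
            # inner helix points its atoms toward the pore: rotate local frame by pi
            flip = _rot_z(math.pi) if inner else np.eye(3)
            for k in range(n):
                atoms = [
                    Atom(name, element, rot @ (flip @ xyz + offset), is_hydrogen=element == "H")
                    for name, element, xyz in _helix_residue_atoms(k, n, descending=inner)
                ]
                residues.append(Residue(dom, seq, "ALA", atoms))
                seq += 1
    return StructureModel("synthetic_bundle", residues)


def _gate_spec_for(spec: SyntheticSpec) -> GateSpec:
    gate_idx = spec.helices_per_domain * spec.residues_per_helix  # bottom of inner helix
    if spec.n_domains == 4:
        pairs = ((("D1", gate_idx), ("D3", gate_idx)),
                 (("D2", gate_idx), ("D4", gate_idx)))
    else:
        pairs = ((("D1", gate_idx), (f"D{spec.n_domains}", gate_idx)),)
    return GateSpec(pairs=pairs)


def gen_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Build the C4 helix-hairpin tetramer hitting the requested gate diameter.

    The pore placement radius is solved with a bracketing root-finder so the
    gate residues' minimum heavy-atom distance matches
    ``spec.gate_diameter_target``; ground-truth contact maps (8 Å minimum
    atom-distance rule) are computed for each domain and across domains.
    """
    gate = _gate_spec_for(spec)

    def diameter_error(r: float) -> float:
        return gate_diameter(_build_tetramer(spec, r), gate) - spec.gate_diameter_target

    lo, hi = 2.0, 40.0
    try:
        if diameter_error(lo) > 0 or diameter_error(hi) < 0:
            raise ValueError("target outside bracket")
        inner_radius = brentq(diameter_error, lo, hi, xtol=1e-4)
    except ValueError as exc:
        raise SyntheticSpecError(
            f"gate diameter target {spec.gate_diameter_target} Å is infeasible: {exc}") from exc

    model = _build_tetramer(spec, float(inner_radius))
    intra = {dom: compute_contact_map(model, Scope.intra(dom))
             for dom in model.domain_ids()}
    inter = compute_contact_map(model, Scope.inter())
    return SyntheticBundle(model, intra, inter, gate, float(inner_radius))


# ---------------------------------------------------------------------------
# EC scores
# ---------------------------------------------------------------------------


def _scope_universe(truth: ContactMap, spec: SyntheticSpec) -> list:
    """All candidate pairs of the truth map's scope, from the spec's numbering."""
    n_res = spec.helices_per_domain * spec.residues_per_helix
    scope = truth.scope
    if scope.kind == "intra":
        dom = scope.domains[0]
        return [((dom, i), (dom, j))
                for i in range(1, n_res + 1) for j in range(i + 1, n_res + 1)]
    doms = list(scope.domains) if scope.domains else [f"D{d + 1}" for d in range(spec.n_domains)]
    pairs = []
    for a in range(len(doms)):
        for b in range(a + 1, len(doms)):
            for i in range(1, n_res + 1):
                for j in range(1, n_res + 1):
                    pairs.append(((doms[a], i), (doms[b], j)))
    return pairs


def gen_ec(truth: ContactMap, spec: SyntheticSpec,
           rng: np.random.Generator | None = None) -> ECSet:
    """Emulate an EC-score table with designed precision ``spec.contact_tpr``.

    Each true contact independently receives a high score U(0.25, 1.0) with
    probability ``contact_tpr``; a same-sized pool of non-contact pairs
    contributes high-scoring decoys with probability ``1 − contact_tpr``, so
    the expected precision of the >0.2 prediction set equals ``contact_tpr``.
    The remaining true pairs and an equal number of non-contact pairs receive
    sub-threshold scores U(0, 0.2) + N(0, ec_noise_sd), clipped to [0, 0.2].
    """
    if not truth.pairs:
        raise SyntheticSpecError("cannot generate EC scores from an empty contact map")
    if rng is None:
        # fold the scope label in so congruent domains get distinct score tables
        rng = np.random.default_rng([spec.seed, _TAG_EC, *truth.scope.label().encode()])
    true_pairs = sorted(truth.pairs)
    universe = _scope_universe(truth, spec)
    false_pool = [p for p in universe if p not in truth.pairs]
    rng.shuffle(false_pool)

    records: list[ECRecord] = []
    high_mask = rng.random(len(true_pairs)) < spec.contact_tpr
    low_true = []
    for pair, high in zip(true_pairs, high_mask):
        if high:
            records.append(ECRecord(pair[0], pair[1], float(rng.uniform(0.25, 1.0))))
        else:
            low_true.append(pair)

    n_decoy_pool = min(len(true_pairs), len(false_pool))
    decoy_mask = rng.random(n_decoy_pool) < (1.0 - spec.contact_tpr)
    n_decoys = int(decoy_mask.sum())
    decoys = false_pool[:n_decoys]
    for pair in decoys:
        records.append(ECRecord(pair[0], pair[1], float(rng.uniform(0.25, 1.0))))

    low_false = false_pool[n_decoys:n_decoys + len(low_true)]
    for pair in low_true + low_false:
        score = rng.uniform(0.0, 0.2) + rng.normal(0.0, spec.ec_noise_sd)
        records.append(ECRecord(pair[0], pair[1], float(np.clip(score, 0.0, 0.2))))
    return ECSet(records, truth.scope)


# ---------------------------------------------------------------------------
# candidate ensembles
# ---------------------------------------------------------------------------


@dataclass
class CandidateSet:
    """Per-domain candidate ensembles with their pseudo-energy table."""

    by_domain: dict[str, list[CandidateModel]]
    table: pd.DataFrame  # model_id, domain_id, noise_level, energy


def gen_candidates(reference: StructureModel, spec: SyntheticSpec,
                   rng: np.random.Generator | None = None) -> CandidateSet:
    """Perturbed copies of each reference domain with noise-correlated energies.

    Candidate i of a domain gets a rigid Gaussian displacement of each whole
    residue at scale ``noise_levels[i mod len(noise_levels)]`` (residue-level,
    not per-atom, so local geometry is preserved while residue–residue
    distances diffuse) and pseudo-energy ``intercept + slope·noise +
    N(0, jitter)`` — lower noise ⇒ lower energy, so the least-perturbed
    candidates are the planted best models.
    """
    rng = rng if rng is not None else spec.rng(_TAG_CAND)
    by_domain: dict[str, list[CandidateModel]] = {}
    rows = []
    for d_idx, (dom, residues) in enumerate(reference.domains().items()):
        domain_struct = StructureModel(f"{dom}_ref", [
            Residue(r.domain_id, r.seq_index, r.name, r.atoms) for r in residues])
        coords = domain_struct.coords_array()
        atoms_per_res = [len(r.atoms) for r in domain_struct.residues]
        cands = []
        for i in range(spec.n_candidates):
            noise = spec.noise_levels[i % len(spec.noise_levels)]
            if noise > 0:
                shifts = rng.normal(0.0, noise, (len(atoms_per_res), 3))
                perturbed = coords + np.repeat(shifts, atoms_per_res, axis=0)
            else:
                perturbed = coords.copy()
            energy = float(spec.energy_intercept + spec.energy_slope * noise
                           + rng.normal(0.0, spec.energy_jitter_sd))
            model_id = f"{dom.lower()}_{1000 * d_idx + i:04d}"
            structure = domain_struct.with_coords(perturbed, model_id=model_id)
            cands.append(CandidateModel(model_id, dom, structure, energy))
            rows.append({"model_id": model_id, "domain_id": dom,
                         "noise_level": noise, "energy": energy})
        by_domain[dom] = cands
    return CandidateSet(by_domain, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# trajectory, poses, energy frames
# ---------------------------------------------------------------------------


def _loop_indices(spec: SyntheticSpec) -> set[int]:
    """Domain-local residue indices treated as the flexible hairpin turn."""
    n = spec.residues_per_helix
    return {n - 1, n, n + 1, n + 2}


def gen_trajectory(reference: StructureModel, spec: SyntheticSpec,
                   rng: np.random.Generator | None = None) -> Trajectory:
    """Jittered frames about the reference with loops noisier than helices.

    Each frame adds per-atom Gaussian noise whose scale depends on the
    residue's secondary-structure class (turn residues fluctuate more than
    helix residues) plus a slow random-walk rigid drift, so no-fit RMSD grows
    above fitted RMSD as in a real equilibration.
    """
    rng = rng if rng is not None else spec.rng(_TAG_TRAJ)
    loops = _loop_indices(spec)
    sigmas = np.array([
        spec.loop_jitter_sd if res.seq_index in loops else spec.helix_jitter_sd
        for res, _atom in reference.atom_records()
    ])
    coords = reference.coords_array()
    frames = []
    drift = np.zeros(3)
    for f in range(spec.n_frames):
        drift = drift + rng.normal(0.0, spec.drift_step_sd, 3)
        noisy = coords + drift + rng.normal(0.0, 1.0, coords.shape) * sigmas[:, None]
        frames.append(reference.with_coords(noisy, model_id=f"frame_{f:04d}"))
    times = np.arange(spec.n_frames) * 0.1
    return Trajectory(frames, frame_times=times)


def gen_poses(pocket_center: np.ndarray, spec: SyntheticSpec,
              rng: np.random.Generator | None = None) -> list[Pose]:
    """Docking decoys: planted geometric clusters plus far outliers.

    Clusters sit ≥ 12 Å apart (well beyond the 2 Å clustering cutoff) around
    the pocket centre; within-cluster jitter keeps pose–pose RMSD well below
    the cutoff.  Energies are drawn about per-cluster baselines ordered by
    cluster index, outliers are weaker binders placed 25 Å out.
    """
    rng = rng if rng is not None else spec.rng(_TAG_POSE)
    pocket_center = np.asarray(pocket_center, dtype=float)
    template = rng.normal(0.0, 1.5, (8, 3))  # rigid 8-atom pseudo-ligand
    k = spec.n_pose_clusters
    angles = 2.0 * math.pi * np.arange(k) / max(k, 1)
    centers = pocket_center + 12.0 * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros(k)])

    n_core = spec.n_poses - spec.n_pose_outliers
    counts = [n_core // k + (1 if j < n_core % k else 0) for j in range(k)]
    poses: list[Pose] = []
    i = 0
    for j, (center, count) in enumerate(zip(centers, counts)):
        base = -120.0 + 0.8 * j
        for _ in range(count):
            coords = template + center + rng.normal(0.0, spec.pose_jitter_sd, template.shape)
            poses.append(Pose(f"p{i:03d}", f"r{i % 3 + 1}", coords,
                              float(base + rng.normal(0.0, 0.3))))
            i += 1
    for _ in range(spec.n_pose_outliers):
        direction = rng.normal(0.0, 1.0, 3)
        direction /= np.linalg.norm(direction)
        coords = template + pocket_center + 25.0 * direction \
            + rng.normal(0.0, spec.pose_jitter_sd, template.shape)
        poses.append(Pose(f"p{i:03d}", f"r{i % 3 + 1}", coords,
                          float(-115.0 + rng.normal(0.0, 0.5))))
        i += 1
    return poses


def gen_energy_frames(spec: SyntheticSpec, rng: np.random.Generator | None = None
                      ) -> tuple[FrameEnergyTable, ResidueDecomposition]:
    """Gaussian per-frame MM-GBSA components plus a planted decomposition.

    Frame components are drawn about ``spec.mmgbsa_means`` with
    ``spec.mmgbsa_sds``; the decomposition plants ``spec.key_residue_energies``
    below the −2.0 kcal/mol rule on top of weak background residues.
    """
    rng = rng if rng is not None else spec.rng(_TAG_ENERGY)
    means = np.asarray(spec.mmgbsa_means, dtype=float)
    sds = np.asarray(spec.mmgbsa_sds, dtype=float)
    draws = rng.normal(means, sds, (spec.n_energy_frames, 4))
    frames = [EnergyComponents(*row) for row in draws]

    records = {tuple(key): float(val) for key, val in spec.key_residue_energies}
    planted = set(records)
    dom_cycle = [f"D{d + 1}" for d in range(max(spec.n_domains, 1))]
    idx = 1
    added = 0
    while added < spec.n_background_residues:
        key = (dom_cycle[added % len(dom_cycle)], idx)
        idx += 1
        if key in planted:
            continue
        records[key] = float(rng.uniform(-1.5, 0.5))
        added += 1
    return FrameEnergyTable(frames, frame_interval_ps=1.0), ResidueDecomposition(records)
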