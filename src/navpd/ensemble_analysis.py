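"""Trajectory descriptors: RMSD series (fit / no-fit), per-residue RMSF, gate series.

All metrics are mass-unweighted and operate on an atom :class:`Selection`
resolved once against the trajectory topology (e.g. Cα only, with optional
per-domain residue-range exclusions such as the mobile P-loops).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError
from .pore_geometry import GateSpec, gate_diameter
from .structure_model import StructureModel, Trajectory, coordinate_rmsd, kabsch_superpose

__all__ = ["Selection", "GateSeries", "rmsd_series", "rmsf", "gate_series"]

SeqRange = tuple[str, int, int]  # (domain_id, first, last) inclusive


@dataclass(frozen=True)
class Selection:
    """Predicate over residues/atoms of a topology.

    ``domains`` restricts to the listed domain ids; ``atom_names`` to the
    listed atom names (e.g. only Cα); ``seq_ranges`` keeps only residues in
    the listed inclusive ranges while ``exclude_ranges`` drops them (useful
    for masking flexible loops).  Heavy atoms only by default.
    """

    domains: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    seq_ranges: tuple[SeqRange, ...] | None = None
    exclude_ranges: tuple[SeqRange, ...] = ()
    heavy_only: bool = True

    @classmethod
    def calpha(cls, domains: Sequence[str] | None = None,
               exclude_ranges: Sequence[SeqRange] = ()) -> "Selection":
        return cls(domains=tuple(domains) if domains else None,
                   atom_names=("CA",), exclude_ranges=tuple(exclude_ranges))

    def _residue_ok(self, domain_id: str, seq_index: int) -> bool:
        if self.domains is not None and domain_id not in self.domains:
            return False
        if self.seq_ranges is not None and not any(
                d == domain_id and lo <= seq_index <= hi for d, lo, hi in self.seq_ranges):
            return False
        return not any(d == domain_id and lo <= seq_index <= hi
                       for d, lo, hi in self.exclude_ranges)

    def resolve(self, model: StructureModel) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Flat-order atom mask plus the residue key of each selected atom."""
        mask, keys = [], []
        for res, atom in model.atom_records():
            ok = (self._residue_ok(res.domain_id, res.seq_index)
                  and (self.atom_names is None or atom.name in self.atom_names)
                  and (not self.heavy_only or not atom.is_hydrogen))
            mask.append(ok)
            if ok:
                keys.append(res.key)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SelectionError("selection resolves to no atoms")
        return mask, keys


def rmsd_series(
    traj: Trajectory,
    reference: StructureModel,
    selection: Selection | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selection against the reference.

    With ``fit`` each frame is optimally superposed on the reference over the
    selection first; without it the raw ("nofit") coordinate RMSD is reported.
    """
    selection = selection or Selection.calpha()
    mask, keys = selection.resolve(traj.frames[0])
    ref_mask, ref_keys = selection.resolve(reference)
    if keys != ref_keys:
        raise SelectionError("trajectory/reference topologies differ on the selection")
    ref = reference.coords_array()[ref_mask]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        x = frame.coords_array()[mask]
        if fit:
            _, _, out[i] = kabsch_superpose(x, ref)
        else:
            out[i] = coordinate_rmsd(x, ref)
    return out


def rmsf(
    traj: Trajectory,
    selection: Selection | None = None,
    fit: bool = True,
    n_iterations: int = 2,
) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (Å) about the time-average structure.

    Frames are superposed on an iterated mean structure (``n_iterations``
    rounds, starting from the first frame) before the fluctuations are
    computed; per-atom fluctuations are averaged within each residue.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    selection = selection or Selection.calpha()
    mask, keys = selection.resolve(traj.frames[0])
    stack = traj.coords_stack()[:, mask, :]
    if fit:
        ref = stack[0]
        for _ in range(max(1, n_iterations)):
            aligned = np.empty_like(stack)
            for i in range(len(stack)):
                R, t, _ = kabsch_superpose(stack[i], ref)
                aligned[i] = stack[i] @ R.T + t
            ref = aligned.mean(axis=0)
        stack = aligned
    mean_pos = stack.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stack - mean_pos) ** 2, axis=2), axis=0))
    out: dict[tuple[str, int], list[float]] = {}
    for key, val in zip(keys, per_atom):
        out.setdefault(key, []).append(float(val))
    return {k: float(np.mean(v)) for k, v in out.items()}


@dataclass
class GateSeries:
    """Per-frame gate diameters with their min/max summary."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())


def gate_series(traj: Trajectory, gate: GateSpec,
                atom_rule: str = "min-heavy-atom") -> GateSeries:
    """Gate diameter of every frame (propagates residue-lookup errors)."""
    return GateSeries(np.array([gate_diameter(f, gate, atom_rule) for f in traj.frames]))
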