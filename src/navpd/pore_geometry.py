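"""Channel axis estimation, pore radius profile, gate diameter and state call.

The activation gate of the pore domain is measured as the larger of the two
cross-pore residue-pair distances (D1–D3 and D2–D4 pairs by default).  A
frame is *closed* when that diameter is strictly below the effective diameter
of a hydrated sodium ion (7.8 Å by default).

The radius profile is a simplified channel-finder: at each position along the
pore axis, the pore radius is the radius of the largest sphere centred in the
perpendicular plane that clears every nearby atom's van der Waals surface,
found by a deterministic multi-start coordinate descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryError, MissingResidueError
from .structure_model import StructureModel, residue_min_distance

__all__ = [
    "PoreAxis",
    "PoreProfile",
    "GateSpec",
    "VDW_RADII",
    "estimate_pore_axis",
    "radius_profile",
    "gate_diameter",
    "classify_state",
]

# Fixed van der Waals radii (Å); the default covers unlisted elements.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
DEFAULT_VDW = 1.70

DEFAULT_ION_DIAMETER = 7.8  # hydrated Na+ (Å)

ResKey = tuple[str, int]


@dataclass(frozen=True)
class GateSpec:
    """Residue pairs defining the gate constriction plus the probe ion size."""

    pairs: tuple[tuple[ResKey, ResKey], ...] = (
        (("D1", 121), ("D3", 356)),
        (("D2", 225), ("D4", 463)),
    )
    ion_diameter: float = DEFAULT_ION_DIAMETER

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("GateSpec needs at least one residue pair")

    def residues(self) -> list[ResKey]:
        return [k for pair in self.pairs for k in pair]


@dataclass(frozen=True)
class PoreAxis:
    """A line: point on the axis plus unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero axis direction")
        object.__setattr__(self, "direction", d / n)

    def plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal vectors spanning the plane normal to the axis."""
        d = self.direction
        ref = np.eye(3)[np.argmin(np.abs(d))]
        b1 = np.cross(d, ref)
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(d, b1)
        return b1, b2


@dataclass
class PoreProfile:
    """Pore radius as a function of position along the channel axis."""

    z_values: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.z_values.shape != self.radii.shape:
            raise ValueError("z_values/radii length mismatch")
        if np.any(self.radii < 0):
            raise ValueError("negative pore radius")

    @property
    def min_radius(self) -> float:
        return float(self.radii.min())

    @property
    def min_z(self) -> float:
        return float(self.z_values[int(np.argmin(self.radii))])


def estimate_pore_axis(model: StructureModel, gate: GateSpec) -> PoreAxis:
    """Estimate the channel axis of a multi-domain assembly.

    The axis passes through the centroid of the gate residues' Cα atoms.  Its
    direction is the spectrally isolated principal axis of the Cα coordinate
    covariance — for a (pseudo-)C4 bundle the two in-plane eigenvalues are
    nearly degenerate while the symmetry axis stands apart, which makes the
    choice rotation-equivariant.  The sign is fixed so the largest-magnitude
    component is positive.
    """
    if len(model.domains()) < 2:
        raise DegenerateGeometryError("pore axis needs a multi-domain assembly")
    gate_ca = []
    for dom, idx in gate.residues():
        gate_ca.append(model.get_residue(dom, idx).get_atom("CA").coords)
    point = np.mean(gate_ca, axis=0)

    ca, _ = model.calpha_coords()
    if len(ca) < 3:
        raise DegenerateGeometryError("too few Cα atoms for axis estimation")
    centred = ca - ca.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    w, v = np.linalg.eigh(cov)
    separation = [min(abs(w[i] - w[j]) for j in range(3) if j != i) for i in range(3)]
    direction = v[:, int(np.argmax(separation))]
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    return PoreAxis(point, direction)


def _clearance(c: np.ndarray, atoms: np.ndarray, radii: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(atoms - c, axis=1) - radii))


def _max_clearance_in_plane(
    origin: np.ndarray,
    b1: np.ndarray,
    b2: np.ndarray,
    atoms: np.ndarray,
    radii: np.ndarray,
    step0: float = 1.0,
    min_step: float = 0.05,
    ring: float = 1.0,
) -> float:
    """Deterministic multi-start coordinate descent maximising the clearance."""
    starts = [(0.0, 0.0)] + [
        (ring * np.cos(k * np.pi / 4), ring * np.sin(k * np.pi / 4)) for k in range(8)
    ]
    best = -np.inf
    for sx, sy in starts:
        x = np.array([sx, sy])
        fx = _clearance(origin + x[0] * b1 + x[1] * b2, atoms, radii)
        step = step0
        while step >= min_step:
            moved = False
            for dx, dy in ((step, 0), (-step, 0), (0, step), (0, -step)):
                cand = x + (dx, dy)
                fc = _clearance(origin + cand[0] * b1 + cand[1] * b2, atoms, radii)
                if fc > fx + 1e-12:
                    x, fx = cand, fc
                    moved = True
                    break
            if not moved:
                step /= 2
        best = max(best, fx)
    return best


def radius_profile(
    model: StructureModel,
    axis: PoreAxis,
    z_range: tuple[float, float],
    step: float = 0.5,
    vdw: Mapping[str, float] | None = None,
    slab_half_width: float = 3.0,
    max_radius: float = 15.0,
    heavy_only: bool = True,
) -> PoreProfile:
    """Pore radius at each position along the axis within ``z_range``.

    Positions are measured along the axis direction relative to ``axis.point``.
    At each position the largest clearance sphere is sought among atoms within
    ``slab_half_width`` of the plane; an empty slab reports the ``max_radius``
    sentinel with a warning.  Negative clearances clamp to zero.
    """
    table = dict(VDW_RADII if vdw is None else vdw)
    coords, radii = [], []
    for res, atom in model.atom_records():
        if heavy_only and atom.is_hydrogen:
            continue
        coords.append(atom.coords)
        radii.append(table.get(atom.element, DEFAULT_VDW))
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    s_atom = (coords - axis.point) @ axis.direction
    b1, b2 = axis.plane_basis()

    z0, z1 = z_range
    z_values = np.arange(z0, z1 + 1e-9, step)
    out = np.empty_like(z_values)
    empty_slabs = 0
    for i, z in enumerate(z_values):
        mask = np.abs(s_atom - z) <= slab_half_width
        if not mask.any():
            empty_slabs += 1
            out[i] = max_radius
            continue
        origin = axis.point + z * axis.direction
        r = _max_clearance_in_plane(origin, b1, b2, coords[mask], radii[mask])
        out[i] = min(max(r, 0.0), max_radius)
    if empty_slabs:
        warnings.warn(f"{empty_slabs} empty axial slab(s): radius reported as the "
                      f"{max_radius} Å upper-bound sentinel")
    return PoreProfile(z_values, out)


def gate_diameter(frame: StructureModel, gate: GateSpec,
                  atom_rule: str = "min-heavy-atom") -> float:
    """Gate diameter of one frame: the largest of the gate-pair distances (Å).

    ``atom_rule`` is ``min-heavy-atom`` (default) or ``calpha``.
    """
    dists = []
    for (dom_a, idx_a), (dom_b, idx_b) in gate.pairs:
        ra = frame.get_residue(dom_a, idx_a)
        rb = frame.get_residue(dom_b, idx_b)
        if atom_rule == "min-heavy-atom":
            dists.append(residue_min_distance(ra, rb, heavy_only=True))
        elif atom_rule == "calpha":
            dists.append(float(np.linalg.norm(
                ra.get_atom("CA").coords - rb.get_atom("CA").coords)))
        else:
            raise ValueError(f"unknown atom_rule {atom_rule!r}")
    return max(dists)


def classify_state(min_diameter: float, ion_diameter: float = DEFAULT_ION_DIAMETER) -> str:
    """'closed' when the gate diameter is strictly below the ion diameter, else 'open'."""
    if min_diameter < 0:
        raise ValueError(f"negative gate diameter {min_diameter}")
    return "closed" if min_diameter < ion_diameter else "open"
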