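"""Hierarchical structure model and PDB I/O.

The data model is atoms → residues → domains.  A *domain* here is one of the
four non-identical repeats (D1–D4) of a eukaryotic sodium-channel pore domain,
or simply a chain for generic structures.  Coordinates are in ångström
throughout.  Multi-model PDB files become :class:`Trajectory` objects whose
frames share one topology.

PDB parsing and writing are delegated to :mod:`gemmi`; this module only maps
between gemmi's hierarchy and the package's own containers (which carry the
domain-local residue numbering the rest of the pipeline keys on).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, MissingResidueError, PDBFormatError

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "residue_min_distance",
    "kabsch_superpose",
]


@dataclass
class Atom:
    """A single atom: name, element symbol and Cartesian coordinates (Å)."""

    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise ValueError(f"atom {self.name!r} has an empty element symbol")


@dataclass
class Residue:
    """A residue within a domain, identified by (domain_id, seq_index)."""

    domain_id: str
    seq_index: int
    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError(f"seq_index must be >= 1, got {self.seq_index}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.domain_id, self.seq_index)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom_coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            raise ValueError(f"residue {self.key} has no eligible atoms")
        return np.array([a.coords for a in atoms])

    def get_atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise MissingResidueError(f"atom {name!r} not found in residue {self.key}")


@dataclass
class StructureModel:
    """An ordered collection of residues grouped by domain.

    Residues must appear grouped by domain with strictly increasing seq_index
    within each domain; ``validate()`` enforces this.
    """

    model_id: str
    residues: list[Residue]
    metadata: dict = field(default_factory=dict)

    # -- organisation -------------------------------------------------

    def domains(self) -> dict[str, list[Residue]]:
        """Residues grouped by domain_id, in first-appearance order."""
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.domain_id, []).append(r)
        return out

    def domain_ids(self) -> list[str]:
        return list(self.domains().keys())

    def get_residue(self, domain_id: str, seq_index: int) -> Residue:
        for r in self.residues:
            if r.domain_id == domain_id and r.seq_index == seq_index:
                return r
        raise MissingResidueError(f"residue ({domain_id!r}, {seq_index}) not in model {self.model_id!r}")

    def validate(self) -> None:
        if not self.residues:
            raise ValueError(f"model {self.model_id!r} has no residues")
        for dom, residues in self.domains().items():
            seen = [r.seq_index for r in residues]
            if any(b <= a for a, b in zip(seen, seen[1:])):
                raise ValueError(f"domain {dom!r} residue numbering not strictly increasing")
            for r in residues:
                if not r.heavy_atoms():
                    raise ValueError(f"residue {r.key} has no heavy atom")

    # -- flat atom access ---------------------------------------------

    def atom_records(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def coords_array(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, flat residue order."""
        return np.array([a.coords for _, a in self.atom_records()])

    def with_coords(self, coords: np.ndarray, model_id: str | None = None) -> "StructureModel":
        """Copy with identical topology but replaced flat-order coordinates."""
        coords = np.asarray(coords, dtype=float)
        n = sum(len(r.atoms) for r in self.residues)
        if coords.shape != (n, 3):
            raise ValueError(f"expected coords of shape ({n}, 3), got {coords.shape}")
        new_res = []
        i = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(Atom(a.name, a.element, coords[i].copy(), a.is_hydrogen))
                i += 1
            new_res.append(Residue(r.domain_id, r.seq_index, r.name, atoms))
        return StructureModel(model_id or self.model_id, new_res, dict(self.metadata))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    model_id: str | None = None) -> "StructureModel":
        """Copy with every coordinate mapped through ``x -> R x + t``."""
        x = self.coords_array()
        return self.with_coords(x @ np.asarray(rotation).T + np.asarray(translation), model_id)

    def calpha_coords(self, domain_id: str | None = None) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Cα coordinates (and residue keys) for one domain or the whole model."""
        coords, keys = [], []
        for r in self.residues:
            if domain_id is not None and r.domain_id != domain_id:
                continue
            for a in r.atoms:
                if a.name == "CA":
                    coords.append(a.coords)
                    keys.append(r.key)
                    break
        return np.array(coords), keys

    def topology_signature(self) -> tuple:
        return tuple(
            (r.domain_id, r.seq_index, r.name, tuple(a.name for a in r.atoms))
            for r in self.residues
        )


@dataclass
class Trajectory:
    """Frames sharing one topology; coordinates differ frame to frame."""

    frames: list[StructureModel]
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        sig = self.frames[0].topology_signature()
        for f in self.frames[1:]:
            if f.topology_signature() != sig:
                raise ValueError("trajectory frames are not topologically identical")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != len(self.frames):
                raise ValueError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_stack(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([f.coords_array() for f in self.frames])


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def _from_gemmi_model(gmodel: gemmi.Model, domain_map: Mapping[str, str] | None,
                      model_id: str) -> StructureModel:
    residues: list[Residue] = []
    icodes: list[tuple[str, int, str]] = []
    for chain in gmodel:
        dom = (domain_map or {}).get(chain.name, chain.name)
        for gres in chain:
            # altloc policy: within each atom name keep the highest-occupancy
            # conformer, first on tie (file order).
            chosen: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = chosen.get(ga.name)
                if prev is None or ga.occ > prev.occ + 1e-12:
                    chosen[ga.name] = ga
            atoms = [
                Atom(ga.name, ga.element.name or "X",
                     np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                     is_hydrogen=ga.is_hydrogen())
                for ga in chosen.values()
            ]
            if not atoms:
                continue
            icode = gres.seqid.icode
            if icode and icode != " ":
                icodes.append((dom, gres.seqid.num, icode))
            residues.append(Residue(dom, gres.seqid.num, gres.name, atoms))
    model = StructureModel(model_id, residues)
    if icodes:
        model.metadata["insertion_codes"] = icodes
    return model


def read_pdb(path: str | Path, domain_map: Mapping[str, str] | None = None
             ) -> StructureModel | Trajectory:
    """Read a PDB file into a StructureModel (or Trajectory for multi-MODEL files).

    ``domain_map`` relabels author chain IDs to domain labels (e.g. A→D1).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    models = [
        _from_gemmi_model(gm, domain_map, f"{path.stem}" if len(st) == 1 else f"{path.stem}.{i + 1}")
        for i, gm in enumerate(st)
    ]
    models = [m for m in models if m.residues]
    if not models:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    if len(models) == 1:
        return models[0]
    return Trajectory(models)


def _to_gemmi_model(model: StructureModel, num: int) -> gemmi.Model:
    gmodel = gemmi.Model(str(num))
    for dom, residues in model.domains().items():
        chain = gemmi.Chain(dom)
        for r in residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_index, " ")
            gres.het_flag = "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                gres.add_atom(ga)
            chain.add_residue(gres)
        gmodel.add_chain(chain)
    return gmodel


def write_pdb(model: StructureModel | Trajectory, path: str | Path) -> None:
    """Write a model or trajectory as standard PDB (MODEL/ENDMDL for frames)."""
    frames = model.frames if isinstance(model, Trajectory) else [model]
    if not frames or not frames[0].residues:
        raise PDBFormatError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = frames[0].model_id
    for i, frame in enumerate(frames):
        st.add_model(_to_gemmi_model(frame, i + 1))
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------


def residue_min_distance(a: Residue, b: Residue, heavy_only: bool = True) -> float:
    """Shortest atom–atom distance between two residues (Å).

    This is the residue–residue distance definition used throughout:
    the minimum pairwise Euclidean distance over (by default heavy) atoms.
    """
    xa = a.atom_coords(heavy_only=heavy_only)
    xb = b.atom_coords(heavy_only=heavy_only)
    return float(cdist(xa, xb).min())


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the proper rotation R (det +1) and
    translation t such that ``mobile @ R.T + t`` best fits ``reference``
    over the corresponding points; ``rmsd`` is evaluated after the fit.

    ``correspondence`` lists (mobile_index, reference_index) pairs; identity
    correspondence is assumed when omitted (requires equal lengths).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if correspondence is None:
        if len(mobile) != len(reference):
            raise ValueError("equal point counts required without an explicit correspondence")
        P, Q = mobile, reference
    else:
        idx = np.asarray(list(correspondence), dtype=int)
        P, Q = mobile[idx[:, 0]], reference[idx[:, 1]]
    if len(P) < 3:
        raise DegenerateGeometryError("need at least 3 corresponding points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    for M in (Pc, Qc):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] <= 1e-8 * max(1.0, s[0]):
            raise DegenerateGeometryError("corresponding points are (near-)collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def coordinate_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) coordinate RMSD between equal-shaped point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
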