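"""MM-GBSA bookkeeping: per-frame components, summaries, decomposition, key residues.

The end-point binding free energy is

    ΔG_bind ≈ ΔE_gas + ΔG_sol − TΔS
            = ΔE_ele + ΔE_vdW + ΔG_GB + ΔG_surf − TΔS

averaged over trajectory frames.  The entropy term is omitted by default (the
optional ``t_ds`` field houses it when available).  Residues contributing
interaction energy strictly below −2.0 kcal/mol are flagged as key binding
residues.  All energies are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnergyComponents",
    "FrameEnergyTable",
    "FrameSummary",
    "ResidueDecomposition",
    "LigandRanking",
    "binding_energy",
    "summarize_frames",
    "key_residues",
    "rank_ligands",
    "read_frame_table",
    "write_frame_table",
    "read_decomposition",
    "write_decomposition",
]

KEY_RESIDUE_THRESHOLD = -2.0
ResKey = tuple[str, int]


@dataclass(frozen=True)
class EnergyComponents:
    """Per-frame MM-GBSA components (kcal/mol); gas/solvation sums are derived."""

    e_ele: float
    e_vdw: float
    g_gb: float
    g_surf: float
    t_ds: float | None = None

    def __post_init__(self) -> None:
        for name in ("e_ele", "e_vdw", "g_gb", "g_surf"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite component {name}")
        if self.t_ds is not None and not math.isfinite(self.t_ds):
            raise ValueError("non-finite t_ds")

    @property
    def e_gas(self) -> float:
        return self.e_ele + self.e_vdw

    @property
    def g_sol(self) -> float:
        return self.g_gb + self.g_surf

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        t_ds = None
        if self.t_ds is not None or other.t_ds is not None:
            t_ds = (self.t_ds or 0.0) + (other.t_ds or 0.0)
        return EnergyComponents(self.e_ele + other.e_ele, self.e_vdw + other.e_vdw,
                                self.g_gb + other.g_gb, self.g_surf + other.g_surf, t_ds)


def binding_energy(c: EnergyComponents) -> float:
    """ΔG_bind = ΔE_ele + ΔE_vdW + ΔG_GB + ΔG_surf − TΔS (TΔS taken as 0 if absent)."""
    return c.e_gas + c.g_sol - (c.t_ds if c.t_ds is not None else 0.0)


@dataclass
class FrameEnergyTable:
    """Ordered per-frame components at a fixed frame separation interval."""

    frames: list[EnergyComponents]
    frame_interval_ps: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("frame table needs at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def component_matrix(self) -> np.ndarray:
        return np.array([[c.e_ele, c.e_vdw, c.g_gb, c.g_surf] for c in self.frames])

    def totals(self) -> np.ndarray:
        return np.array([binding_energy(c) for c in self.frames])


@dataclass
class FrameSummary:
    """Mean ± standard error per component and for the framewise total."""

    mean: EnergyComponents
    sem: EnergyComponents | None
    total_mean: float
    total_sem: float | None
    n_frames: int


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def summarize_frames(t: FrameEnergyTable, block_size: int | None = None) -> FrameSummary:
    """Average the frame table; SEM = sample sd / √N per component and total.

    ``block_size`` switches the SEM to block averaging (SEM over means of
    consecutive blocks) as a crude guard against frame autocorrelation; the
    means are unchanged.  With a single frame the SEMs are reported absent.
    """
    mat = t.component_matrix()
    totals = t.totals()
    means = mat.mean(axis=0)
    mean_c = EnergyComponents(*means)
    total_mean = float(totals.mean())
    # linearity check: the mean of totals must equal the total of means
    assert abs(total_mean - binding_energy(mean_c)) < 1e-9 or any(
        c.t_ds is not None for c in t.frames)
    if t.n_frames < 2:
        return FrameSummary(mean_c, None, total_mean, None, t.n_frames)
    if block_size is not None:
        if block_size < 1 or block_size > t.n_frames // 2:
            raise ValueError("block_size must allow at least 2 blocks")
        n_blocks = t.n_frames // block_size
        trimmed = mat[: n_blocks * block_size].reshape(n_blocks, block_size, 4).mean(axis=1)
        trimmed_tot = totals[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
        sems = np.apply_along_axis(_sem, 0, trimmed)
        total_sem = _sem(trimmed_tot)
    else:
        sems = np.apply_along_axis(_sem, 0, mat)
        total_sem = _sem(totals)
    return FrameSummary(mean_c, EnergyComponents(*sems), total_mean, total_sem, t.n_frames)


@dataclass
class ResidueDecomposition:
    """Per-residue interaction energies from an MM-GBSA decomposition."""

    records: dict[ResKey, float]

    def __post_init__(self) -> None:
        for key, val in self.records.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite decomposition energy for {key}")


def key_residues(d: ResidueDecomposition, threshold: float = KEY_RESIDUE_THRESHOLD
                 ) -> list[tuple[ResKey, float]]:
    """Residues with interaction energy strictly below the threshold, most favourable first."""
    hits = [(k, v) for k, v in d.records.items() if v < threshold]
    return sorted(hits, key=lambda kv: (kv[1], kv[0]))


@dataclass
class LigandRanking:
    """Ligands ordered most→least tightly bound (ascending total binding energy)."""

    order: tuple[str, ...]
    tied: bool


def rank_ligands(totals: Mapping[str, float]) -> LigandRanking:
    if len(totals) < 2:
        raise ValueError("ranking needs at least 2 ligands")
    items = sorted(totals.items(), key=lambda kv: (kv[1], kv[0]))
    values = [v for _, v in items]
    tied = any(a == b for a, b in zip(values, values[1:]))
    return LigandRanking(tuple(k for k, _ in items), tied)


# ---------------------------------------------------------------------------
# TSV I/O (MMPBSA-style per-frame dumps and decomposition tables)
# ---------------------------------------------------------------------------

_FRAME_COLUMNS = ["frame_index", "e_ele", "e_vdw", "g_gb", "g_surf"]


def write_frame_table(t: FrameEnergyTable, path: str | Path) -> None:
    has_tds = any(c.t_ds is not None for c in t.frames)
    rows = []
    for i, c in enumerate(t.frames):
        row = {"frame_index": i, "e_ele": c.e_ele, "e_vdw": c.e_vdw,
               "g_gb": c.g_gb, "g_surf": c.g_surf}
        if has_tds:
            row["t_ds"] = c.t_ds if c.t_ds is not None else 0.0
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_frame_table(path: str | Path, frame_interval_ps: float = 1.0) -> FrameEnergyTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frames = [
        EnergyComponents(r.e_ele, r.e_vdw, r.g_gb, r.g_surf,
                         getattr(r, "t_ds", None))
        for r in df.itertuples(index=False)
    ]
    return FrameEnergyTable(frames, frame_interval_ps)


def write_decomposition(d: ResidueDecomposition, path: str | Path,
                        resnames: Mapping[ResKey, str] | None = None) -> None:
    rows = [
        {"domain": dom, "resindex": idx,
         "resname": (resnames or {}).get((dom, idx), "UNK"), "energy": val}
        for (dom, idx), val in sorted(d.records.items())
    ]
    pd.DataFrame(rows, columns=["domain", "resindex", "resname", "energy"]).to_csv(
        path, sep="\t", index=False)


def read_decomposition(path: str | Path) -> ResidueDecomposition:
    df = pd.read_csv(path, sep="\t")
    records = {(str(r.domain), int(r.resindex)): float(r.energy)
               for r in df.itertuples(index=False)}
    return ResidueDecomposition(records)
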