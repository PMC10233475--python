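"""Candidate ranking, top-k selection, tetramer assembly and assembly ranking.

Candidate domain models arrive with an external energy (Rosetta-style, lower
is better).  Each candidate is scored against the domain's EC set; selection
favours low energy *and* high contact precision.  The field's informal rule
"lowest energy and highest prediction consistency" is operationalised as
Pareto-front selection ordered by energy (a pure-energy mode is available).

Selected domain models are assembled into pore-domain tetramers by rigid
superposition of each member onto the corresponding template domain, matching
Cα atoms by domain-local residue number.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .contact_analysis import (
    ContactEvalResult,
    ECSet,
    Scope,
    compute_contact_map,
    evaluate_predictions,
)
from .errors import ConfigurationError
from .structure_model import Residue, StructureModel, kabsch_superpose

__all__ = [
    "CandidateModel",
    "ScoredCandidate",
    "AssemblyModel",
    "AssemblyRanking",
    "score_candidates",
    "select_top",
    "assemble_pd",
    "rank_assemblies",
]


@dataclass
class CandidateModel:
    """A single-domain candidate structure with an externally computed energy."""

    model_id: str
    domain_id: str
    structure: StructureModel
    energy: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"candidate {self.model_id!r}: non-finite energy")

    @property
    def short_id(self) -> str:
        """Trailing token of the model id (the conventional 4-digit decoy tag)."""
        return self.model_id.rsplit("_", 1)[-1]


@dataclass
class ScoredCandidate:
    candidate: CandidateModel
    eval: ContactEvalResult

    @property
    def energy(self) -> float:
        return self.candidate.energy

    @property
    def precision(self) -> float:
        return self.eval.precision_pct


@dataclass
class AssemblyModel:
    """A four-domain pore-domain assembly built from selected candidates."""

    assembly_id: str
    structure: StructureModel
    members: dict[str, CandidateModel] = field(default_factory=dict)
    energy: float | None = None
    inter_eval: ContactEvalResult | None = None


def score_candidates(
    candidates: Sequence[CandidateModel],
    ec: ECSet,
    cutoff: float = 8.0,
    threshold: float = 0.2,
    min_seq_sep: int = 0,
) -> list[ScoredCandidate]:
    """Evaluate every candidate's own contact map against the domain EC set."""
    if ec.scope.kind != "intra":
        raise ConfigurationError("score_candidates needs an intra-domain EC set")
    dom = ec.scope.domains[0]
    out = []
    for cand in candidates:
        if cand.domain_id != dom:
            raise ConfigurationError(
                f"candidate {cand.model_id!r} is domain {cand.domain_id!r}, EC set is {dom!r}")
        cmap = compute_contact_map(cand.structure, ec.scope, cutoff=cutoff,
                                   min_seq_sep=min_seq_sep)
        out.append(ScoredCandidate(cand, evaluate_predictions(ec, cmap, threshold=threshold)))
    return out


def _dominates(a: ScoredCandidate, b: ScoredCandidate) -> bool:
    pa = -math.inf if math.isnan(a.precision) else a.precision
    pb = -math.inf if math.isnan(b.precision) else b.precision
    return (a.energy <= b.energy and pa >= pb) and (a.energy < b.energy or pa > pb)


def _front_key(s: ScoredCandidate):
    p = -math.inf if math.isnan(s.precision) else s.precision
    return (s.energy, -p, s.candidate.model_id)


def select_top(scored: Sequence[ScoredCandidate], k: int = 2,
               mode: str = "pareto") -> list[ScoredCandidate]:
    """Select the k best candidates.

    ``pareto`` mode peels successive Pareto fronts of (minimise energy,
    maximise precision), ordering each front by energy ascending with ties
    broken by precision descending then model id; ``energy`` mode sorts purely
    by energy.  Idempotent: selecting k from the selected k returns the same set.
    """
    if len(scored) < k:
        raise ConfigurationError(f"need at least {k} candidates, got {len(scored)}")
    if mode == "energy":
        return sorted(scored, key=_front_key)[:k]
    if mode != "pareto":
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    remaining = list(scored)
    ranked: list[ScoredCandidate] = []
    while remaining:
        front = [s for s in remaining
                 if not any(_dominates(o, s) for o in remaining if o is not s)]
        if not front:  # identical duplicates dominating each other mutually
            front = remaining
        ranked.extend(sorted(front, key=_front_key))
        remaining = [s for s in remaining if s not in front]
    return ranked[:k]


def _calpha_by_index(residues: Sequence[Residue]) -> dict[int, np.ndarray]:
    out = {}
    for r in residues:
        for a in r.atoms:
            if a.name == "CA":
                out[r.seq_index] = a.coords
                break
    return out


def assemble_pd(
    selected: Mapping[str, Sequence[CandidateModel]],
    template: StructureModel,
) -> list[AssemblyModel]:
    """Assemble all combinations of selected domain models on the template.

    Each member is rigidly superposed (Kabsch) onto the corresponding template
    domain over Cα atoms matched by domain-local residue number; unmatched
    residues are excluded from the fit but kept in the output.  The assembly
    id concatenates the member short ids in domain order.
    """
    template_domains = template.domains()
    domain_order = [d for d in template_domains if d in selected]
    missing = set(selected) - set(template_domains)
    if missing:
        raise ConfigurationError(f"template lacks domains {sorted(missing)}")
    if set(domain_order) != set(selected):
        raise ConfigurationError("selection/template domain mismatch")

    assemblies = []
    for combo in itertools.product(*(selected[d] for d in domain_order)):
        residues: list[Residue] = []
        for dom, cand in zip(domain_order, combo):
            t_ca = _calpha_by_index(template_domains[dom])
            c_ca = _calpha_by_index(cand.structure.residues)
            common = sorted(set(t_ca) & set(c_ca))
            if len(common) < 3:
                raise ConfigurationError(
                    f"candidate {cand.model_id!r}: fewer than 3 Cα matches to template {dom!r}")
            mob = np.array([c_ca[i] for i in common])
            ref = np.array([t_ca[i] for i in common])
            R, t, _ = kabsch_superpose(mob, ref)
            placed = cand.structure.transformed(R, t)
            for r in placed.residues:
                residues.append(Residue(dom, r.seq_index, r.name, r.atoms))
        assembly_id = "_".join(c.short_id for c in combo)
        structure = StructureModel(assembly_id, residues)
        assemblies.append(AssemblyModel(assembly_id, structure,
                                        dict(zip(domain_order, combo))))
    return assemblies


@dataclass
class AssemblyRanking:
    """Energy-ordered assemblies with the selected best flagged."""

    ordered: list[AssemblyModel]
    best: AssemblyModel
    energy_precision_consistent: bool  # best-by-energy also maximises precision


def rank_assemblies(
    assemblies: Sequence[AssemblyModel],
    energies: Mapping[str, float],
    inter_ec: ECSet,
    cutoff: float = 8.0,
    threshold: float = 0.2,
) -> AssemblyRanking:
    """Attach inter-domain contact evaluations and rank assemblies by energy.

    Ties in energy are broken by precision descending then assembly id.  The
    best assembly is the lowest-energy one; the ranking records whether it
    also maximises inter-domain precision (the energy/precision consistency check).
    """
    evaluated = []
    for asm in assemblies:
        if asm.assembly_id not in energies:
            raise ConfigurationError(f"no energy for assembly {asm.assembly_id!r}")
        cmap = compute_contact_map(asm.structure, inter_ec.scope, cutoff=cutoff)
        ev = evaluate_predictions(inter_ec, cmap, threshold=threshold)
        evaluated.append(replace(asm, energy=float(energies[asm.assembly_id]), inter_eval=ev))

    def sort_key(a: AssemblyModel):
        p = a.inter_eval.precision_pct
        return (a.energy, -(-math.inf if math.isnan(p) else p), a.assembly_id)

    ordered = sorted(evaluated, key=sort_key)
    best = ordered[0]
    precisions = [a.inter_eval.precision_pct for a in evaluated]
    finite = [p for p in precisions if not math.isnan(p)]
    consistent = bool(finite) and not math.isnan(best.inter_eval.precision_pct) \
        and best.inter_eval.precision_pct >= max(finite) - 1e-12
    return AssemblyRanking(ordered, best, consistent)
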