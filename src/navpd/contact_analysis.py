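"""Structural contact maps and evaluation of evolutionary-coupling predictions.

A residue pair is *in contact* when the minimum heavy-atom distance between
the two residues is strictly below the cutoff (default 8 Å).  Co-evolution
analysis assigns each pair an EC score; pairs scoring strictly above the
threshold (default 0.2) are *predicted* contacts.  Prediction quality is
summarised per scope (one domain, or a pair / all pairs of domains) by:

=========  ==========================================================
CA_Str     number of contact pairs in the structure
CA_DCA     number of predicted pairs
N_Coin     predicted pairs that are real contacts
N/DCA      precision, 100·N_Coin/CA_DCA (%)
N_T10      hits among the ten highest-scoring predictions
=========  ==========================================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, ECTableFormatError, MissingResidueError
from .structure_model import StructureModel, residue_min_distance

__all__ = [
    "Scope",
    "ContactMap",
    "ECRecord",
    "ECSet",
    "ContactEvalResult",
    "compute_contact_map",
    "parse_ec_table",
    "write_ec_table",
    "predict_contacts",
    "evaluate_predictions",
    "canonical_pair",
]

ResKey = tuple[str, int]
Pair = tuple[ResKey, ResKey]

DEFAULT_CONTACT_CUTOFF = 8.0
DEFAULT_EC_THRESHOLD = 0.2


def canonical_pair(a: ResKey, b: ResKey) -> Pair:
    """Order-independent residue-pair key (sorted by domain then index)."""
    if a == b:
        raise ValueError(f"self-pair {a}")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Scope:
    """Which residue pairs an EC set or contact map covers.

    ``intra`` scopes cover pairs within one domain; ``inter`` scopes cover
    pairs between two given domains (unordered) or, with no domains given,
    between any two distinct domains.
    """

    kind: str  # "intra" | "inter"
    domains: tuple[str, ...] = ()

    @classmethod
    def intra(cls, domain_id: str) -> "Scope":
        return cls("intra", (domain_id,))

    @classmethod
    def inter(cls, a: str | None = None, b: str | None = None) -> "Scope":
        if a is None and b is None:
            return cls("inter", ())
        if a is None or b is None or a == b:
            raise ValueError("inter scope needs two distinct domains (or none for all pairs)")
        return cls("inter", tuple(sorted((a, b))))

    def label(self) -> str:
        if self.kind == "intra":
            return f"intra:{self.domains[0]}"
        return "inter:" + ("*" if not self.domains else "-".join(self.domains))

    def admits(self, pair: Pair) -> bool:
        (da, _), (db, _) = pair
        if self.kind == "intra":
            return da == db == self.domains[0]
        if da == db:
            return False
        return not self.domains or tuple(sorted((da, db))) == self.domains


@dataclass(frozen=True)
class ContactMap:
    """Set of residue pairs in structural contact under a distance cutoff."""

    scope: Scope
    pairs: frozenset
    cutoff: float = DEFAULT_CONTACT_CUTOFF

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.pairs


def compute_contact_map(
    model: StructureModel,
    scope: Scope,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_seq_sep: int = 0,
    heavy_only: bool = True,
) -> ContactMap:
    """Contact map of ``model`` over ``scope``: pairs with min atom distance < cutoff.

    ``min_seq_sep`` (intra scopes only) drops pairs with ``|i - j| < min_seq_sep``;
    the default 0 keeps sequence-adjacent pairs.
    """
    domains = model.domains()
    pairs: set[Pair] = set()
    if scope.kind == "intra":
        dom = scope.domains[0]
        if dom not in domains:
            raise MissingResidueError(f"domain {dom!r} not in model {model.model_id!r}")
        residues = domains[dom]
        for i, ra in enumerate(residues):
            for rb in residues[i + 1:]:
                if abs(ra.seq_index - rb.seq_index) < min_seq_sep:
                    continue
                if residue_min_distance(ra, rb, heavy_only=heavy_only) < cutoff:
                    pairs.add(canonical_pair(ra.key, rb.key))
    else:
        if scope.domains:
            for dom in scope.domains:
                if dom not in domains:
                    raise MissingResidueError(f"domain {dom!r} not in model {model.model_id!r}")
            groups = [(scope.domains[0], scope.domains[1])]
        else:
            ids = list(domains)
            groups = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        for da, db in groups:
            for ra in domains[da]:
                for rb in domains[db]:
                    if residue_min_distance(ra, rb, heavy_only=heavy_only) < cutoff:
                        pairs.add(canonical_pair(ra.key, rb.key))
    return ContactMap(scope, frozenset(pairs), cutoff)


@dataclass(frozen=True)
class ECRecord:
    res_i: ResKey
    res_j: ResKey
    score: float

    def pair(self) -> Pair:
        return canonical_pair(self.res_i, self.res_j)


@dataclass
class ECSet:
    """Scored residue pairs; duplicate pairs collapse keeping the max score."""

    records: list[ECRecord]
    scope: Scope

    def __post_init__(self) -> None:
        scores: dict[Pair, float] = {}
        for rec in self.records:
            if not math.isfinite(rec.score):
                raise ValueError(f"non-finite EC score for pair {rec.pair()}")
            p = rec.pair()
            if p not in scores or rec.score > scores[p]:
                scores[p] = rec.score
        self._scores = scores
        self.records = [ECRecord(p[0], p[1], s) for p, s in sorted(scores.items())]

    def __len__(self) -> int:
        return len(self._scores)

    def scores(self) -> dict[Pair, float]:
        return dict(self._scores)

    def top_records(self, k: int) -> list[ECRecord]:
        """The k highest-scoring records, ties broken by pair lexicographic order."""
        ordered = sorted(self.records, key=lambda r: (-r.score, r.pair()))
        return ordered[:k]


_EC_COLUMNS = ["domain_i", "index_i", "domain_j", "index_j", "score"]


def parse_ec_table(path: str | Path, scope: Scope) -> ECSet:
    """Read a tab-separated EC-score table (header + the five standard columns)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ECTableFormatError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in _EC_COLUMNS if c not in df.columns]
    if missing:
        raise ECTableFormatError(f"{path}: missing columns {missing}")
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            res_i = (str(row.domain_i), int(row.index_i))
            res_j = (str(row.domain_j), int(row.index_j))
            score = float(row.score)
            records.append(ECRecord(res_i, res_j, score))
        except (TypeError, ValueError) as exc:
            raise ECTableFormatError(f"{path}: malformed row {row_number}: {exc}") from exc
    return ECSet(records, scope)


def write_ec_table(ec: ECSet, path: str | Path) -> None:
    rows = [
        {"domain_i": r.res_i[0], "index_i": r.res_i[1],
         "domain_j": r.res_j[0], "index_j": r.res_j[1], "score": r.score}
        for r in ec.records
    ]
    pd.DataFrame(rows, columns=_EC_COLUMNS).to_csv(path, sep="\t", index=False)


def predict_contacts(ec: ECSet, threshold: float = DEFAULT_EC_THRESHOLD) -> frozenset:
    """Pairs whose EC score is strictly above the threshold."""
    return frozenset(p for p, s in ec.scores().items() if s > threshold)


@dataclass(frozen=True)
class ContactEvalResult:
    """One evaluation row: structural/predicted/coincident counts, precision, top-10 hits."""

    ca_str: int
    ca_dca: int
    n_coin: int
    precision_pct: float
    n_t10: int

    def __post_init__(self) -> None:
        if self.n_coin > min(self.ca_str, self.ca_dca):
            raise ValueError("n_coin cannot exceed min(ca_str, ca_dca)")
        if self.n_t10 > 10:
            raise ValueError("n_t10 cannot exceed 10")

    @classmethod
    def from_counts(cls, ca_str: int, ca_dca: int, n_coin: int, n_t10: int = 0
                    ) -> "ContactEvalResult":
        """Build a row from externally tabulated counts, recomputing the precision."""
        if ca_dca > 0:
            precision = 100.0 * n_coin / ca_dca
        else:
            warnings.warn("ca_dca is 0: precision undefined (NaN)")
            precision = float("nan")
        return cls(ca_str, ca_dca, n_coin, precision, n_t10)


def evaluate_predictions(
    ec: ECSet,
    cmap: ContactMap,
    threshold: float = DEFAULT_EC_THRESHOLD,
    k_top: int = 10,
) -> ContactEvalResult:
    """Score EC predictions against a structural contact map (same scope)."""
    if ec.scope != cmap.scope:
        raise ConfigurationError(
            f"scope mismatch: EC set is {ec.scope.label()}, contact map is {cmap.scope.label()}")
    predicted = predict_contacts(ec, threshold)
    n_coin = len(predicted & cmap.pairs)
    n_t10 = sum(1 for r in ec.top_records(k_top) if r.pair() in cmap.pairs)
    if predicted:
        precision = 100.0 * n_coin / len(predicted)
    else:
        warnings.warn(f"no predicted contacts at threshold {threshold}: precision undefined")
        precision = float("nan")
    return ContactEvalResult(cmap.n_pairs, len(predicted), n_coin, precision, n_t10)
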