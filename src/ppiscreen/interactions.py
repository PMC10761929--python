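"""Publication-weighted scoring of protein-protein interaction evidence.

Interaction databases aggregate evidence rows of the form (protein A,
protein B, publication).  A single high-throughput screen can contribute
thousands of rows, so counting publications naively over-weights screens
relative to focused studies.  Here each publication receives weight
``1/sqrt(n)`` where ``n`` is the number of distinct interactions it
reports, and a pair's evidence score is the sum of the weights of its
distinct supporting publications.  Pairs scoring at or above a threshold
(default 0.3) are selected as candidates: a pair supported only by a
single publication reporting 11 interactions still qualifies
(1/sqrt(11) ~ 0.3015), one reporting 12 does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "DriverGene",
    "InteractionRecord",
    "PublicationWeight",
    "ScoredPair",
    "load_interaction_table",
    "load_driver_table",
    "publication_weights",
    "score_pairs",
    "filter_driver_pairs",
    "write_scored_pairs",
]

DRIVER_ROLES = frozenset({"oncogene", "tumor_suppressor", "unclassified"})
DRIVER_SOURCES = frozenset({"NCG_canonical", "NCG_candidate", "OncoVar"})

_BIOGRID_COL_A = "Official Symbol Interactor A"
_BIOGRID_COL_B = "Official Symbol Interactor B"
_BIOGRID_COL_PUB = "Publication Source"


@dataclass(frozen=True)
class DriverGene:
    """A cancer driver gene with its functional annotation."""

    symbol: str
    category: str = ""
    role: str = "unclassified"
    source: str = "NCG_canonical"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("driver symbol must be non-empty")
        if self.role not in DRIVER_ROLES:
            raise ValueError(f"unknown driver role {self.role!r}")
        if self.source not in DRIVER_SOURCES:
            raise ValueError(f"unknown driver source {self.source!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """One pair-publication evidence row, with the pair canonicalized."""

    protein_a: str
    protein_b: str
    pmid: str

    def __post_init__(self) -> None:
        if not (self.protein_a and self.protein_b and self.pmid):
            raise ValueError("protein symbols and pmid must be non-empty")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass(frozen=True)
class PublicationWeight:
    """Evidence weight of one publication: 1/sqrt(#interactions it reports)."""

    pmid: str
    n_interactions: int
    weight: float

    def __post_init__(self) -> None:
        if self.n_interactions < 1:
            raise ValueError("n_interactions must be positive")


@dataclass
class ScoredPair:
    """A protein pair with its summed publication-weight evidence score."""

    protein_a: str
    protein_b: str
    score: float
    supporting_pmids: frozenset[str] = field(default_factory=frozenset)
    is_candidate: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b


def _parse_pmid(value: str) -> str:
    value = str(value).strip()
    if value.upper().startswith("PUBMED:"):
        return value.split(":", 1)[1]
    return value


def load_interaction_table(path: str | Path, dialect: str = "simple_tsv") -> list[InteractionRecord]:
    """Read an interaction table into deduplicated evidence records.

    Parameters
    ----------
    path
        Tab-delimited file.  For ``dialect="simple_tsv"`` columns
        ``protein_a``, ``protein_b``, ``pmid`` are required; for
        ``dialect="biogrid_tab3"`` the official-symbol interactor columns
        and the publication-source column are used (PUBMED: prefixes are
        stripped).
    dialect
        ``"simple_tsv"`` or ``"biogrid_tab3"``.

    Returns one record per distinct (canonical pair, pmid) combination.
    """
    path = Path(path)
    if dialect == "simple_tsv":
        cols = {"a": "protein_a", "b": "protein_b", "pub": "pmid"}
    elif dialect == "biogrid_tab3":
        cols = {"a": _BIOGRID_COL_A, "b": _BIOGRID_COL_B, "pub": _BIOGRID_COL_PUB}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    seen: set[InteractionRecord] = set()
    records: list[InteractionRecord] = []
    for a, b, pub in zip(df[cols["a"]], df[cols["b"]], df[cols["pub"]]):
        rec = InteractionRecord(str(a).strip(), str(b).strip(), _parse_pmid(pub))
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    return records


def load_driver_table(path: str | Path) -> list[DriverGene]:
    """Read a driver catalog TSV with columns symbol, category, role, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "symbol" not in df.columns:
        raise ValueError(f"{path}: missing required column(s) ['symbol']")
    drivers = []
    for row in df.itertuples(index=False):
        drivers.append(
            DriverGene(
                symbol=str(row.symbol),
                category=str(getattr(row, "category", "")),
                role=str(getattr(row, "role", "unclassified")),
                source=str(getattr(row, "source", "NCG_canonical")),
            )
        )
    return drivers


def publication_weights(records: list[InteractionRecord]) -> dict[str, PublicationWeight]:
    """Weight each publication by the reciprocal square root of the number
    of distinct interactions it supports."""
    pairs_per_pmid: dict[str, set[tuple[str, str]]] = {}
    for rec in records:
        pairs_per_pmid.setdefault(rec.pmid, set()).add(rec.pair)
    return {
        pmid: PublicationWeight(pmid, len(pairs), 1.0 / math.sqrt(len(pairs)))
        for pmid, pairs in pairs_per_pmid.items()
    }


def score_pairs(
    records: list[InteractionRecord],
    threshold: float = 0.3,
    include_self: bool = True,
) -> list[ScoredPair]:
    """Score every pair as the sum of its distinct supporting-publication
    weights and flag candidates scoring >= ``threshold``.

    Output is sorted score-descending with ties broken by canonical pair
    name, so rankings are reproducible.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    weights = publication_weights(records)
    pmids_per_pair: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        if not include_self and rec.is_self:
            continue
        pmids_per_pair.setdefault(rec.pair, set()).add(rec.pmid)

    scored = []
    for pair, pmids in pmids_per_pair.items():
        score = sum(weights[p].weight for p in pmids)
        scored.append(
            ScoredPair(
                protein_a=pair[0],
                protein_b=pair[1],
                score=score,
                supporting_pmids=frozenset(pmids),
                is_candidate=score >= threshold,
            )
        )
    scored.sort(key=lambda sp: (-sp.score, sp.pair))
    return scored


def filter_driver_pairs(pairs: list[ScoredPair], drivers: list[DriverGene]) -> list[ScoredPair]:
    """Retain pairs in which at least one member is a driver gene."""
    if not drivers:
        raise ValueError("driver catalog must be non-empty")
    symbols = {d.symbol for d in drivers}
    return [p for p in pairs if p.protein_a in symbols or p.protein_b in symbols]


def write_scored_pairs(pairs: list[ScoredPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "protein_a": [p.protein_a for p in pairs],
            "protein_b": [p.protein_b for p in pairs],
            "score": [p.score for p in pairs],
            "n_pmids": [len(p.supporting_pmids) for p in pairs],
            "is_candidate": [p.is_candidate for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)
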