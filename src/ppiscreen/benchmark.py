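"""Top-k ranking benchmarks for competing PPI prediction methods.

Each method ranks the same candidate pairs by its own confidence metric
(contact probability, interface score, pDockQ, ...).  Performance is
summarized as the cumulative number of reference-supported pairs (for
example, pairs with experimentally determined complex structures) among
the top k predictions, and agreement between three methods as the seven
Venn regions of their top-k sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RankedPrediction",
    "ReferenceSet",
    "rank_predictions",
    "supported_at_rank",
    "topk_overlap",
    "load_score_table",
    "load_reference_set",
    "DEFAULT_K_VALUES",
]

DEFAULT_K_VALUES = (50, 100, 200, 1000)


@dataclass(frozen=True)
class RankedPrediction:
    pair: str  # canonical pair identifier
    method: str
    score: float
    rank: int


@dataclass(frozen=True)
class ReferenceSet:
    """Canonical pair identifiers supported by independent evidence."""

    supported_pairs: frozenset[str]


def canonical_pair_id(a: str, b: str) -> str:
    return "--".join(sorted((a, b)))


def rank_predictions(scores: list[tuple[str, float]], method: str) -> list[RankedPrediction]:
    """Sort score-descending with ties broken by canonical pair name and
    assign ranks 1..N."""
    pairs = [p for p, _ in scores]
    if len(pairs) != len(set(pairs)):
        raise ValueError(f"duplicate pair within method {method!r}")
    for p, s in scores:
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for pair {p!r}")
    ordered = sorted(scores, key=lambda ps: (-ps[1], ps[0]))
    return [
        RankedPrediction(pair=p, method=method, score=s, rank=i + 1)
        for i, (p, s) in enumerate(ordered)
    ]


def supported_at_rank(
    ranked: list[RankedPrediction], ref: ReferenceSet, k_max: int
) -> list[tuple[int, int]]:
    """Cumulative count of reference-supported pairs among the top k, for
    k = 1..k_max."""
    if k_max > len(ranked):
        raise ValueError(f"k_max={k_max} exceeds ranking length {len(ranked)}")
    ordered = sorted(ranked, key=lambda r: r.rank)
    curve = []
    count = 0
    for k, pred in enumerate(ordered[:k_max], start=1):
        if pred.pair in ref.supported_pairs:
            count += 1
        curve.append((k, count))
    return curve


def topk_overlap(
    rankings: list[list[RankedPrediction]], k: int
) -> dict[str, int]:
    """Seven-region Venn counts of three methods' top-k sets.

    Region keys name the methods sharing the pairs, joined by "&"
    (e.g. "A", "A&B", "A&B&C" for methods labelled A, B, C).  For each
    method its four regions sum to k.
    """
    if len(rankings) != 3:
        raise ValueError("exactly three rankings are required")
    names = []
    tops = []
    for ranking in rankings:
        if len(ranking) < k:
            raise ValueError("every ranking must have at least k entries")
        names.append(ranking[0].method)
        tops.append({r.pair for r in ranking if r.rank <= k})
    a, b, c = tops
    na, nb, nc = names
    return {
        na: len(a - b - c),
        nb: len(b - a - c),
        nc: len(c - a - b),
        f"{na}&{nb}": len((a & b) - c),
        f"{na}&{nc}": len((a & c) - b),
        f"{nb}&{nc}": len((b & c) - a),
        f"{na}&{nb}&{nc}": len(a & b & c),
    }


def load_score_table(path: str | Path, method: str | None = None) -> list[RankedPrediction]:
    """Read a per-method score TSV (pair, score[, method]) and rank it."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("pair", "score") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if method is None:
        method = str(df["method"].iloc[0]) if "method" in df.columns else Path(path).stem
    return rank_predictions(
        [(str(p), float(s)) for p, s in zip(df["pair"], df["score"])], method
    )


def load_reference_set(path: str | Path) -> ReferenceSet:
    """Read a reference-set TSV with a ``pair`` column."""
    df = pd.read_csv(path, sep="\t")
    if "pair" not in df.columns:
        raise ValueError(f"{path}: missing required column(s) ['pair']")
    return ReferenceSet(supported_pairs=frozenset(str(p) for p in df["pair"]))
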