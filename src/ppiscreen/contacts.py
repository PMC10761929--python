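"""Distogram-based contact-probability scoring of protein pairs (AF-contact).

A structure-prediction network emits, for every residue pair, logits over
64 equal-width Cbeta-Cbeta distance bins spanning 2-22 A (bin width
0.3125 A).  The contact probability of a residue pair is the softmax mass
in the first 32 bins, i.e. distances between 2 and 12 A.  For a two-chain
input of lengths L1 and L2 the contact matrix m is (L1+L2) x (L1+L2); the
inter-protein submatrix m' = m[0:L1, L1:L1+L2] holds the cross-chain
entries, and its maximum is the pair's contact probability.  Pairs with
score strictly above 0.9 are called high-confidence.  Large proteins are
modelled as domain pairs; the protein-level score is the maximum over its
domain-pair scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import softmax

__all__ = [
    "N_BINS",
    "N_CONTACT_BINS",
    "BIN_MIN_ANGSTROM",
    "BIN_MAX_ANGSTROM",
    "bin_edges",
    "Distogram",
    "ContactMatrix",
    "PairScore",
    "softmax_bins",
    "contact_probability",
    "interchain_block",
    "pair_score",
    "aggregate_domain_pairs",
    "load_distogram",
    "score_distogram",
]

N_BINS = 64
N_CONTACT_BINS = 32
BIN_MIN_ANGSTROM = 2.0
BIN_MAX_ANGSTROM = 22.0


def bin_edges() -> np.ndarray:
    """The 65 edges of the 64 equal distance bins from 2 to 22 A.

    The upper edge of bin 32 is exactly 12 A, so the first 32 bins cover
    the 2-12 A contact range.
    """
    return np.linspace(BIN_MIN_ANGSTROM, BIN_MAX_ANGSTROM, N_BINS + 1)


@dataclass
class Distogram:
    """Per-residue-pair distance-bin logits for a two-chain input."""

    logits: np.ndarray  # (L, L, 64)
    L1: int
    L2: int

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.logits.ndim != 3 or self.logits.shape[2] != N_BINS:
            raise ValueError(f"logits must be (L, L, {N_BINS}), got {self.logits.shape}")
        L = self.logits.shape[0]
        if self.logits.shape[1] != L or self.L1 + self.L2 != L:
            raise ValueError("L1 + L2 must equal both leading logit dimensions")
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValueError("chain lengths must be positive")


@dataclass
class ContactMatrix:
    """Residue-residue contact probabilities (mass in the 2-12 A bins)."""

    probs: np.ndarray  # (L, L)
    L1: int
    L2: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValueError("chain lengths must be positive")
        if self.L1 + self.L2 != self.probs.shape[0]:
            raise ValueError("L1 + L2 must equal matrix dimension")


@dataclass
class PairScore:
    """Contact-probability score for one (domain) pair of chains."""

    pair_id: str
    score: float
    argmax: tuple[int, int]  # 1-based residue indices, per-chain numbering
    is_high_confidence: bool
    n_qualifying_domain_pairs: int = 0


def softmax_bins(logits: np.ndarray) -> np.ndarray:
    """Normalize distance-bin logits to probabilities along the last axis."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return softmax(logits, axis=-1)


def contact_probability(probs: np.ndarray, L1: int, L2: int) -> ContactMatrix:
    """Sum the first 32 bin probabilities (2-12 A) per residue pair."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 3 or probs.shape[2] != N_BINS:
        raise ValueError(f"expected (L, L, {N_BINS}) bin probabilities, got {probs.shape}")
    return ContactMatrix(probs[:, :, :N_CONTACT_BINS].sum(axis=2), L1=L1, L2=L2)


def interchain_block(m: ContactMatrix) -> np.ndarray:
    """Extract the (L1, L2) inter-protein submatrix m'."""
    return m.probs[: m.L1, m.L1 :]


def pair_score(block: np.ndarray, pair_id: str = "", threshold: float = 0.9) -> PairScore:
    """Score a pair by the maximum entry of its inter-chain block.

    High confidence requires score strictly greater than ``threshold``.
    The argmax is reported 1-based in per-chain numbering; ties resolve to
    the first (row-major) maximal entry.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.size == 0:
        raise ValueError("inter-chain block must be non-empty")
    if block.min() < 0 or block.max() > 1 + 1e-9:
        raise ValueError("contact probabilities must lie in [0, 1]")
    flat = int(np.argmax(block))
    i, j = np.unravel_index(flat, block.shape)
    score = float(block[i, j])
    return PairScore(
        pair_id=pair_id,
        score=score,
        argmax=(int(i) + 1, int(j) + 1),
        is_high_confidence=score > threshold,
    )


def aggregate_domain_pairs(domain_scores: list[PairScore], threshold: float = 0.9) -> PairScore:
    """Protein-level score: the max over domain-pair scores, with a count
    of domain pairs individually exceeding the confidence gate."""
    if not domain_scores:
        raise ValueError("at least one domain-pair score is required")
    best = max(domain_scores, key=lambda s: s.score)
    n_qual = sum(1 for s in domain_scores if s.score > threshold)
    return PairScore(
        pair_id=best.pair_id,
        score=best.score,
        argmax=best.argmax,
        is_high_confidence=best.score > threshold,
        n_qualifying_domain_pairs=n_qual,
    )


# ---------------------------------------------------------------------------
# I/O

def load_distogram(path: str | Path) -> Distogram:
    """Load a distogram from an .npz container with fields ``logits``,
    ``L1`` and ``L2``; a sidecar ``<stem>.json`` may override L1/L2."""
    path = Path(path)
    with np.load(path) as data:
        logits = data["logits"]
        L1 = int(data["L1"]) if "L1" in data else None
        L2 = int(data["L2"]) if "L2" in data else None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        L1 = int(meta.get("L1", L1))
        L2 = int(meta.get("L2", L2))
    if L1 is None or L2 is None:
        raise ValueError(f"{path}: chain lengths L1/L2 not found")
    return Distogram(logits=logits, L1=L1, L2=L2)


def score_distogram(
    dist: Distogram,
    pair_id: str = "",
    threshold: float = 0.9,
    pre_normalized: bool = False,
) -> PairScore:
    """Full scoring path: logits -> bin probabilities -> contact matrix ->
    inter-chain block -> max score."""
    probs = dist.logits if pre_normalized else softmax_bins(dist.logits)
    m = contact_probability(probs, dist.L1, dist.L2)
    return pair_score(interchain_block(m), pair_id=pair_id, threshold=threshold)
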