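"""Organism-matched joint MSA construction for protein-complex modeling.

Coevolutionary signal between two interacting proteins is only visible to
a structure-prediction network if homologous rows of the two per-protein
alignments are matched by organism.  This module selects one best ortholog
per organism per target (identity strictly above 35%, e-value <= 0.001,
highest similarity among surviving hits), removes alignment columns that
are gaps in the target, and concatenates same-organism rows into a joint
MSA.  Organisms present in only one of the two alignments are appended at
the end with the missing block replaced by gaps.  Chain-2 residues are
renumbered with a 200-residue index offset so the network treats the two
chains as separate molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "OrthologHit",
    "LabeledMSA",
    "JointMSA",
    "select_best_hits",
    "clean_target_gap_columns",
    "build_joint_msa",
    "length_gate",
    "enumerate_domain_pairs",
    "read_labeled_msa",
    "read_hit_table",
    "write_joint_msa",
]

GAP = "-"


@dataclass(frozen=True)
class OrthologHit:
    """A homology-search hit for one target protein in one organism."""

    organism: str
    sequence_id: str
    identity_pct: float
    similarity: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class LabeledMSA:
    """A per-protein alignment whose first row is the target sequence and
    whose other rows are labelled by source organism (one row each)."""

    target_row: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.target_row)
        for org, seq in self.rows:
            if len(seq) != n:
                raise ValueError(
                    f"row for organism {org!r} has length {len(seq)}, expected {n}"
                )
        organisms = [org for org, _ in self.rows]
        if len(organisms) != len(set(organisms)):
            raise ValueError("at most one row per organism")

    @property
    def alignment_length(self) -> int:
        return len(self.target_row)

    @property
    def organisms(self) -> list[str]:
        return [org for org, _ in self.rows]


@dataclass
class JointMSA:
    """Row-wise concatenation of two cleaned alignments matched by organism.

    ``rows`` holds (organism-or-tag, sequence of length L1+L2).  Paired
    rows precede unpaired rows; an unpaired row is all-gap in exactly one
    block.  ``residue_index_offset`` records the numbering gap inserted
    between the chains (chain-2 residue i is numbered L1 + offset + i).
    """

    L1: int
    L2: int
    rows: list[tuple[str, str]]
    pairing: list[str]  # per-row tag: "target" | "paired" | "msa1_only" | "msa2_only"
    residue_index_offset: int = 200

    def __post_init__(self) -> None:
        for org, seq in self.rows:
            if len(seq) != self.L1 + self.L2:
                raise ValueError(f"row {org!r} length != L1+L2")


def select_best_hits(
    hits: list[OrthologHit],
    identity_floor: float = 35.0,
    evalue_ceiling: float = 0.001,
) -> dict[str, OrthologHit]:
    """Pick, per organism, the surviving hit with the highest similarity.

    Hits with identity at or below ``identity_floor`` (strict "above 35%")
    or e-value above ``evalue_ceiling`` are excluded.  Ties in similarity
    are broken by sequence_id for determinism.
    """
    best: dict[str, OrthologHit] = {}
    for hit in hits:
        if hit.identity_pct <= identity_floor or hit.evalue > evalue_ceiling:
            continue
        cur = best.get(hit.organism)
        if cur is None or (hit.similarity, hit.sequence_id) > (cur.similarity, cur.sequence_id):
            best[hit.organism] = hit
    return best


def clean_target_gap_columns(msa: LabeledMSA) -> LabeledMSA:
    """Drop every alignment column in which the target row has a gap."""
    keep = [i for i, c in enumerate(msa.target_row) if c != GAP]
    if len(keep) == msa.alignment_length:
        return replace(msa, rows=list(msa.rows))
    return LabeledMSA(
        target_row="".join(msa.target_row[i] for i in keep),
        rows=[(org, "".join(seq[i] for i in keep)) for org, seq in msa.rows],
    )


def build_joint_msa(msa1: LabeledMSA, msa2: LabeledMSA, index_gap: int = 200) -> JointMSA:
    """Concatenate same-organism rows of two cleaned alignments.

    Row order: the target row first, then organisms found in both
    alignments (in msa1 order), then msa1-only rows gap-padded in block 2,
    then msa2-only rows gap-padded in block 1.
    """
    if GAP in msa1.target_row or GAP in msa2.target_row:
        raise ValueError("MSAs must be cleaned of target-gap columns first")
    L1, L2 = msa1.alignment_length, msa2.alignment_length
    by_org2 = dict(msa2.rows)
    set1, set2 = set(msa1.organisms), set(msa2.organisms)

    rows: list[tuple[str, str]] = [("target", msa1.target_row + msa2.target_row)]
    pairing = ["target"]
    for org, seq in msa1.rows:
        if org in by_org2:
            rows.append((org, seq + by_org2[org]))
            pairing.append("paired")
    for org, seq in msa1.rows:
        if org not in set2:
            rows.append((org, seq + GAP * L2))
            pairing.append("msa1_only")
    for org, seq in msa2.rows:
        if org not in set1:
            rows.append((org, GAP * L1 + seq))
            pairing.append("msa2_only")
    return JointMSA(L1=L1, L2=L2, rows=rows, pairing=pairing, residue_index_offset=index_gap)


def length_gate(L1: int, L2: int, limit: int = 1500) -> bool:
    """True if the combined chain length allows direct modeling; False
    signals that the proteins must be split into domains."""
    if L1 <= 0 or L2 <= 0:
        raise ValueError("chain lengths must be positive")
    return L1 + L2 <= limit


@dataclass(frozen=True)
class DomainPair:
    range1: tuple[int, int]
    range2: tuple[int, int]
    combined_length: int
    within_limit: bool


def _check_ranges(domains: list[tuple[int, int]]) -> None:
    for start, end in domains:
        if start < 1 or end < start:
            raise ValueError(f"invalid residue range ({start}, {end})")
    for i, (s1, e1) in enumerate(domains):
        for s2, e2 in domains[i + 1 :]:
            if s1 <= e2 and s2 <= e1:
                raise ValueError(f"overlapping ranges ({s1},{e1}) and ({s2},{e2})")


def enumerate_domain_pairs(
    domains1: list[tuple[int, int]],
    domains2: list[tuple[int, int]],
    limit: int = 1500,
) -> list[DomainPair]:
    """Cross product of 1-based inclusive domain ranges; each pair carries
    a flag marking whether its combined length fits under ``limit``."""
    _check_ranges(domains1)
    _check_ranges(domains2)
    out = []
    for r1 in domains1:
        for r2 in domains2:
            n = (r1[1] - r1[0] + 1) + (r2[1] - r2[0] + 1)
            out.append(DomainPair(r1, r2, n, n <= limit))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_labeled_msa(path: str | Path) -> LabeledMSA:
    """Read a FASTA/A3M alignment whose first record is the target and
    whose other headers carry an ``organism=<taxid>`` tag.

    Lowercase insertion states are uppercased; "." gaps become "-".
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty alignment")

    def norm(seq: str) -> str:
        return seq.upper().replace(".", GAP)

    target = norm(str(records[0].seq))
    rows = []
    for rec in records[1:]:
        org = None
        for token in rec.description.split():
            if token.startswith("organism="):
                org = token.split("=", 1)[1]
        if org is None:
            org = rec.id
        rows.append((org, norm(str(rec.seq))))
    return LabeledMSA(target_row=target, rows=rows)


def read_hit_table(path: str | Path) -> list[OrthologHit]:
    """Read a hit table TSV (organism, sequence_id, identity_pct,
    similarity, evalue)."""
    df = pd.read_csv(path, sep="\t")
    required = ["organism", "sequence_id", "identity_pct", "similarity", "evalue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        OrthologHit(
            organism=str(r.organism),
            sequence_id=str(r.sequence_id),
            identity_pct=float(r.identity_pct),
            similarity=float(r.similarity),
            evalue=float(r.evalue),
        )
        for r in df.itertuples(index=False)
    ]


def write_joint_msa(joint: JointMSA, prefix: str | Path, literal_gap: bool = False) -> None:
    """Write a joint alignment as FASTA plus a sidecar TSV of pairing
    status and the residue-index map.

    By default the 200-residue separation between chains is a numbering
    offset recorded in the sidecar; with ``literal_gap=True`` it is
    emitted as literal gap characters between the blocks instead.
    """
    prefix = Path(prefix)
    spacer = GAP * joint.residue_index_offset if literal_gap else ""
    with open(f"{prefix}.fasta", "w") as fh:
        for org, seq in joint.rows:
            fh.write(f">{org}\n{seq[: joint.L1]}{spacer}{seq[joint.L1 :]}\n")
    pd.DataFrame(
        {
            "row": [org for org, _ in joint.rows],
            "pairing": joint.pairing,
        }
    ).to_csv(f"{prefix}.pairing.tsv", sep="\t", index=False)
    # chain-2 residue i (1-based) is numbered L1 + offset + i downstream
    pd.DataFrame(
        {
            "chain": [1, 2],
            "length": [joint.L1, joint.L2],
            "first_residue_index": [1, joint.L1 + joint.residue_index_offset + 1],
        }
    ).to_csv(f"{prefix}.index_map.tsv", sep="\t", index=False)
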