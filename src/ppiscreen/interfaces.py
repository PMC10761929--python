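"""Inter-chain residue contacts, interface qualification and mutation mapping.

An interface between two chains of a complex structure is defined by
residue contacts: two residues from different chains are in contact when
their distance is strictly below 8 A.  By default the distance is the
minimum over all heavy-atom pairs (the common, more inclusive interface
convention); a Cbeta mode (Calpha for glycine) is available.  A chain
pair qualifies as an interface when it has at least 10 such contacts.
Somatic missense mutations, given in 1-based canonical-sequence
coordinates, are mapped onto interface residues through an explicit
per-gene (chain, numbering offset) table; disagreements between the
mutation's reference residue and the structure are flagged, never
silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Residue",
    "ComplexStructure",
    "ResidueContact",
    "InterfaceContactSet",
    "MutationRecord",
    "MutationMapping",
    "load_structure",
    "residue_contacts",
    "qualify_interfaces",
    "interface_residues",
    "map_mutations",
    "load_mutation_table",
    "load_chain_map",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1 = frozenset(AA3_TO_1.values())

# modified residues mapped to their parent, mirroring the limits of
# structure-prediction models that only handle standard residues
MODIFIED_PARENT = {
    "MSE": "MET", "HYP": "PRO", "SEP": "SER", "TPO": "THR",
    "PTR": "TYR", "MLY": "LYS", "CSO": "CYS", "KCX": "LYS",
}


@dataclass
class Residue:
    number: int
    name: str  # parent 3-letter code
    atoms: dict[str, np.ndarray]  # atom name -> xyz (A), heavy atoms only

    @property
    def one_letter(self) -> str | None:
        return AA3_TO_1.get(self.name)

    def contact_coords(self, atom_mode: str) -> np.ndarray | None:
        """Coordinates used for the distance rule; None if unusable."""
        if atom_mode == "min_heavy_atom":
            if not self.atoms:
                return None
            return np.vstack(list(self.atoms.values()))
        if atom_mode == "c_beta":
            name = "CA" if self.name == "GLY" else "CB"
            xyz = self.atoms.get(name)
            if xyz is None and name == "CB":  # incomplete side chain
                xyz = self.atoms.get("CA")
            return None if xyz is None else xyz.reshape(1, 3)
        raise ValueError(f"unknown atom_mode {atom_mode!r}")


@dataclass
class ComplexStructure:
    """Polymer chains of one (bio)assembly, heavy atoms only."""

    chains: dict[str, list[Residue]]
    source: str = "synthetic"

    def residue(self, chain: str, number: int) -> Residue | None:
        for res in self.chains.get(chain, []):
            if res.number == number:
                return res
        return None


@dataclass(frozen=True)
class ResidueContact:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    min_distance: float


@dataclass
class InterfaceContactSet:
    """All contacts between one chain pair, with the >=10 qualification."""

    chain_pair: tuple[str, str]
    contacts: list[ResidueContact] = field(default_factory=list)
    min_contacts: int = 10

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def qualifies(self) -> bool:
        return self.n_contacts >= self.min_contacts


@dataclass(frozen=True)
class MutationRecord:
    """A somatic missense substitution in canonical-protein coordinates."""

    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.ref_aa not in AA1 or self.alt_aa not in AA1:
            raise ValueError(
                f"{self.gene} p.{self.ref_aa}{self.position}{self.alt_aa}: "
                "ref/alt must be standard one-letter amino-acid codes"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt residues must differ (missense)")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")


@dataclass
class MutationMapping:
    mutation: MutationRecord
    chain: str | None
    matched: bool
    ref_consistent: bool | None  # None when the residue is absent from the model
    note: str = ""


def load_structure(path: str | Path) -> ComplexStructure:
    """Read a PDB or mmCIF file into polymer chains of heavy atoms.

    Waters and hetero compounds are excluded; modified residues with a
    known parent (e.g. MSE, HYP) are renamed to the parent.
    """
    st = gemmi.read_structure(str(path))
    st.remove_waters()
    st.remove_hydrogens()
    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            name = MODIFIED_PARENT.get(res.name, res.name)
            if name not in AA3_TO_1:
                continue  # ligands, nucleotides, unknown het groups
            atoms = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(pos)):
                    raise ValueError(f"{path}: non-finite coordinates in {chain.name}/{res.seqid.num}")
                atoms[atom.name] = pos
            residues.append(Residue(number=res.seqid.num, name=name, atoms=atoms))
        if residues:
            chains[chain.name] = residues
    return ComplexStructure(chains=chains, source=Path(path).stem)


def residue_contacts(
    structure: ComplexStructure,
    cutoff: float = 8.0,
    atom_mode: str = "min_heavy_atom",
) -> list[ResidueContact]:
    """All inter-chain residue pairs with distance strictly below ``cutoff``.

    Ordering is deterministic: by (chain_a, chain_b) then (res_a, res_b)
    with chain_a < chain_b.
    """
    chain_ids = sorted(structure.chains)
    if len(chain_ids) < 2:
        warnings.warn("structure has fewer than two polymer chains; no interface possible")
        return []
    contacts: list[ResidueContact] = []
    for ia, ca in enumerate(chain_ids):
        for cb in chain_ids[ia + 1 :]:
            for res_a in structure.chains[ca]:
                xa = res_a.contact_coords(atom_mode)
                if xa is None:
                    continue
                for res_b in structure.chains[cb]:
                    xb = res_b.contact_coords(atom_mode)
                    if xb is None:
                        continue
                    d = float(cdist(xa, xb).min())
                    if d < cutoff:
                        contacts.append(ResidueContact(ca, res_a.number, cb, res_b.number, d))
    return contacts


def qualify_interfaces(
    contacts: list[ResidueContact], min_contacts: int = 10
) -> list[InterfaceContactSet]:
    """Group contacts by chain pair and apply the >= ``min_contacts`` rule."""
    by_pair: dict[tuple[str, str], list[ResidueContact]] = {}
    for c in contacts:
        by_pair.setdefault((c.chain_a, c.chain_b), []).append(c)
    return [
        InterfaceContactSet(chain_pair=pair, contacts=clist, min_contacts=min_contacts)
        for pair, clist in sorted(by_pair.items())
    ]


def interface_residues(iface: InterfaceContactSet) -> dict[str, set[int]]:
    """Residues of each chain participating in at least one contact."""
    ca, cb = iface.chain_pair
    out: dict[str, set[int]] = {ca: set(), cb: set()}
    for c in iface.contacts:
        out[c.chain_a].add(c.res_a)
        out[c.chain_b].add(c.res_b)
    return out


def map_mutations(
    mutations: list[MutationRecord],
    iface: InterfaceContactSet,
    chain_map: dict[str, tuple[str, int]],
    structure: ComplexStructure | None = None,
) -> list[MutationMapping]:
    """Map canonical-sequence mutations onto interface residues.

    ``chain_map`` gives, per gene, the structure chain and the offset such
    that structure residue number = canonical position + offset.  A
    mutation is matched when its mapped residue is an interface residue;
    ``ref_consistent`` compares the mutation's reference amino acid with
    the structure's residue identity when a structure is supplied.
    """
    residues = interface_residues(iface)
    out = []
    for mut in mutations:
        if mut.gene not in chain_map:
            out.append(
                MutationMapping(mut, None, False, None, note="gene not in chain map; skipped")
            )
            continue
        chain, offset = chain_map[mut.gene]
        pos = mut.position + offset
        matched = pos in residues.get(chain, set())
        ref_ok: bool | None = None
        note = ""
        if structure is not None:
            res = structure.residue(chain, pos)
            if res is None:
                note = "residue absent from structure"
            else:
                ref_ok = res.one_letter == mut.ref_aa
                if ref_ok is False:
                    note = f"reference mismatch: structure has {res.one_letter} at {chain}/{pos}"
        out.append(MutationMapping(mut, chain, matched, ref_ok, note=note))
    return out


# ---------------------------------------------------------------------------
# tabular I/O

def load_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a mutation TSV with columns gene, position, ref, alt[, source]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene", "position", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        MutationRecord(
            gene=str(r.gene),
            position=int(r.position),
            ref_aa=str(r.ref),
            alt_aa=str(r.alt),
            source=str(getattr(r, "source", "")),
        )
        for r in df.itertuples(index=False)
    ]


def load_chain_map(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a chain-map TSV with columns gene, chain, offset."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene", "chain", "offset") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return {str(r.gene): (str(r.chain), int(r.offset)) for r in df.itertuples(index=False)}
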