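"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to the screen — interaction-database exports, search-hit
tables, distogram tensors, complex bioassemblies, somatic-mutation lists
and ddG tables — require large external resources.  These generators
emulate each of them with exactly known ground truth so every stage is
testable end to end:

* interaction tables with heavy-tailed per-publication interaction counts
  (sizes drawn as ceil(exp(Normal)), mimicking the screen-vs-focused-study
  dichotomy that motivates publication weighting), plus analytically
  computed true pair scores;
* distograms whose softmax mass in the 2-12 A bins equals a planted
  contact probability at chosen inter-chain residue pairs;
* toy two-chain structures with an exact, analytically constructed number
  of inter-chain residue contacts under the 8 A rule;
* mutation/ddG cohorts with exact per-band counts (defaults mirror a
  cohort of 996 mapped mutations with 268 destabilizing and 88 possibly
  destabilizing);
* three method score tables over one pair universe with tunable
  concordance, plus a supported reference set correlated with the true
  quality scores.

All generators are deterministic under a fixed seed; each draws from its
own seeded generator, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax

from .contacts import N_BINS, N_CONTACT_BINS, Distogram
from .interfaces import AA3_TO_1, ComplexStructure, Residue

__all__ = [
    "SimulationConfig",
    "gen_interaction_table",
    "gen_distogram",
    "gen_toy_complex",
    "gen_random_complex",
    "gen_mutations_and_ddg",
    "gen_method_scores",
    "structure_to_pdb",
]

_AA1 = sorted(set(AA3_TO_1.values()))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the test conditions."""

    seed: int = 0
    # interaction tables
    n_pairs: int = 300
    n_publications: int = 120
    publication_log_mean: float = 1.0
    publication_log_sd: float = 1.5
    # distograms
    L1: int = 50
    L2: int = 50
    planted_contacts: tuple[tuple[int, int, float], ...] = ((10, 20, 0.95),)
    background_contact_max: float = 0.08
    # toy complexes
    n_chain_residues: int = 30
    n_interchain_contacts: int = 10
    # mutation / ddG cohorts (destabilizing, possibly, neutral, stabilizing)
    n_mutations: int = 996
    band_counts: tuple[int, int, int, int] = (268, 88, 640, 0)
    # method benchmark
    method_concordance: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.method_concordance <= 1:
            raise ValueError("method_concordance must be in [0, 1]")
        for i, j, p in self.planted_contacts:
            if not 0 <= p <= 1:
                raise ValueError("planted contact probability must be in [0, 1]")
            if not (1 <= i <= self.L1 and 1 <= j <= self.L2):
                raise ValueError("planted contact indices must be 1-based within (L1, L2)")
        if sum(self.band_counts) != self.n_mutations:
            raise ValueError("band counts must sum to n_mutations")

    def rng(self, stream: int) -> np.random.Generator:
        # one independent generator per generator invocation
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# interaction tables

def gen_interaction_table(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction evidence rows plus analytically derived true scores.

    Returns (table, truth): ``table`` has columns protein_a, protein_b,
    pmid; ``truth`` has protein_a, protein_b, true_score where the score
    is computed directly from the planted publication assignments
    (sum over supporting publications of 1/sqrt(publication size)).
    """
    rng = cfg.rng(1)
    genes = [f"G{i:04d}" for i in range(2 * cfg.n_pairs)]
    pair_pool = [
        tuple(sorted((genes[2 * i], genes[2 * i + 1]))) for i in range(cfg.n_pairs)
    ]
    sizes = np.ceil(
        np.exp(rng.normal(cfg.publication_log_mean, cfg.publication_log_sd, cfg.n_publications))
    ).astype(int)
    sizes = np.clip(sizes, 1, cfg.n_pairs)

    rows = []
    support: dict[tuple[str, str], list[int]] = {}
    for pub_idx, size in enumerate(sizes):
        pmid = f"{900000 + pub_idx}"
        chosen = rng.choice(len(pair_pool), size=size, replace=False)
        for ci in chosen:
            pair = pair_pool[ci]
            rows.append({"protein_a": pair[0], "protein_b": pair[1], "pmid": pmid})
            support.setdefault(pair, []).append(pub_idx)

    weights = 1.0 / np.sqrt(sizes.astype(float))
    truth_rows = [
        {
            "protein_a": pair[0],
            "protein_b": pair[1],
            "true_score": float(sum(weights[i] for i in pubs)),
        }
        for pair, pubs in sorted(support.items())
    ]
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# distograms

def gen_distogram(cfg: SimulationConfig) -> tuple[Distogram, pd.DataFrame]:
    """A distogram whose 2-12 A softmax mass is exactly the planted
    probability at planted inter-chain pairs and below
    ``background_contact_max`` elsewhere.

    Per residue pair the 64 bin probabilities are drawn with random
    within-half composition, then the first 32 bins are scaled to total
    contact mass p; logits are the log-probabilities, so the softmax
    recovers p to float precision (probabilities are clipped away from
    0 and 1 by 1e-12).  The tensor is symmetric.  Truth columns: i, j
    (1-based per-chain) and planted probability.
    """
    rng = cfg.rng(2)
    L = cfg.L1 + cfg.L2
    contact_mass = rng.uniform(0.01, cfg.background_contact_max, size=(L, L))
    contact_mass = np.triu(contact_mass) + np.triu(contact_mass, 1).T
    truth_rows = []
    for i, j, p in cfg.planted_contacts:
        r, c = i - 1, cfg.L1 + j - 1
        contact_mass[r, c] = contact_mass[c, r] = p
        truth_rows.append({"i": i, "j": j, "planted_probability": p})

    contact_mass = np.clip(contact_mass, 1e-12, 1 - 1e-12)
    # random composition within each half, scaled to the target mass
    comp = rng.uniform(0.1, 1.0, size=(L, L, N_BINS))
    comp = np.triu(comp.transpose(2, 0, 1)).transpose(1, 2, 0) + np.triu(
        comp.transpose(2, 0, 1), 1
    ).transpose(2, 1, 0)
    near = comp[:, :, :N_CONTACT_BINS]
    far = comp[:, :, N_CONTACT_BINS:]
    near = near / near.sum(axis=2, keepdims=True) * contact_mass[:, :, None]
    far = far / far.sum(axis=2, keepdims=True) * (1 - contact_mass)[:, :, None]
    probs = np.concatenate([near, far], axis=2)
    logits = np.log(probs)
    # The log/exp round trip through the scoring softmax perturbs the
    # planted mass by O(1e-16); resolve the roundoff downward so a value
    # planted exactly at a strict confidence threshold never crosses it.
    for i, j, p in cfg.planted_contacts:
        r, c = i - 1, cfg.L1 + j - 1
        for rr, cc in ((r, c), (c, r)):
            row = logits[rr, cc]
            for _ in range(64):
                mass = float(softmax(row)[:N_CONTACT_BINS].sum())
                if mass <= p:
                    break
                step = (mass - p) / max(mass * (1 - mass), 1e-12) + 1e-13
                row[:N_CONTACT_BINS] -= step
    return Distogram(logits=logits, L1=cfg.L1, L2=cfg.L2), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# toy structures

_CA_CB_Z = 1.5  # A, Cbeta offset perpendicular to the chain plane
_RESIDUE_SPACING = 10.0  # A along the chain axis; keeps non-facing pairs apart
_CONTACT_SEP = 5.0  # A between facing residues (< 8, a contact)
_FAR_SEP = 60.0  # A for non-contacting residues of chain B


def gen_toy_complex(cfg: SimulationConfig) -> ComplexStructure:
    """A two-chain structure with exactly ``n_interchain_contacts``
    inter-chain residue pairs under 8 A, by analytic placement.

    Residues of both chains sit on parallel lines spaced 10 A along x.
    The first k residues of chain B face their chain-A counterparts at
    5 A; the rest are displaced to 60 A.  Facing pairs are therefore the
    only ones within 8 A under either atom mode (the closest non-facing
    pair is sqrt(10^2 + 5^2) ~ 11.2 A away).
    """
    k = cfg.n_interchain_contacts
    n = cfg.n_chain_residues
    if k < 0 or k > n:
        raise ValueError(
            f"cannot place {k} contacts with {n} residues per chain"
        )

    def residue(num: int, x: float, y: float) -> Residue:
        return Residue(
            number=num,
            name="ALA",
            atoms={
                "CA": np.array([x, y, 0.0]),
                "CB": np.array([x, y, _CA_CB_Z]),
            },
        )

    chain_a = [residue(i + 1, i * _RESIDUE_SPACING, 0.0) for i in range(n)]
    chain_b = [
        residue(i + 1, i * _RESIDUE_SPACING, _CONTACT_SEP if i < k else _FAR_SEP)
        for i in range(n)
    ]
    return ComplexStructure(chains={"A": chain_a, "B": chain_b}, source="synthetic_toy")


def gen_random_complex(
    cfg: SimulationConfig, box_size: float = 25.0
) -> ComplexStructure:
    """A seeded random two-chain complex for oracle comparisons: residues
    scattered uniformly in a box so contact counts are irregular."""
    rng = cfg.rng(3)

    def chain(n: int) -> list[Residue]:
        out = []
        for i in range(n):
            ca = rng.uniform(0, box_size, 3)
            cb = ca + rng.normal(0, 1, 3) * 0.8
            name = "GLY" if rng.random() < 0.1 else "ALA"
            atoms = {"CA": ca} if name == "GLY" else {"CA": ca, "CB": cb}
            out.append(Residue(number=i + 1, name=name, atoms=atoms))
        return out

    return ComplexStructure(
        chains={"A": chain(cfg.n_chain_residues), "B": chain(cfg.n_chain_residues)},
        source="synthetic_random",
    )


def structure_to_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write a structure as standard PDB ATOM records (heavy atoms only)."""
    lines = []
    serial = 1
    for chain_id in sorted(structure.chains):
        for res in structure.chains[chain_id]:
            for atom_name, xyz in res.atoms.items():
                element = atom_name[0]
                name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else atom_name
                lines.append(
                    f"ATOM  {serial:5d} {name_field} {res.name:>3s} {chain_id}"
                    f"{res.number:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mutations and ddG

_BAND_RANGES = {
    "destabilizing": (1.45, 4.0),
    "possibly_destabilizing": (1.05, 1.35),
    "neutral": (-0.9, 0.95),
    "stabilizing": (-3.0, -1.1),
}
_BAND_ORDER = ("destabilizing", "possibly_destabilizing", "neutral", "stabilizing")


def gen_mutations_and_ddg(
    cfg: SimulationConfig,
    gene: str = "GENE1",
    interface_positions: tuple[int, ...] | None = None,
    on_interface_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A mutation table and a ddG table with exact per-band counts.

    ddG values are drawn uniformly within band-interior intervals, so the
    planted band labels are recovered exactly by classification.  Mutation
    positions land on the supplied interface positions with probability
    ``on_interface_fraction`` (and off them otherwise); defaults place the
    interface at positions 1..n_interchain_contacts as in the toy complex.

    Returns (mutations, ddg): mutations has gene, position, ref, alt,
    source, on_interface; ddg has gene, mutation, complex_id, ddg,
    true_band.
    """
    rng = cfg.rng(4)
    n = cfg.n_mutations
    if n == 0:
        mut_cols = ["gene", "position", "ref", "alt", "source", "on_interface"]
        ddg_cols = ["gene", "mutation", "complex_id", "ddg", "true_band"]
        return pd.DataFrame(columns=mut_cols), pd.DataFrame(columns=ddg_cols)
    if interface_positions is None:
        interface_positions = tuple(range(1, cfg.n_interchain_contacts + 1))
    off_positions = tuple(
        p for p in range(1, cfg.n_chain_residues + 1) if p not in interface_positions
    )

    bands = np.repeat(_BAND_ORDER, cfg.band_counts)
    ddg_values = np.empty(n)
    for band in _BAND_ORDER:
        mask = bands == band
        lo, hi = _BAND_RANGES[band]
        ddg_values[mask] = rng.uniform(lo, hi, mask.sum())

    on_iface = rng.random(n) < on_interface_fraction
    mut_rows = []
    ddg_rows = []
    for idx in range(n):
        pool = interface_positions if on_iface[idx] else off_positions or interface_positions
        pos = int(pool[rng.integers(len(pool))])
        ref, alt = rng.choice(_AA1, size=2, replace=False)
        mut_rows.append(
            {
                "gene": gene,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "source": "synthetic",
                "on_interface": bool(on_iface[idx]),
            }
        )
        ddg_rows.append(
            {
                "gene": gene,
                "mutation": f"{ref}{pos}{alt}",
                "complex_id": "CPLX1",
                "ddg": float(ddg_values[idx]),
                "true_band": bands[idx],
            }
        )
    return pd.DataFrame(mut_rows), pd.DataFrame(ddg_rows)


# ---------------------------------------------------------------------------
# method scores

def gen_method_scores(
    cfg: SimulationConfig,
    methods: tuple[str, str, str] = ("af_contact", "af2complex", "folddock"),
    supported_fraction: float = 0.25,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Three method score tables over one pair universe, plus a supported
    reference set correlated with the latent quality score.

    Each method's score is ``c * q + (1 - c) * noise`` where q is the
    latent pair quality, c the concordance and noise independent per
    method; at c = 1 the three rankings are identical, and expected top-k
    overlap grows monotonically with c.  A pair is supported with
    probability proportional to q, scaled so the expected supported
    fraction matches ``supported_fraction``.
    """
    rng = cfg.rng(5)
    n = cfg.n_pairs
    pairs = [f"P{i:04d}--Q{i:04d}" for i in range(n)]
    quality = rng.random(n)
    supported = rng.random(n) < quality * 2 * supported_fraction

    tables = {}
    for method in methods:
        noise = rng.random(n)
        score = cfg.method_concordance * quality + (1 - cfg.method_concordance) * noise
        tables[method] = pd.DataFrame(
            {"pair": pairs, "score": score, "method": method}
        )
    reference = pd.DataFrame({"pair": [p for p, s in zip(pairs, supported) if s]})
    return tables, reference
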