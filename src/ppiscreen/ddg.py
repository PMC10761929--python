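"""Classification of binding free-energy changes (ddG) of interface mutations.

ddG is the difference in binding free energy between mutant and wild-type
complex, in kcal/mol; positive values destabilize binding.  Values above
1.4 kcal/mol are classified destabilizing — a deliberately stringent
cutoff: RT ln 10 at room temperature is 1.36 kcal/mol, so 1.4 kcal/mol
corresponds to more than a 10-fold loss in binding affinity.  Values in
(1.0, 1.4] are possibly destabilizing, values below -1.0 stabilizing
(the conventional stabilizing threshold), the rest neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .interfaces import MutationRecord

__all__ = [
    "BANDS",
    "ThermoContext",
    "DdgResult",
    "classify_ddg",
    "ddg_to_fold_change",
    "fold_change_to_ddg",
    "summarize_cohort",
    "load_ddg_table",
    "classify_table",
]

BANDS = ("destabilizing", "possibly_destabilizing", "neutral", "stabilizing")

R_KCAL = 1.987e-3  # gas constant, kcal/(mol K)
ROOM_T = 298.0  # K


@dataclass(frozen=True)
class ThermoContext:
    """Gas constant and temperature used for energy/affinity conversion."""

    R: float = R_KCAL  # kcal/(mol K)
    T: float = ROOM_T  # K

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class DdgResult:
    mutation: MutationRecord | None
    complex_id: str
    ddg: float
    band: str


def classify_ddg(
    ddg: float,
    destabilizing_cutoff: float = 1.4,
    possible_cutoff: float = 1.0,
    stabilizing_cutoff: float = -1.0,
) -> str:
    """Band a ddG value.

    ddg > 1.4 -> destabilizing (strict, "above 1.4"); 1.0 < ddg <= 1.4 ->
    possibly_destabilizing; -1.0 <= ddg <= 1.0 -> neutral; ddg < -1.0 ->
    stabilizing.
    """
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    if ddg > destabilizing_cutoff:
        return "destabilizing"
    if ddg > possible_cutoff:
        return "possibly_destabilizing"
    if ddg >= stabilizing_cutoff:
        return "neutral"
    return "stabilizing"


def ddg_to_fold_change(ddg: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Fold change in dissociation constant implied by a ddG: exp(ddG/RT).

    At room temperature a ddG of 1.36 kcal/mol gives ~10-fold weaker
    binding (RT ln 10 = 1.36 kcal/mol).
    """
    return math.exp(ddg / ctx.RT)


def fold_change_to_ddg(fold: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Inverse of :func:`ddg_to_fold_change`: RT ln(fold)."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return ctx.RT * math.log(fold)


def summarize_cohort(results: list[DdgResult]) -> pd.DataFrame:
    """Counts and fractions per band, per complex and overall.

    Fractions use mapped mutations (rows present in ``results``) as the
    denominator.  The overall row has complex_id "ALL".
    """
    rows = []
    groups: dict[str, list[DdgResult]] = {"ALL": list(results)}
    for r in results:
        groups.setdefault(r.complex_id, []).append(r)
    for cid in sorted(groups, key=lambda c: (c != "ALL", c)):
        members = groups[cid]
        n = len(members)
        for band in BANDS:
            count = sum(1 for r in members if r.band == band)
            rows.append(
                {
                    "complex_id": cid,
                    "band": band,
                    "count": count,
                    "fraction": count / n if n else 0.0,
                    "n_total": n,
                }
            )
    return pd.DataFrame(rows, columns=["complex_id", "band", "count", "fraction", "n_total"])


def load_ddg_table(path: str | Path) -> pd.DataFrame:
    """Read a ddG TSV with columns gene, mutation, complex_id, ddg."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "mutation", "complex_id", "ddg") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def classify_table(df: pd.DataFrame, highlight_cutoff: float = 1.4) -> pd.DataFrame:
    """Add band and highlight columns to a ddG table.

    ``highlighted`` replicates the convention of flagging destabilizing
    entries (ddg > ``highlight_cutoff``) in supplementary tables.
    """
    out = df.copy()
    out["band"] = [classify_ddg(x) for x in out["ddg"]]
    out["highlighted"] = out["ddg"] > highlight_cutoff
    return out
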