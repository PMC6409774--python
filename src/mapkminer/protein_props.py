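"""Theoretical isoelectric point, molecular weight, and family summaries.

pI follows the Henderson-Hasselbalch net-charge model with a
Bjellqvist-style pKa table (the convention of the common web calculators),
solved by bisection; Mw uses average residue masses plus one water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_model import AnnotationTable

#: ionizable-group pKa values (Bjellqvist-style constants); sign "+" groups
#: are protonated below their pKa, "-" groups deprotonated above it.
DEFAULT_PKA: dict[str, tuple[float, str]] = {
    "Nterm": (7.50, "+"),
    "Cterm": (3.55, "-"),
    "D": (4.05, "-"),
    "E": (4.45, "-"),
    "C": (9.00, "-"),
    "Y": (10.00, "-"),
    "H": (5.98, "+"),
    "K": (10.00, "+"),
    "R": (12.00, "+"),
}

#: average residue (monomer minus water) masses in Da, ExPASy convention
AVERAGE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER = 18.01524


@dataclass
class PkaTable:
    values: dict[str, tuple[float, str]] = field(
        default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self) -> None:
        for group, (pka, sign) in self.values.items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"{group}: pKa {pka} outside (0, 14)")
            if sign not in "+-":
                raise ValueError(f"{group}: sign must be '+' or '-'")


def net_charge(seq: str, pH: float, pka: PkaTable | None = None) -> float:
    """Net protein charge at ``pH``: positive groups contribute
    1/(1+10^(pH-pKa)), negative groups -1/(1+10^(pKa-pH)); termini count
    once, side chains by occurrence.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    table = (pka or PkaTable()).values
    seq = seq.upper()
    charge = 0.0
    for group, (pk, sign) in table.items():
        if group == "Nterm" or group == "Cterm":
            count = 1
        else:
            count = seq.count(group)
        if not count:
            continue
        if sign == "+":
            charge += count / (1.0 + 10.0 ** (pH - pk))
        else:
            charge -= count / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(seq: str, pka: PkaTable | None = None,
                      tol: float = 1e-3) -> float:
    """pH at which net_charge crosses zero, by bisection on [0, 14].

    The termini always ionize, so a sign change on [0, 14] is guaranteed.
    """
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da (sum of residue masses + one water)."""
    if not seq:
        raise ValueError("empty sequence")
    total = WATER
    for ch in seq.upper():
        try:
            total += AVERAGE_MASS[ch]
        except KeyError:
            raise ValueError(f"residue {ch!r} has no defined mass") from None
    return total


@dataclass(frozen=True)
class PropertyRecord:
    protein_id: str
    length: int
    pI: float
    Mw: float


def property_record(protein) -> PropertyRecord:
    return PropertyRecord(protein_id=protein.id, length=len(protein.sequence),
                          pI=isoelectric_point(protein.sequence),
                          Mw=molecular_weight(protein.sequence))


@dataclass(frozen=True)
class FamilySummary:
    family: str
    n: int
    mean_length: float
    mean_length_rounded: int
    pI_min: float
    pI_min_gene: str
    pI_max: float
    pI_max_gene: str
    mean_Mw: float
    mean_exons: float
    exon_min: int
    exon_max: int


def summarize_family(table: AnnotationTable, family: str) -> FamilySummary:
    """Family-level aggregates over an annotation table (all rows counted,
    including short outliers).
    """
    rows = table.family(family)
    if rows.empty:
        raise ValueError(f"no rows for family {family!r}")
    pI = rows["pI"]
    return FamilySummary(
        family=family,
        n=len(rows),
        mean_length=float(rows["PL"].mean()),
        mean_length_rounded=int(round(rows["PL"].mean())),
        pI_min=float(pI.min()), pI_min_gene=str(pI.idxmin()),
        pI_max=float(pI.max()), pI_max_gene=str(pI.idxmax()),
        mean_Mw=float(rows["Mw"].mean()),
        mean_exons=float(rows["Exo"].mean()),
        exon_min=int(rows["Exo"].min()),
        exon_max=int(rows["Exo"].max()),
    )
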