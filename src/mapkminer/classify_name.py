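"""Family calls, clade assignment, and orthology-based nomenclature.

A candidate passes the family funnel when its profile-HMM hit clears the
e-value threshold AND the mandatory signature motifs are present in kinase
order.  Clades (A-D) come from the best local-alignment reference of the
same family; corroborating evidence (T-loop type, common-docking-site
distance, MKK S/T spacing) is recorded but never overrides the top hit.
Names follow the MAPK nomenclature guidelines: species prefix + family +
homolog number, with "-k" paralog suffixes when a number is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_phylo import ScoringScheme, local_score
from .gene_structure import _natural_key
from .io_model import GeneModel, ProteinRecord
from .motif_engine import EvidenceProfile, compile_pattern, evidence_profile
from .profile_hmm import HmmHit

#: consensus common docking (CD) sites of the four MPK clades
DOCKING_CONSENSUS: dict[str, str] = {
    "A": "KMLVFDPNKRIVEEAL",
    "B": "KMLVFDPSKRISVTEAL",
    "C": "SLCSWDPCKRPTAEEAL",
    "D": "RLLAFDPKDRPTAEEAL",
}

#: MKK clade-specific S/T spacing signatures: residues at offsets 0, 6, 12
#: of a 13-mer (clade A tolerates S or T at the middle position)
MKK_SPACING_CLADES: dict[str, tuple[str, str, str]] = {
    "B": ("S", "T", "T"),
    "C": ("S", "T", "S"),
    "D": ("S", "S", "T"),
    "A": ("S", "ST", "T"),
}


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    sequence: str
    family: str              # MPK | MKK
    clade: str               # A | B | C | D
    homolog_number: int
    species_code: str = ""

    def __post_init__(self) -> None:
        if self.homolog_number < 1:
            raise ValueError("homolog_number must be >= 1")


@dataclass
class FamilyCall:
    protein_id: str
    family: str              # MPK | MKK | none
    hmm_evalue: float
    evidence: EvidenceProfile
    accepted: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class CladeAssignment:
    protein_id: str
    family: str
    clade: str
    top_reference: str
    homolog_number: int
    tloop_consistent: bool
    docking_distance: int
    mkk_spacing_clade: str   # A|B|C|D|none
    score: float


@dataclass(frozen=True)
class GeneName:
    name: str
    species_prefix: str
    family: str
    homolog_number: int
    paralog_index: int | None


# ---------------------------------------------------------------------------
# family calling

#: optional motifs recorded as "<name>_absent" flags when missing
_OPTIONAL_FLAGGED = {
    "MPK": ["P-loop", "ATP-anchor", "DFGLAR", "TRWYRAPE"],
    "MKK": ["spacing"],
}


def call_family(protein: ProteinRecord, hit: HmmHit, family: str,
                near_match_budget: int = 1) -> FamilyCall:
    """Combine the HMM screen with motif gating into an accept/reject call."""
    if hit.protein_id != protein.id:
        raise ValueError("hit does not belong to this protein")
    ev = evidence_profile(protein, family, near_match_budget=near_match_budget)
    flags: list[str] = []

    mandatory_ok = True
    for motif in ("C-loop", "T-loop") if family == "MPK" else \
                 ("activation", "C-loop-relaxed"):
        if motif == "C-loop":
            # strict C-loop, else the relaxed D(L/I/V)K fallback
            if not ev.has("C-loop"):
                if ev.has("C-loop-relaxed"):
                    flags.append("cloop_relaxed")
                else:
                    mandatory_ok = False
                    flags.append("cloop_absent")
        elif not ev.has(motif):
            mandatory_ok = False
            flags.append(f"{'tloop' if motif == 'T-loop' else motif}_absent")
    for motif in _OPTIONAL_FLAGGED[family]:
        if not ev.has(motif):
            flags.append(f"{motif.lower().replace('-', '')}_absent")
    for motif, budget in ev.near_match_used.items():
        flags.append(f"{motif}_near_match_{budget}")
    if not ev.order_ok:
        flags.append("motif_order_violated")

    accepted = bool(hit.passes and mandatory_ok and ev.order_ok)
    return FamilyCall(protein_id=protein.id,
                      family=family if accepted else "none",
                      hmm_evalue=hit.e_value, evidence=ev,
                      accepted=accepted, flags=flags)


# ---------------------------------------------------------------------------
# clade assignment

def _docking_distance(sequence: str, consensus: str, window: int = 60) -> int:
    """Minimum Hamming distance between the clade consensus and any
    equal-length window in the C-terminal ``window`` residues."""
    tail = sequence[-window:]
    w = len(consensus)
    if len(tail) < w:
        return w
    return min(
        sum(1 for x, y in zip(tail[i:i + w], consensus) if x != y)
        for i in range(len(tail) - w + 1)
    )


def _mkk_spacing_clade(sequence: str) -> str:
    for clade in ("B", "C", "D", "A"):    # specific patterns before clade A
        p0, pm, p1 = MKK_SPACING_CLADES[clade]
        for i in range(len(sequence) - 12):
            if (sequence[i] in p0 and sequence[i + 6] in pm
                    and sequence[i + 12] in p1):
                return clade
    return "none"


def assign_clade(call: FamilyCall, protein: ProteinRecord,
                 references: list[ReferenceEntry],
                 scheme: ScoringScheme = ScoringScheme()) -> CladeAssignment:
    """Clade = clade of the best-scoring same-family reference (first in
    the reference list wins ties).  T-loop concordance (TEY => A/B,
    TDY => C/D) and docking-site distance are corroboration only.
    """
    if not call.accepted:
        raise ValueError(f"{call.protein_id}: cannot assign clade to a rejected call")
    fam_refs = [r for r in references if r.family == call.family]
    if not fam_refs:
        raise ValueError(f"no references for family {call.family}")
    best, best_score = None, float("-inf")
    for ref in fam_refs:
        s = local_score(protein.sequence, ref.sequence, scheme)
        if s > best_score:
            best, best_score = ref, s
    tloop = call.evidence.tloop_type
    if tloop == "TEY":
        consistent = best.clade in ("A", "B")
    elif tloop == "TDY":
        consistent = best.clade in ("C", "D")
    else:
        consistent = False
    dock = _docking_distance(protein.sequence, DOCKING_CONSENSUS[best.clade]) \
        if call.family == "MPK" else -1
    spacing = _mkk_spacing_clade(protein.sequence) if call.family == "MKK" else "none"
    return CladeAssignment(
        protein_id=call.protein_id, family=call.family, clade=best.clade,
        top_reference=best.id, homolog_number=best.homolog_number,
        tloop_consistent=consistent, docking_distance=dock,
        mkk_spacing_clade=spacing, score=best_score)


# ---------------------------------------------------------------------------
# nomenclature

def assign_names(assignments: list[CladeAssignment],
                 gene_models: dict[str, GeneModel],
                 species_prefix: str = "Ha") -> list[GeneName]:
    """Nomenclature strings: prefix + family + homolog number, and "-k"
    suffixes (k = 1..m by chromosome natural order, then start coordinate)
    whenever >= 2 queries share a (family, number).
    """
    for a in assignments:
        if a.protein_id not in gene_models:
            raise KeyError(f"no gene model for {a.protein_id}")
    groups: dict[tuple[str, int], list[CladeAssignment]] = {}
    for a in assignments:
        groups.setdefault((a.family, a.homolog_number), []).append(a)
    names = {}
    for (family, number), members in groups.items():
        if len(members) == 1:
            a = members[0]
            names[a.protein_id] = GeneName(
                name=f"{species_prefix}{family}{number}",
                species_prefix=species_prefix, family=family,
                homolog_number=number, paralog_index=None)
        else:
            ordered = sorted(members, key=lambda a: (
                _natural_key(gene_models[a.protein_id].chromosome),
                gene_models[a.protein_id].start,
                a.protein_id))
            for k, a in enumerate(ordered, 1):
                names[a.protein_id] = GeneName(
                    name=f"{species_prefix}{family}{number}-{k}",
                    species_prefix=species_prefix, family=family,
                    homolog_number=number, paralog_index=k)
    return [names[a.protein_id] for a in assignments]


def validate_docking_consensus() -> None:
    """Sanity check: four clade consensi, each a plain residue string."""
    assert set(DOCKING_CONSENSUS) == {"A", "B", "C", "D"}
    for consensus in DOCKING_CONSENSUS.values():
        compile_pattern(consensus)
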