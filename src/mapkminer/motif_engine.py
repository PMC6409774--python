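"""Degenerate signature-motif grammar, scanning, and per-protein evidence.

The motif grammar covers the fixed-width consensus patterns that gate
MPK/MKK family membership: capital letters match a single exact residue,
``x`` matches any standard residue, and ``(A/B/...)`` is an alternation
over single residues.  Windows containing the ambiguity letter X never
match (conservative evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_model import AMINO_ACIDS, ProteinRecord


class MotifGrammarError(ValueError):
    """Raised when a pattern string does not parse."""


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str
    family: str = "both"          # MPK | MKK | both
    mandatory: bool = False

    def __post_init__(self) -> None:
        compile_pattern(self.pattern)  # validate eagerly


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int                    # 0-based offset in the protein
    matched: str


@dataclass
class EvidenceProfile:
    """All signature-motif evidence for one candidate protein."""

    protein_id: str
    family: str
    hits: dict[str, list[MotifHit]] = field(default_factory=dict)
    tloop_type: str = "absent"    # TEY | TDY | variant | absent
    order_ok: bool = True
    near_match_used: dict[str, int] = field(default_factory=dict)

    def has(self, motif_name: str) -> bool:
        return bool(self.hits.get(motif_name))


class CompiledPattern:
    """A fixed-width matcher: one frozenset of allowed residues per position."""

    def __init__(self, pattern: str, positions: list[frozenset[str]]):
        self.pattern = pattern
        self.positions = positions
        self.width = len(positions)

    def matches_window(self, window: str, budget: int = 0) -> int | None:
        """Number of mismatches at non-wildcard positions, or None if it
        exceeds ``budget`` / the window contains X."""
        if len(window) != self.width or "X" in window:
            return None
        mismatches = 0
        for ch, allowed in zip(window, self.positions):
            if ch not in allowed:
                if len(allowed) == 20:   # wildcard never counts as near-match
                    return None
                mismatches += 1
                if mismatches > budget:
                    return None
        return mismatches


_ANY = frozenset(AMINO_ACIDS)


def compile_pattern(pattern: str) -> CompiledPattern:
    """Compile a fixed-width degenerate pattern into a positional matcher."""
    if not pattern:
        raise MotifGrammarError("empty pattern")
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "x":
            positions.append(_ANY)
            i += 1
        elif ch == "(":
            j = pattern.find(")", i)
            if j == -1:
                raise MotifGrammarError(f"{pattern!r}: unbalanced parenthesis")
            body = pattern[i + 1:j]
            letters = [p for p in body.split("/") if p]
            if not letters:
                raise MotifGrammarError(f"{pattern!r}: empty alternation")
            for letter in letters:
                if len(letter) != 1 or letter not in AMINO_ACIDS:
                    raise MotifGrammarError(
                        f"{pattern!r}: alternation element {letter!r} is not a residue")
            positions.append(frozenset(letters))
            i = j + 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise MotifGrammarError(f"{pattern!r}: unexpected character {ch!r}")
    return CompiledPattern(pattern, positions)


def scan(seq: ProteinRecord | str, pattern: MotifPattern | str,
         budget: int = 0) -> list[MotifHit]:
    """All (possibly overlapping) occurrences of ``pattern``, leftmost first."""
    if isinstance(pattern, MotifPattern):
        name, pat = pattern.name, pattern.pattern
    else:
        name, pat = pattern, pattern
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq
    matcher = compile_pattern(pat)
    hits = []
    for start in range(len(sequence) - matcher.width + 1):
        window = sequence[start:start + matcher.width]
        if matcher.matches_window(window, budget=budget) is not None:
            hits.append(MotifHit(motif_name=name, start=start, matched=window))
    return hits


# ---------------------------------------------------------------------------
# signature catalogs

P_LOOP = "(I/V/L)GxGx(S/F/G)GxV"
ATP_ANCHOR = "VA(I/V/M)KK(I/M)xxx(F/Y)"
C_LOOP = "HRD(L/I)KPxN"
C_LOOP_RELAXED = "D(L/I/V)K"
T_LOOP = "T(D/E)Y"
DFG = "DFGLAR"
APE = "TRWYRAPE"
MKK_ACTIVATION = "GTxxYMSPER"
MKK_SPACING = "(S/T)xxxxx(S/T)"


def signature_catalog(family: str) -> list[MotifPattern]:
    """The signature motifs gating membership in one kinase family.

    The mandatory MPK motifs are the catalytic C-loop (with a relaxed
    fallback) and the activation-loop T(D/E)Y; the MKK essentials are the
    relaxed C-loop and the GTxxYMSPER activation motif (near-match
    tolerated, see evidence_profile).
    """
    if family == "MPK":
        return [
            MotifPattern("P-loop", P_LOOP, "MPK", mandatory=False),
            MotifPattern("ATP-anchor", ATP_ANCHOR, "MPK", mandatory=False),
            MotifPattern("C-loop", C_LOOP, "MPK", mandatory=True),
            MotifPattern("C-loop-relaxed", C_LOOP_RELAXED, "MPK", mandatory=False),
            MotifPattern("T-loop", T_LOOP, "MPK", mandatory=True),
            MotifPattern("DFGLAR", DFG, "MPK", mandatory=False),
            MotifPattern("TRWYRAPE", APE, "MPK", mandatory=False),
        ]
    if family == "MKK":
        return [
            MotifPattern("activation", MKK_ACTIVATION, "MKK", mandatory=True),
            MotifPattern("spacing", MKK_SPACING, "MKK", mandatory=False),
            MotifPattern("C-loop-relaxed", C_LOOP_RELAXED, "MKK", mandatory=True),
        ]
    raise ValueError(f"unknown family {family!r}")


#: motifs whose first occurrences must appear in kinase-domain order
KINASE_ORDER = ["C-loop", "DFGLAR", "T-loop", "TRWYRAPE"]


def evidence_profile(seq: ProteinRecord, family: str,
                     near_match_budget: int = 1) -> EvidenceProfile:
    """Scan one candidate against the family catalog.

    The mandatory MKK activation motif (and the MPK relaxed C-loop
    fallback) may match with up to ``near_match_budget`` mismatches at
    non-wildcard positions.  ``order_ok`` checks that the first hits of
    C-loop < DFGLAR < T-loop < TRWYRAPE whenever all four are present.
    """
    profile = EvidenceProfile(protein_id=seq.id, family=family)
    for motif in signature_catalog(family):
        hits = scan(seq, motif)
        if not hits and motif.name == "activation" and near_match_budget > 0:
            hits = scan(seq, motif, budget=near_match_budget)
            if hits:
                profile.near_match_used[motif.name] = near_match_budget
        if not hits and motif.name == "C-loop-relaxed" and near_match_budget > 0:
            hits = scan(seq, motif, budget=near_match_budget)
            if hits:
                profile.near_match_used[motif.name] = near_match_budget
        profile.hits[motif.name] = hits

    tloop_hits = profile.hits.get("T-loop", [])
    if tloop_hits:
        profile.tloop_type = tloop_hits[0].matched   # TEY or TDY
    elif family == "MPK":
        # look for the documented activation-loop variants
        for variant in ("T(Q/V/S)Y", "T(Q/R)M", "MEY", "TEC"):
            if scan(seq, MotifPattern("T-variant", variant, "MPK")):
                profile.tloop_type = "variant"
                break
        else:
            profile.tloop_type = "absent"
    else:
        profile.tloop_type = "absent"

    ordered = [profile.hits.get(m) for m in KINASE_ORDER]
    if all(ordered):
        starts = [h[0].start for h in ordered]
        profile.order_ok = all(a < b for a, b in zip(starts, starts[1:]))
    else:
        profile.order_ok = True   # vacuous when the quartet is incomplete
    return profile
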