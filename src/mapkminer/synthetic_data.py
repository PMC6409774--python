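"""Synthetic reference sets, proteomes, gene models, expression matrices
and rate-asymmetric triplets with recorded ground truth.

The generators emulate the structure of a plant MPK/MKK mining study: four
clades per family distinguished by activation-loop type (TEY in clades
A/B, TDY in C/D) and C-terminal common-docking consensus, kinase-order
signature motifs, clade-conditioned exon counts, dispersed paralog pairs,
and a pooled two-tissue x {control, SA, NaCl, Peg} TPM design with planted
fold changes.  Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify_name import DOCKING_CONSENSUS, ReferenceEntry
from .io_model import AMINO_ACIDS, GeneModel, ProteinRecord
from .expression import QuantTable

_LETTERS = np.array(list(AMINO_ACIDS))

# ---------------------------------------------------------------------------
# family scaffold layouts: fixed motif realizations at fixed offsets

MPK_MOTIF_LAYOUT = {
    # name -> (offset, realization); clade-dependent slots hold None
    "P-loop": (20, "IGEGSFGSV"),
    "ATP-anchor": (45, "VAIKKIANSF"),
    "C-loop": (120, "HRDLKPSN"),
    "DFGLAR": (150, "DFGLAR"),
    "T-loop": (170, None),          # TEY (clades A/B) or TDY (C/D)
    "TRWYRAPE": (200, "TRWYRAPE"),
}
MPK_SCAFFOLD_LEN = 360
MPK_DOCKING_OFFSET = 330            # docking consensus placed here (C-terminal)

MKK_MOTIF_LAYOUT = {
    "C-loop-relaxed": (110, "DLK"),
    "activation": (160, "GTAAYMSPER"),
    "spacing": (200, None),          # clade-specific S/T spacing 13-mer
}
MKK_SCAFFOLD_LEN = 340

#: clade-specific spacing realizations (offsets 0, 6, 12 of the 13-mer)
MKK_SPACING_REALIZATION = {
    "A": ("S", "S", "T"),
    "B": ("S", "T", "T"),
    "C": ("S", "T", "S"),
    "D": ("S", "S", "T"),
}

#: homolog numbers available per clade, mirroring typical plant MPK/MKK sets
MPK_HOMOLOGS = {"A": [3, 6, 4, 11], "B": [1, 2, 7], "C": [22, 23],
                "D": [16, 19, 9, 17]}
MKK_HOMOLOGS = {"A": [1, 2, 6], "B": [3], "C": [4, 5], "D": [9]}

#: default clade-conditioned exon counts (MPK clade B = 3 exons, MKK clades
#: C/D intronless, per the structural patterns the generator emulates)
DEFAULT_EXON_PLAN = {
    ("MPK", "A"): 6, ("MPK", "B"): 3, ("MPK", "C"): 18, ("MPK", "D"): 10,
    ("MKK", "A"): 8, ("MKK", "B"): 12, ("MKK", "C"): 1, ("MKK", "D"): 1,
}

CONTRASTS = [f"{t}:{c}" for t in ("leaf", "root") for c in ("SA", "NaCl", "Peg")]


@dataclass
class TruthTable:
    """Ground truth for one synthetic proteome."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.df["id"].duplicated().any():
            raise ValueError("truth ids must be unique")
        self.df = self.df.set_index("id", drop=False)

    def planted(self, family: str | None = None) -> pd.DataFrame:
        sel = self.df[self.df["kind"] == "planted"]
        if family:
            sel = sel[sel["family"] == family]
        return sel

    def decoys(self) -> pd.DataFrame:
        return self.df[self.df["kind"] != "planted"]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence-level helpers

def mutate(seq: str, rate: float, seed: int,
           protect: list[tuple[int, int]] | None = None) -> str:
    """Per-site substitution with probability ``rate`` to a uniformly drawn
    different residue; 0-based half-open ``protect`` intervals untouched.
    """
    if not 0.0 <= rate < 1.0 and rate != 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    protected = np.zeros(len(seq), dtype=bool)
    for s, e in protect or []:
        protected[s:e] = True
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.nonzero(hits & ~protected)[0]:
        choices = [c for c in AMINO_ACIDS if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_LETTERS, size=n))


def _scrub_tdey(seq: list[str], keep_start: int,
                protected: np.ndarray) -> None:
    """Destroy accidental T(D/E)Y occurrences outside the designated
    activation-loop window (in place)."""
    i = 0
    while i <= len(seq) - 3:
        if (seq[i] == "T" and seq[i + 1] in "DE" and seq[i + 2] == "Y"
                and i != keep_start):
            for off in (2, 0, 1):
                if not protected[i + off]:
                    seq[i + off] = "A"
                    break
        i += 1


def _protected_mask(length: int, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def _mpk_archetype(scaffold: str, clade: str) -> tuple[str, list[tuple[int, int]]]:
    """Stamp the MPK motif layout plus clade T-loop and docking consensus
    onto a scaffold; returns the sequence and its protected intervals."""
    seq = list(scaffold)
    intervals = []
    for name, (off, realization) in MPK_MOTIF_LAYOUT.items():
        if name == "T-loop":
            realization = "TEY" if clade in ("A", "B") else "TDY"
        seq[off:off + len(realization)] = realization
        intervals.append((off, off + len(realization)))
    dock = DOCKING_CONSENSUS[clade]
    seq[MPK_DOCKING_OFFSET:MPK_DOCKING_OFFSET + len(dock)] = dock
    intervals.append((MPK_DOCKING_OFFSET, MPK_DOCKING_OFFSET + len(dock)))
    mask = _protected_mask(len(seq), intervals)
    _scrub_tdey(seq, MPK_MOTIF_LAYOUT["T-loop"][0], mask)
    return "".join(seq), intervals


def _mkk_archetype(scaffold: str, clade: str) -> tuple[str, list[tuple[int, int]]]:
    seq = list(scaffold)
    intervals = []
    for name, (off, realization) in MKK_MOTIF_LAYOUT.items():
        if name == "spacing":
            p0, pm, p1 = MKK_SPACING_REALIZATION[clade]
            window = list(seq[off:off + 13])
            window[0], window[6], window[12] = p0, pm, p1
            realization = "".join(window)
        seq[off:off + len(realization)] = realization
        intervals.append((off, off + len(realization)))
    return "".join(seq), intervals


# ---------------------------------------------------------------------------
# reference sets

@dataclass(frozen=True)
class FamilySpec:
    family: str
    clade: str
    homolog_number: int
    scaffold_length: int
    divergence: float


def _archetypes(reference_seed: int):
    """Deterministic clade/homolog archetypes shared by make_reference_set
    and make_proteome.  Returns {family: {(clade, number): (seq, protect)}}.
    """
    rng = np.random.default_rng((reference_seed, 0xA5C3))
    out = {"MPK": {}, "MKK": {}}
    mpk_scaffold = _random_seq(MPK_SCAFFOLD_LEN, rng)
    mkk_scaffold = _random_seq(MKK_SCAFFOLD_LEN, rng)
    for family, scaffold, homologs, stamp in (
            ("MPK", mpk_scaffold, MPK_HOMOLOGS, _mpk_archetype),
            ("MKK", mkk_scaffold, MKK_HOMOLOGS, _mkk_archetype)):
        for clade, numbers in homologs.items():
            clade_seed = int(rng.integers(2 ** 31))
            clade_base = mutate(scaffold, 0.25, clade_seed)
            clade_seq, intervals = stamp(clade_base, clade)
            for number in numbers:
                hom_seed = int(rng.integers(2 ** 31))
                seq = mutate(clade_seq, 0.12, hom_seed, protect=intervals)
                if family == "MPK":
                    chars = list(seq)
                    _scrub_tdey(chars, MPK_MOTIF_LAYOUT["T-loop"][0],
                                _protected_mask(len(seq), intervals))
                    seq = "".join(chars)
                out[family][(clade, number)] = (seq, intervals)
    return out


def make_reference_set(seed: int = 0
                       ) -> tuple[list[ReferenceEntry], dict[str, list[str]]]:
    """Clade archetype reference entries for both families, plus their
    (ungapped, per-family) alignments keyed by family."""
    arch = _archetypes(seed)
    refs: list[ReferenceEntry] = []
    alignments: dict[str, list[str]] = {"MPK": [], "MKK": []}
    for family in ("MPK", "MKK"):
        for (clade, number), (seq, _prot) in sorted(arch[family].items()):
            refs.append(ReferenceEntry(
                id=f"At{family}{number}", sequence=seq, family=family,
                clade=clade, homolog_number=number, species_code="At"))
            alignments[family].append(seq)
    return refs, alignments


# ---------------------------------------------------------------------------
# proteomes

def make_proteome(n_mpk: int = 10, n_mkk: int = 5, n_kinase_decoys: int = 20,
                  n_random_decoys: int = 200, divergence: float = 0.15,
                  seed: int = 0, reference_seed: int = 0
                  ) -> tuple[list[ProteinRecord], TruthTable]:
    """A proteome of planted kinases (mutated archetypes, motifs
    protected), kinase-like decoys (activation loop ablated) and
    composition-matched shuffled decoys, with a complete truth table.
    """
    arch = _archetypes(reference_seed)
    rng = np.random.default_rng((seed, 0x9E37))
    records: list[ProteinRecord] = []
    rows: list[dict] = []

    def plant(family: str, count: int) -> None:
        keys = sorted(arch[family])
        for i in range(count):
            clade, number = keys[i % len(keys)]
            base, intervals = arch[family][(clade, number)]
            copy = i // len(keys) + 1
            sub_seed = int(rng.integers(2 ** 31))
            seq = mutate(base, divergence, sub_seed, protect=intervals)
            if family == "MPK":
                chars = list(seq)
                _scrub_tdey(chars, MPK_MOTIF_LAYOUT["T-loop"][0],
                            _protected_mask(len(seq), intervals))
                seq = "".join(chars)
            pid = f"g{family}{number}_{copy}"
            records.append(ProteinRecord(id=pid, sequence=seq))
            rows.append(dict(id=pid, kind="planted", family=family,
                             clade=clade, homolog_number=number,
                             decoy_class=""))

    plant("MPK", n_mpk)
    plant("MKK", n_mkk)

    keys_mpk, keys_mkk = sorted(arch["MPK"]), sorted(arch["MKK"])
    for i in range(n_kinase_decoys):
        family = "MPK" if i % 2 == 0 else "MKK"
        keys = keys_mpk if family == "MPK" else keys_mkk
        clade, number = keys[i % len(keys)]
        base, intervals = arch[family][(clade, number)]
        chars = list(mutate(base, divergence, int(rng.integers(2 ** 31)),
                            protect=intervals))
        if family == "MPK":
            off, _ = MPK_MOTIF_LAYOUT["T-loop"]
            chars[off:off + 3] = "AAA"      # ablate the T-loop
            _scrub_tdey(chars, -1, _protected_mask(len(chars), []))
        else:
            off, realization = MKK_MOTIF_LAYOUT["activation"]
            chars[off:off + len(realization)] = "A" * len(realization)
        pid = f"decoyK{i}"
        records.append(ProteinRecord(id=pid, sequence="".join(chars)))
        rows.append(dict(id=pid, kind="kinase_decoy", family="", clade="",
                         homolog_number=0, decoy_class=f"{family}_ablated"))

    pool = [r.sequence for r in records] or [_random_seq(300, rng)]
    for i in range(n_random_decoys):
        src = pool[int(rng.integers(len(pool)))]
        shuffled = "".join(rng.permutation(list(src)))
        pid = f"decoyR{i}"
        records.append(ProteinRecord(id=pid, sequence=shuffled))
        rows.append(dict(id=pid, kind="random_decoy", family="", clade="",
                         homolog_number=0, decoy_class="shuffled"))

    truth = TruthTable(pd.DataFrame(rows, columns=[
        "id", "kind", "family", "clade", "homolog_number", "decoy_class"]))
    return records, truth


# ---------------------------------------------------------------------------
# gene models

def make_gff(truth: TruthTable,
             exon_plan: dict[tuple[str, str], int] | None = None,
             chromosomes: int = 17, seed: int = 0,
             same_chromosome_groups: list[tuple[str, int]] | None = None
             ) -> list[GeneModel]:
    """Gene models for the planted genes: clade-conditioned exon counts and
    paralog groups dispersed over distinct chromosomes (groups listed in
    ``same_chromosome_groups`` are co-located instead).
    """
    plan = dict(DEFAULT_EXON_PLAN)
    plan.update(exon_plan or {})
    co_located = set(same_chromosome_groups or [])
    rng = np.random.default_rng((seed, 0x6F))
    planted = truth.planted()
    models = []
    groups: dict[tuple[str, int], list[str]] = {}
    for _, row in planted.iterrows():
        groups.setdefault((row["family"], row["homolog_number"]), []).append(row["id"])
    chrom_names = [f"Chr{i + 1:02d}" for i in range(chromosomes)]
    for (family, number), members in sorted(groups.items()):
        if (family, number) in co_located or len(members) == 1:
            chosen = [chrom_names[int(rng.integers(chromosomes))]] * len(members)
        else:
            order = rng.permutation(chromosomes)
            chosen = [chrom_names[order[i % chromosomes]] for i in range(len(members))]
        clade = planted.loc[members[0], "clade"]
        n_exons = plan[(family, clade)]
        for pid, chrom in zip(members, chosen):
            start = int(rng.integers(10_000, 150_000_000))
            exons, pos = [], start
            for _ in range(n_exons):
                length = int(rng.integers(120, 400))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(80, 900))
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(gene_id=pid, chromosome=chrom,
                                    strand=strand, start=start,
                                    end=exons[-1][1], exons=tuple(exons)))
    return models


# ---------------------------------------------------------------------------
# expression

def make_expression(truth: TruthTable,
                    planted_log2fc: dict[tuple[str, str], float] | None = None,
                    noise_sd: float = 0.25, seed: int = 0) -> QuantTable:
    """Pooled two-tissue TPM design: control TPM ~ lognormal(meanlog 3,
    sdlog 1) per gene/tissue; treatment TPM = control * 2^(planted +
    N(0, noise_sd)).  ``planted_log2fc`` keys are (gene id, "tissue:trt").
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    planted_log2fc = planted_log2fc or {}
    rng = np.random.default_rng((seed, 0xE1))
    genes = list(truth.planted()["id"])
    samples = []
    for tissue in ("leaf", "root"):
        for trt in ("control", "SA", "NaCl", "Peg"):
            samples.append((f"{tissue}_{trt}", tissue, trt))
    meta = pd.DataFrame([(t, c) for _, t, c in samples],
                        index=[s for s, _, _ in samples],
                        columns=["tissue", "treatment"])
    data = {}
    control = {t: np.exp(rng.normal(3.0, 1.0, size=len(genes)))
               for t in ("leaf", "root")}
    for name, tissue, trt in samples:
        if trt == "control":
            data[name] = control[tissue]
        else:
            fc = np.array([planted_log2fc.get((g, f"{tissue}:{trt}"), 0.0)
                           for g in genes])
            noise = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd else 0.0
            data[name] = control[tissue] * 2.0 ** (fc + noise)
    tpm = pd.DataFrame(data, index=genes)
    return QuantTable(tpm=tpm, samples=meta)


# ---------------------------------------------------------------------------
# triplets for the relative rate test

def make_triplet(n_sites: int, rate_a: float, rate_b: float,
                 seed: int = 0) -> tuple[str, str, str]:
    """(a, b, outgroup): ancestor drawn uniform over residues; lineages a/b
    substituted at their rates; the outgroup equals the ancestor."""
    for r in (rate_a, rate_b):
        if not 0.0 <= r < 1.0:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng((seed, 0x7A))
    ancestor = _random_seq(n_sites, rng)
    a = mutate(ancestor, rate_a, int(rng.integers(2 ** 31)))
    b = mutate(ancestor, rate_b, int(rng.integers(2 ** 31)))
    return a, b, ancestor
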