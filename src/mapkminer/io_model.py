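"""Core record types and readers/writers for FASTA, GFF3 and the packaged
annotation fixture.

All genomic coordinates are 1-based inclusive, following the GFF3
convention; conversion to 0-based half-open happens only inside interval
arithmetic helpers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in a ProteinRecord; X is tolerated but flagged
VALID_LETTERS = frozenset(AMINO_ACIDS + "X")


class ParseError(ValueError):
    """Raised on malformed FASTA/GFF3 input."""


class ConsistencyError(ValueError):
    """Raised when structurally valid input violates a cross-record contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single proteome entry.

    ``species_code`` is the short prefix used in gene nomenclature
    (e.g. ``"Ha"`` for Helianthus annuus).
    """

    id: str
    sequence: str
    description: str = ""
    species_code: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_LETTERS
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its exon structure (1-based inclusive intervals)."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise ConsistencyError(f"{self.gene_id}: start > end")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            raise ConsistencyError(f"{self.gene_id}: gene model needs >= 1 exon")
        prev_end = None
        for s, e in exons:
            if s > e:
                raise ConsistencyError(f"{self.gene_id}: exon start > end")
            if s < self.start or e > self.end:
                raise ConsistencyError(
                    f"{self.gene_id}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ConsistencyError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


# canonical column headers of the annotation TSV
TABLE_COLUMNS = [
    "Name", "Gene ID", "Chr", "Str", "Start", "End",
    "PL", "Exo", "Int", "Sl", "pI", "Mw",
]


@dataclass
class AnnotationTable:
    """Per-gene annotation rows (name, location, structure, pI/Mw).

    Wraps a DataFrame with the fixture's column headers plus a derived
    ``Family`` column (MPK or MKK parsed from the gene name).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConsistencyError(f"annotation table missing columns {missing}")
        df = self.df.copy()
        if "Family" not in df.columns:
            df["Family"] = [
                "MKK" if "MKK" in n else "MPK" for n in df["Name"]
            ]
        bad = df[df["Int"] != df["Exo"] - 1]
        if len(bad):
            raise ConsistencyError(
                f"introns != exons - 1 for {list(bad['Name'])}"
            )
        if (df["PL"] <= 0).any():
            raise ConsistencyError("protein length must be positive")
        df = df.set_index("Name", drop=False)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def family(self, family: str) -> pd.DataFrame:
        if family not in ("MPK", "MKK"):
            raise ValueError(f"unknown family {family!r}")
        return self.df[self.df["Family"] == family]

    def row(self, name: str) -> pd.Series:
        return self.df.loc[name]

    def to_tsv(self, path) -> None:
        self.df[TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA into ProteinRecords (order preserved).

    Raises ParseError for text before the first header or duplicate ids,
    and for an empty file.
    """
    with open(path) as fh:
        first = fh.readline()
        if first == "":
            raise ParseError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected '>' header, got {first[:30]!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(),
                                     description=desc))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as multi-FASTA wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


def read_aligned_fasta(path) -> tuple[list[str], list[str]]:
    """Read a gapped (aligned) FASTA; returns (labels, rows).  Rows must be
    rectangular."""
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise ParseError(f"{path}: no FASTA records found")
    if len({len(r) for r in rows}) != 1:
        raise ParseError(f"{path}: aligned rows have unequal lengths")
    return labels, rows


def write_aligned_fasta(labels: list[str], rows: list[str], path) -> None:
    with open(path, "w") as fh:
        for lab, row in zip(labels, rows):
            fh.write(f">{lab}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene/exon dialect with Parent links)

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path, feature_kinds: set[str] | None = None) -> list[GeneModel]:
    """Assemble GeneModels from a GFF3 file via gene features + Parent-linked
    exons.  Coordinates stay 1-based inclusive.
    """
    feature_kinds = feature_kinds or {"gene"}
    genes: dict[str, dict] = {}
    order: list[str] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _src, kind, start, end, _score, strand, _phase, attrs = fields
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attr = _parse_attributes(attrs)
            if kind in feature_kinds:
                gid = attr.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = dict(chromosome=seqid, strand=strand,
                                  start=int(start), end=int(end))
                order.append(gid)
            elif kind == "exon":
                parent = attr.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: exon without Parent")
                exons.setdefault(parent, []).append((int(start), int(end)))
    for parent in exons:
        if parent not in genes:
            raise ConsistencyError(f"{path}: exon Parent {parent!r} has no gene feature")
    models = []
    for gid in order:
        g = genes[gid]
        ex = sorted(exons.get(gid, [(g["start"], g["end"])]))
        models.append(GeneModel(gene_id=gid, chromosome=g["chromosome"],
                                strand=g["strand"], start=g["start"],
                                end=g["end"], exons=tuple(ex)))
    return models


def write_gff3(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write("\t".join([m.chromosome, "mapkminer", "gene", str(m.start),
                                str(m.end), ".", m.strand, ".", f"ID={m.gene_id}"]) + "\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write("\t".join([m.chromosome, "mapkminer", "exon", str(s),
                                    str(e), ".", m.strand, ".",
                                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"]) + "\n")


# ---------------------------------------------------------------------------
# packaged annotation fixture

def load_table2_fixture() -> AnnotationTable:
    """Load the packaged 36-gene sunflower MPK/MKK annotation table
    (28 MPK + 8 MKK rows: name, location, structure, localization, pI, Mw).
    """
    text = (resources.files("mapkminer") / "data" / "table2_ha_mapk.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    table = AnnotationTable(df)
    n_mpk, n_mkk = len(table.family("MPK")), len(table.family("MKK"))
    assert (n_mpk, n_mkk) == (28, 8), "packaged fixture corrupted"
    return table
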