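"""Exon/intron statistics, chromosome distribution, paralog dispersion."""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .io_model import AnnotationTable, GeneModel


def exon_intron_counts(model: GeneModel) -> tuple[int, int]:
    """(exons, introns) for one gene model; introns = exons - 1."""
    return model.n_exons, model.n_introns


@dataclass
class ChromosomeDistribution:
    per_chromosome: dict[str, dict]          # chrom -> {mpk, mkk, genes}
    absent: dict[str, list[str]]             # family -> chromosomes w/o genes

    def counts(self, chromosome: str) -> tuple[int, int]:
        entry = self.per_chromosome.get(chromosome, {"mpk": 0, "mkk": 0})
        return entry["mpk"], entry["mkk"]

    def total(self, chromosome: str) -> int:
        return sum(self.counts(chromosome))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"Chr": c, "MPK": v["mpk"], "MKK": v["mkk"],
             "Genes": ",".join(v["genes"])}
            for c, v in sorted(self.per_chromosome.items(),
                               key=lambda kv: _natural_key(kv[0]))
        ]
        return pd.DataFrame(rows)


def _natural_key(s: str):
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", s)]


def chromosome_distribution(table: AnnotationTable,
                            all_chromosomes: list[str] | None = None
                            ) -> ChromosomeDistribution:
    """Per-chromosome MPK/MKK tallies; ``all_chromosomes`` (if given)
    defines the universe for reporting family-absent chromosomes.
    """
    per: dict[str, dict] = {}
    for _, row in table.df.iterrows():
        entry = per.setdefault(row["Chr"], {"mpk": 0, "mkk": 0, "genes": []})
        entry["mpk" if row["Family"] == "MPK" else "mkk"] += 1
        entry["genes"].append(row["Name"])
    universe = all_chromosomes if all_chromosomes is not None else sorted(
        per, key=_natural_key)
    absent = {
        fam: [c for c in universe
              if per.get(c, {}).get(fam.lower(), 0) == 0]
        for fam in ("MPK", "MKK")
    }
    return ChromosomeDistribution(per_chromosome=per, absent=absent)


@dataclass
class ParalogGroup:
    family: str
    homolog_number: int
    members: list[tuple[str, str]]           # (gene name, chromosome)
    dispersed: bool
    same_chromosome_pairs: list[tuple[str, str]]


_NAME_RE = re.compile(r"^([A-Z][a-z]{1,3})(MPK|MKK)(\d+)(?:-(\d+))?$")


def parse_gene_name(name: str) -> tuple[str, str, int, int | None]:
    """Split a nomenclature string into (prefix, family, number, paralog)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"gene name {name!r} does not follow nomenclature")
    prefix, family, num, idx = m.groups()
    return prefix, family, int(num), int(idx) if idx else None


def paralog_dispersion(table: AnnotationTable,
                       family: str | None = None) -> list[ParalogGroup]:
    """Multi-member homolog-number groups and whether each spans multiple
    chromosomes; same-chromosome member pairs are listed per group.
    """
    groups: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for _, row in table.df.iterrows():
        _, fam, num, _ = parse_gene_name(row["Name"])
        if family is not None and fam != family:
            continue
        groups.setdefault((fam, num), []).append((row["Name"], row["Chr"]))
    out = []
    for (fam, num), members in sorted(groups.items()):
        if len(members) < 2:
            continue
        chroms = {c for _, c in members}
        same = [
            (a[0], b[0])
            for i, a in enumerate(members) for b in members[i + 1:]
            if a[1] == b[1]
        ]
        out.append(ParalogGroup(family=fam, homolog_number=num,
                                members=sorted(members),
                                dispersed=len(chroms) > 1,
                                same_chromosome_pairs=sorted(same)))
    return out


def karyotype_table(table: AnnotationTable) -> pd.DataFrame:
    """Text stand-in for a chromosome-map figure: one row per gene with its
    chromosome, start position, family and strand.
    """
    df = table.df
    out = pd.DataFrame({
        "chromosome": df["Chr"], "position": df["Start"],
        "name": df["Name"], "family": df["Family"], "strand": df["Str"],
    }).reset_index(drop=True)
    order = sorted(range(len(out)), key=lambda i: (
        _natural_key(out.loc[i, "chromosome"]), out.loc[i, "position"]))
    return out.iloc[order].reset_index(drop=True)
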