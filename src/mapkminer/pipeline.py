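"""End-to-end orchestration of the mining funnel:
identify -> classify -> name -> characterize -> express -> evolve.

Each stage writes plain TSV so a run directory is a complete, regenerable
report; the run log records every threshold and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import align_phylo, classify_name, expression, gene_structure, \
    profile_hmm, protein_props
from .io_model import AnnotationTable, ProteinRecord, read_fasta, read_gff3, \
    TABLE_COLUMNS
from .classify_name import ReferenceEntry


class ConfigError(ValueError):
    pass


DEFAULTS = {
    "evalue_max": 0.01,
    "n_null": 1000,
    "near_match_budget": 1,
    "seed": 0,
    "species_prefix": "Ha",
    "pseudocount_tpm": 1.0,
    "kmeans_k": 4,
    "bootstrap_reps": 100,
}


def read_reference_set(fasta_path, labels_path) -> list[ReferenceEntry]:
    """Reference kinases: FASTA plus a label TSV
    (id, family, clade, homolog_number, species_code)."""
    records = {r.id: r for r in read_fasta(fasta_path)}
    labels = pd.read_csv(labels_path, sep="\t")
    refs = []
    for _, row in labels.iterrows():
        if row["id"] not in records:
            raise ConfigError(f"label row {row['id']!r} missing from reference FASTA")
        refs.append(ReferenceEntry(
            id=row["id"], sequence=records[row["id"]].sequence,
            family=row["family"], clade=row["clade"],
            homolog_number=int(row["homolog_number"]),
            species_code=str(row.get("species_code", ""))))
    return refs


def write_reference_set(refs: list[ReferenceEntry], fasta_path, labels_path) -> None:
    from .io_model import write_fasta
    write_fasta([ProteinRecord(id=r.id, sequence=r.sequence) for r in refs],
                fasta_path)
    pd.DataFrame([
        dict(id=r.id, family=r.family, clade=r.clade,
             homolog_number=r.homolog_number, species_code=r.species_code)
        for r in refs
    ]).to_csv(labels_path, sep="\t", index=False)


def identify_and_classify(proteome: list[ProteinRecord],
                          refs: list[ReferenceEntry],
                          evalue_max: float = 0.01, n_null: int = 1000,
                          seed: int = 0, near_match_budget: int = 1):
    """HMM screen + motif gating + clade assignment for both families.

    Returns (family calls, clade assignments, hit tables by family).
    """
    by_id = {p.id: p for p in proteome}
    calls: dict[str, classify_name.FamilyCall] = {}
    assignments: list[classify_name.CladeAssignment] = []
    hit_tables = {}
    for family in ("MPK", "MKK"):
        fam_refs = [r for r in refs if r.family == family]
        if len(fam_refs) < 2:
            raise ConfigError(f"need >= 2 {family} references")
        msa = [r.sequence for r in fam_refs]
        if len({len(s) for s in msa}) != 1:
            aligned = [align_phylo.global_align(msa[0], s) for s in msa]
            msa = [a.aligned_b for a in aligned]   # crude anchor alignment
        hmm = profile_hmm.build_profile(msa)
        cal = profile_hmm.calibrate(
            hmm, n_null=n_null, lengths=[len(s) for s in msa], seed=seed)
        hits = profile_hmm.search_proteome(hmm, proteome, cal,
                                           evalue_max=evalue_max)
        hit_tables[family] = hits
        for hit in hits:
            if not hit.passes:
                continue
            call = classify_name.call_family(
                by_id[hit.protein_id], hit, family,
                near_match_budget=near_match_budget)
            if call.accepted and (hit.protein_id not in calls
                                  or hit.e_value < calls[hit.protein_id].hmm_evalue):
                calls[hit.protein_id] = call
    for call in calls.values():
        assignments.append(classify_name.assign_clade(
            call, by_id[call.protein_id], refs))
    return calls, assignments, hit_tables


def identification_metrics(seeds, n_mpk: int = 10, n_mkk: int = 5,
                           n_kinase_decoys: int = 20,
                           n_random_decoys: int = 200,
                           divergence: float = 0.15, n_null: int = 300,
                           calibration_seed: int = 1,
                           reference_seed: int = 0) -> dict:
    """Planted-truth recovery of the identification funnel over a set of
    proteome seeds (references and calibration are built once).

    Returns pooled family recall/precision and clade recovery.
    """
    from .synthetic_data import make_proteome, make_reference_set

    refs, aln = make_reference_set(reference_seed)
    models = {}
    for family in ("MPK", "MKK"):
        hmm = profile_hmm.build_profile(aln[family])
        cal = profile_hmm.calibrate(hmm, n_null=n_null,
                                    lengths=[len(aln[family][0])],
                                    seed=calibration_seed)
        models[family] = (hmm, cal)
    tp = n_planted = n_pred = clade_ok = 0
    for seed in seeds:
        proteome, truth = make_proteome(
            n_mpk, n_mkk, n_kinase_decoys, n_random_decoys,
            divergence=divergence, seed=seed, reference_seed=reference_seed)
        by_id = {p.id: p for p in proteome}
        calls = {}
        for family, (hmm, cal) in models.items():
            for hit in profile_hmm.search_proteome(hmm, proteome, cal):
                if not hit.passes:
                    continue
                call = classify_name.call_family(by_id[hit.protein_id], hit,
                                                 family)
                if call.accepted and (
                        hit.protein_id not in calls
                        or hit.e_value < calls[hit.protein_id].hmm_evalue):
                    calls[hit.protein_id] = call
        planted = truth.planted()
        n_planted += len(planted)
        n_pred += len(calls)
        for pid, call in calls.items():
            if pid in planted.index and planted.loc[pid, "family"] == call.family:
                tp += 1
                assignment = classify_name.assign_clade(call, by_id[pid], refs)
                clade_ok += assignment.clade == planted.loc[pid, "clade"]
    return {
        "recall": tp / n_planted if n_planted else float("nan"),
        "precision": tp / n_pred if n_pred else float("nan"),
        "clade_recovery": clade_ok / tp if tp else float("nan"),
        "n_planted": n_planted, "n_predicted": n_pred,
    }


def run_pipeline(config: dict, outdir) -> Path:
    """Run the configured stages; returns the report directory."""
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    for key in ("proteome", "refs", "refs_labels"):
        if key not in cfg:
            raise ConfigError(f"config is missing mandatory key {key!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteome = read_fasta(cfg["proteome"])
    refs = read_reference_set(cfg["refs"], cfg["refs_labels"])

    calls, assignments, hit_tables = identify_and_classify(
        proteome, refs, evalue_max=float(cfg["evalue_max"]),
        n_null=int(cfg["n_null"]), seed=int(cfg["seed"]),
        near_match_budget=int(cfg["near_match_budget"]))
    for family, hits in hit_tables.items():
        profile_hmm.hits_to_tsv(hits, outdir / f"hits_{family.lower()}.tsv")

    ev_rows = []
    for call in calls.values():
        ev = call.evidence
        ev_rows.append(dict(
            protein_id=call.protein_id, family=call.family,
            e_value=call.hmm_evalue, tloop_type=ev.tloop_type,
            order_ok=ev.order_ok, flags=";".join(call.flags),
            motifs=";".join(m for m in ev.hits if ev.hits[m])))
    pd.DataFrame(ev_rows).to_csv(outdir / "evidence.tsv", sep="\t", index=False)

    by_id = {p.id: p for p in proteome}
    gene_models = {}
    if cfg.get("gff"):
        gene_models = {m.gene_id: m for m in read_gff3(cfg["gff"])}
    named = bool(gene_models)
    if named:
        assignments = [a for a in assignments if a.protein_id in gene_models]
        names = classify_name.assign_names(
            assignments, gene_models, species_prefix=cfg["species_prefix"])
    else:
        names = None

    # per-gene result table in the annotation-table layout
    rows = []
    for i, a in enumerate(assignments):
        protein = by_id[a.protein_id]
        props = protein_props.property_record(protein)
        model = gene_models.get(a.protein_id)
        rows.append({
            "Name": names[i].name if named else a.protein_id,
            "Gene ID": a.protein_id,
            "Chr": model.chromosome if model else "-",
            "Str": model.strand if model else "-",
            "Start": model.start if model else 0,
            "End": model.end if model else 0,
            "PL": props.length,
            "Exo": model.n_exons if model else 1,
            "Int": model.n_introns if model else 0,
            "Sl": "-",
            "pI": round(props.pI, 2),
            "Mw": round(props.Mw, 2),
            "Family": a.family, "Clade": a.clade,
            "TopReference": a.top_reference,
            "TloopConsistent": a.tloop_consistent,
            "DockingDistance": a.docking_distance,
        })
    result = pd.DataFrame(rows, columns=TABLE_COLUMNS + [
        "Family", "Clade", "TopReference", "TloopConsistent", "DockingDistance"])
    result.to_csv(outdir / "genes.tsv", sep="\t", index=False)

    # family summaries + docking report + distributions
    if len(result):
        table = AnnotationTable(result[TABLE_COLUMNS].copy())
        summaries = []
        for family in ("MPK", "MKK"):
            if len(table.family(family)):
                summaries.append(vars(protein_props.summarize_family(table, family)))
        pd.DataFrame(summaries).to_csv(outdir / "family_summary.tsv",
                                       sep="\t", index=False)
        dist = gene_structure.chromosome_distribution(table)
        dist.to_frame().to_csv(outdir / "chromosome_distribution.tsv",
                               sep="\t", index=False)
        if named:
            groups = gene_structure.paralog_dispersion(table)
            pd.DataFrame([
                dict(family=g.family, homolog_number=g.homolog_number,
                     members=";".join(n for n, _ in g.members),
                     dispersed=g.dispersed,
                     same_chromosome_pairs=";".join(
                         f"{a}|{b}" for a, b in g.same_chromosome_pairs))
                for g in groups
            ]).to_csv(outdir / "paralogs.tsv", sep="\t", index=False)
            gene_structure.karyotype_table(table).to_csv(
                outdir / "karyotype.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"Clade": c, "Consensus": s}
         for c, s in classify_name.DOCKING_CONSENSUS.items()]
    ).to_csv(outdir / "docking_consensus.tsv", sep="\t", index=False)

    # expression
    if cfg.get("quant") and cfg.get("design"):
        q = expression.QuantTable.from_tsv(cfg["quant"], cfg["design"])
        accepted_ids = [a.protein_id for a in assignments]
        sub = q.tpm.loc[[g for g in q.tpm.index if g in accepted_ids]]
        q = expression.QuantTable(tpm=sub, samples=q.samples)
        de = expression.log2fc(q, pseudocount=float(cfg["pseudocount_tpm"]))
        de.to_csv(outdir / "log2fc.tsv", sep="\t")
        z, dropped = expression.standardize(de)
        if len(z) >= int(cfg["kmeans_k"]):
            km = expression.kmeans_cluster(z, k=int(cfg["kmeans_k"]),
                                           seed=int(cfg["seed"]))
            km.labels.rename("cluster").to_csv(outdir / "kmeans.tsv", sep="\t")
            hc = expression.hclust_correlation_average(z, k=int(cfg["kmeans_k"]))
            hc.labels.rename("cluster").to_csv(outdir / "hclust.tsv", sep="\t")
        expression.heatmap_matrix(z).to_csv(outdir / "heatmap.tsv", sep="\t")

    log = dict(cfg)
    log["n_proteome"] = len(proteome)
    log["n_accepted"] = len(assignments)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({k: str(v) for k, v in log.items()}, fh, indent=2)
    return outdir
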