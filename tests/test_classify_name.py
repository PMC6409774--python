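import pytest

from mapkminer.classify_name import (DOCKING_CONSENSUS, ReferenceEntry,
                                     assign_clade, assign_names, call_family,
                                     validate_docking_consensus)
from mapkminer.gene_structure import parse_gene_name
from mapkminer.io_model import GeneModel, ProteinRecord
from mapkminer.profile_hmm import HmmHit
from mapkminer.synthetic_data import (MPK_MOTIF_LAYOUT, make_proteome,
                                      make_reference_set)
from mapkminer.pipeline import identify_and_classify


def _hit(pid, e=1e-30, passes=True):
    return HmmHit(protein_id=pid, bit_score=500.0, e_value=e, passes=passes)


@pytest.fixture(scope="module")
def planted():
    proteome, truth = make_proteome(10, 5, 4, 0, divergence=0.15, seed=2)
    return proteome, truth


class TestCallFamily:
    def test_planted_mpk_accepted(self, planted):
        proteome, truth = planted
        rec = next(p for p in proteome
                   if truth.df.loc[p.id, "kind"] == "planted"
                   and truth.df.loc[p.id, "family"] == "MPK")
        call = call_family(rec, _hit(rec.id), "MPK")
        assert call.accepted and call.family == "MPK"
        assert "tloop_absent" not in call.flags

    def test_tloop_ablated_decoy_rejected(self, planted):
        proteome, truth = planted
        rec = next(p for p in proteome
                   if truth.df.loc[p.id, "decoy_class"] == "MPK_ablated")
        call = call_family(rec, _hit(rec.id), "MPK")
        assert not call.accepted
        assert "tloop_absent" in call.flags

    def test_missing_ploop_accepted_with_flag(self):
        # complete kinase core but no P-loop (the short-MPK precedent)
        seq = ("M" * 10 + "VAIKKIANSF" + "A" * 10 + "HRDLKPSN" + "A" * 10
               + "DFGLAR" + "A" * 10 + "TEY" + "A" * 10 + "TRWYRAPE" + "A" * 10)
        rec = ProteinRecord(id="p", sequence=seq)
        call = call_family(rec, _hit("p"), "MPK")
        assert call.accepted
        assert "ploop_absent" in call.flags

    def test_hmm_fail_blocks_acceptance(self, planted):
        proteome, truth = planted
        rec = next(p for p in proteome
                   if truth.df.loc[p.id, "family"] == "MPK")
        call = call_family(rec, _hit(rec.id, e=0.5, passes=False), "MPK")
        assert not call.accepted

    def test_wrong_protein_rejected(self, planted):
        proteome, _ = planted
        with pytest.raises(ValueError):
            call_family(proteome[0], _hit("someone_else"), "MPK")


class TestAssignClade:
    def test_identical_to_reference(self, reference_set):
        refs, _ = reference_set
        ref = next(r for r in refs if r.family == "MPK" and r.clade == "A")
        rec = ProteinRecord(id="q", sequence=ref.sequence)
        call = call_family(rec, _hit("q"), "MPK")
        assert call.accepted
        a = assign_clade(call, rec, refs)
        assert a.clade == "A" and a.top_reference == ref.id
        assert a.docking_distance == 0
        assert a.tloop_consistent

    def test_tey_in_clade_c_flagged_inconsistent(self, reference_set):
        refs, _ = reference_set
        ref = next(r for r in refs if r.family == "MPK" and r.clade == "C")
        # swap the TDY activation loop for TEY, keeping everything else
        off, _ = MPK_MOTIF_LAYOUT["T-loop"]
        seq = ref.sequence[:off] + "TEY" + ref.sequence[off + 3:]
        rec = ProteinRecord(id="q", sequence=seq)
        call = call_family(rec, _hit("q"), "MPK")
        a = assign_clade(call, rec, refs)
        assert a.clade == "C"
        assert not a.tloop_consistent

    def test_clade_recovery_on_synthetic_proteomes(self, reference_set):
        refs, _ = reference_set
        total = correct = 0
        for seed in range(1, 6):
            proteome, truth = make_proteome(8, 4, 0, 0, divergence=0.15,
                                            seed=seed)
            for rec in proteome:
                family = truth.df.loc[rec.id, "family"]
                call = call_family(rec, _hit(rec.id), family)
                if not call.accepted:
                    continue
                a = assign_clade(call, rec, refs)
                total += 1
                correct += a.clade == truth.df.loc[rec.id, "clade"]
        assert total >= 50
        assert correct / total >= 0.95

    def test_no_references_rejected(self, planted, reference_set):
        refs, _ = reference_set
        proteome, truth = planted
        rec = next(p for p in proteome if truth.df.loc[p.id, "family"] == "MPK")
        call = call_family(rec, _hit(rec.id), "MPK")
        with pytest.raises(ValueError):
            assign_clade(call, rec, [r for r in refs if r.family == "MKK"])


def _model(pid, chrom, start):
    return GeneModel(gene_id=pid, chromosome=chrom, strand="+", start=start,
                     end=start + 99, exons=((start, start + 99),))


class TestAssignNames:
    def _assignments(self, reference_set, n=2):
        refs, _ = reference_set
        proteome, truth = make_proteome(8, 0, 0, 0, divergence=0.1, seed=3)
        out = []
        for rec in proteome:
            call = call_family(rec, _hit(rec.id), "MPK")
            out.append(assign_clade(call, rec, refs))
        return out

    def test_paralogs_numbered_by_chromosome_order(self, reference_set):
        refs, _ = reference_set
        ref6 = next(r for r in refs if r.family == "MPK"
                    and r.homolog_number == 6)
        assignments = []
        for pid in ("gA", "gB"):
            rec = ProteinRecord(id=pid, sequence=ref6.sequence)
            call = call_family(rec, _hit(pid), "MPK")
            assignments.append(assign_clade(call, rec, refs))
        models = {"gA": _model("gA", "Chr11", 500),
                  "gB": _model("gB", "Chr1", 900)}
        names = assign_names(assignments, models, species_prefix="Ha")
        by_id = dict(zip(("gA", "gB"), names))
        assert by_id["gB"].name == "HaMPK6-1"   # chromosome 1 before 11
        assert by_id["gA"].name == "HaMPK6-2"

    def test_singleton_gets_no_suffix(self, reference_set):
        refs, _ = reference_set
        ref7 = next(r for r in refs if r.family == "MPK"
                    and r.homolog_number == 7)
        rec = ProteinRecord(id="g", sequence=ref7.sequence)
        call = call_family(rec, _hit("g"), "MPK")
        a = assign_clade(call, rec, refs)
        names = assign_names([a], {"g": _model("g", "Chr2", 1)})
        assert names[0].name == "HaMPK7"
        assert names[0].paralog_index is None

    def test_stable_under_permutation(self, reference_set):
        refs, _ = reference_set
        ref6 = next(r for r in refs if r.family == "MPK"
                    and r.homolog_number == 6)
        assignments = []
        models = {}
        for i, pid in enumerate(("x", "y", "z")):
            rec = ProteinRecord(id=pid, sequence=ref6.sequence)
            call = call_family(rec, _hit(pid), "MPK")
            assignments.append(assign_clade(call, rec, refs))
            models[pid] = _model(pid, f"Chr{3 - i:02d}", 10)
        fwd = assign_names(assignments, models)
        rev = assign_names(assignments[::-1], models)
        assert {n.name for n in fwd} == {n.name for n in rev}
        assert dict(zip([a.protein_id for a in assignments], [n.name for n in fwd])) == \
               dict(zip([a.protein_id for a in assignments[::-1]], [n.name for n in rev]))

    def test_missing_gene_model_rejected(self, reference_set):
        refs, _ = reference_set
        ref7 = next(r for r in refs if r.family == "MPK" and r.homolog_number == 7)
        rec = ProteinRecord(id="g", sequence=ref7.sequence)
        call = call_family(rec, _hit("g"), "MPK")
        a = assign_clade(call, rec, refs)
        with pytest.raises(KeyError):
            assign_names([a], {})

    def test_names_parse_back_losslessly(self):
        for name in ("HaMPK6-1", "HaMPK7", "HaMKK23-4", "AtMKK3"):
            prefix, family, num, idx = parse_gene_name(name)
            rebuilt = f"{prefix}{family}{num}" + (f"-{idx}" if idx else "")
            assert rebuilt == name


class TestEndToEnd:
    def test_family_precision_recall_at_moderate_divergence(self, reference_set):
        refs, _ = reference_set
        proteome, truth = make_proteome(10, 5, 10, 60, divergence=0.15, seed=6)
        calls, assignments, _ = identify_and_classify(
            proteome, refs, n_null=200, seed=1)
        planted = truth.planted()
        pred = {a.protein_id: a.family for a in assignments}
        tp = sum(1 for pid in planted["id"]
                 if pred.get(pid) == planted.loc[pid, "family"])
        recall = tp / len(planted)
        precision = tp / max(len(pred), 1)
        assert recall >= 0.95 and precision >= 0.95

    def test_docking_consensus_table(self):
        validate_docking_consensus()
        assert DOCKING_CONSENSUS["A"] == "KMLVFDPNKRIVEEAL"
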