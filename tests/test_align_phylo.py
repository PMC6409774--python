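import itertools
import math

import numpy as np
import pytest

from mapkminer.align_phylo import (DistanceMatrix, ScoringScheme,
                                   _bipartitions, bootstrap_support,
                                   distance_matrix_from_alignment,
                                   from_newick, global_align, is_monophyletic,
                                   local_score, nj_tree, p_distance,
                                   poisson_correct, root_with_outgroup,
                                   to_newick, top_hits)
from mapkminer.io_model import ProteinRecord
from mapkminer.synthetic_data import make_proteome, make_reference_set

SCHEME = ScoringScheme()
B62 = SCHEME.matrix()


def brute_force_global(a, b, scheme=SCHEME):
    """Enumerate every global alignment (as monotone edit paths) of two short
    sequences under affine gap scoring."""
    mat = scheme.matrix()
    best = -math.inf

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + mat[a[i], b[j]], "M")
        # affine convention: first gap position costs gap_open, each further
        # position gap_extend
        if i < len(a):
            cost = scheme.gap_extend if prev == "A" else scheme.gap_open
            rec(i + 1, j, score + cost, "A")
        if j < len(b):
            cost = scheme.gap_extend if prev == "B" else scheme.gap_open
            rec(i, j + 1, score + cost, "B")

    rec(0, 0, 0.0, "-")
    return best


class TestPairwise:
    def test_identical_triple_a(self):
        aln = global_align("AAA", "AAA")
        assert aln.score == 3 * B62["A", "A"] == 12
        assert aln.identity_fraction == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("A", "")

    def test_score_is_symmetric(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(letters, int(rng.integers(3, 12))))
            b = "".join(rng.choice(letters, int(rng.integers(3, 12))))
            assert global_align(a, b).score == global_align(b, a).score

    def test_matches_brute_force_enumeration(self, rng):
        letters = list("ACDEFG")
        for _ in range(15):
            a = "".join(rng.choice(letters, int(rng.integers(1, 5))))
            b = "".join(rng.choice(letters, int(rng.integers(1, 5))))
            assert global_align(a, b).score == pytest.approx(
                brute_force_global(a, b)), (a, b)

    def test_degapping_recovers_inputs(self):
        aln = global_align("MKTEY", "MTEY")
        assert aln.aligned_a.replace("-", "") == "MKTEY"
        assert aln.aligned_b.replace("-", "") == "MTEY"


class TestTopHits:
    def test_identical_entry_ranks_first(self, reference_set):
        refs, _ = reference_set
        db = [ProteinRecord(id=r.id, sequence=r.sequence) for r in refs]
        hits = top_hits(db[3], db, k=5)
        assert hits[0][0] == db[3].id

    def test_ranking_equals_exhaustive_scoring(self, rng):
        proteome, _ = make_proteome(5, 3, 5, 12, divergence=0.2, seed=13)
        db = proteome[:25]
        query = db[0]
        ranked = top_hits(query, db, k=len(db))
        exhaustive = sorted(
            [(r.id, local_score(query, r)) for r in db],
            key=lambda t: -t[1])
        assert [r[1] for r in ranked] == [e[1] for e in exhaustive]

    def test_k_validation_and_default(self):
        db = [ProteinRecord(id="a", sequence="MTEY")]
        with pytest.raises(ValueError):
            top_hits(db[0], db, k=0)
        import inspect
        assert inspect.signature(top_hits).parameters["k"].default == 10


class TestDistances:
    def test_identity_gives_zero(self):
        assert p_distance("MTEY", "MTEY") == 0.0
        assert poisson_correct(0.0) == 0.0

    def test_quarter_mismatch(self):
        p = p_distance("AAAA", "AAAT")
        assert p == 0.25
        assert poisson_correct(p) == pytest.approx(-math.log(0.75))

    def test_gap_columns_excluded(self):
        assert p_distance("A-AA", "ATAA") == 0.0  # over 3 comparable columns
        assert p_distance("A-CA", "ATAA") == pytest.approx(1 / 3)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            poisson_correct(1.0)


def _tree_distances(newick):
    """Leaf-to-leaf path lengths of a newick tree (independent of NJ)."""
    tree = from_newick(newick)
    leaves = tree.get_terminals()
    out = {}
    for x, y in itertools.combinations(leaves, 2):
        out[frozenset((x.name, y.name))] = tree.distance(x, y)
    return out


def random_additive_tree(labels, rng):
    """Random binary newick tree with random branch lengths (oracle input)."""
    def bl():
        return round(float(rng.uniform(0.5, 3.0)), 3)
    nodes = [f"{lab}:{bl()}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl()}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # ((a:2,b:3):1,(c:4,d:5)); pairwise path lengths are additive
        d = {("a", "b"): 5, ("a", "c"): 7, ("a", "d"): 8,
             ("b", "c"): 8, ("b", "d"): 9, ("c", "d"): 9}
        labels = ["a", "b", "c", "d"]
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            m[i, j] = m[j, i] = v
        tree = nj_tree(DistanceMatrix(labels, m))
        got = _tree_distances(to_newick(tree))
        for (x, y), v in d.items():
            assert got[frozenset((x, y))] == pytest.approx(v)
        assert frozenset({"a", "b"}) in _bipartitions(tree) or \
               frozenset({"c", "d"}) in _bipartitions(tree)

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        got = _tree_distances(to_newick(tree))
        assert got[frozenset(("a", "b"))] == pytest.approx(3)
        assert got[frozenset(("a", "c"))] == pytest.approx(4)
        assert got[frozenset(("b", "c"))] == pytest.approx(5)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0., 1.], [1., 0.]])))

    def test_random_additive_matrices_exact(self, rng):
        """NJ reconstructs random additive trees (<= 8 taxa) exactly."""
        for trial in range(10):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            # random binary tree via sequential attachment, random lengths
            newick = random_additive_tree(labels, rng)
            want = _tree_distances(newick)
            m = np.zeros((n, n))
            for i, x in enumerate(labels):
                for j, y in enumerate(labels):
                    if i < j:
                        m[i, j] = m[j, i] = want[frozenset((x, y))]
            tree = nj_tree(DistanceMatrix(labels, m))
            got = _tree_distances(to_newick(tree))
            for key, v in want.items():
                assert got[key] == pytest.approx(v, abs=1e-6), newick

    def test_taxon_order_invariance(self, rng):
        n = 6
        labels = [f"t{i}" for i in range(n)]
        newick = random_additive_tree(labels, rng)
        want = _tree_distances(newick)
        m = np.zeros((n, n))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    m[i, j] = m[j, i] = want[frozenset((x, y))]
        t1 = nj_tree(DistanceMatrix(labels, m))
        perm = list(rng.permutation(n))
        t2 = nj_tree(DistanceMatrix([labels[i] for i in perm],
                                    m[np.ix_(perm, perm)]))
        assert _bipartitions(t1) == _bipartitions(t2)

    def test_agrees_with_skbio_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj
        d = np.array([[0, 5, 9, 9, 8], [5, 0, 10, 10, 9],
                      [9, 10, 0, 8, 7], [9, 10, 8, 0, 3],
                      [8, 9, 7, 3, 0]], dtype=float)
        labels = list("abcde")
        ours = nj_tree(DistanceMatrix(labels, d))
        theirs = sknj(SkDM(d, ids=labels))
        their_splits = set()
        all_l = frozenset(labels)
        for node in theirs.non_tips():
            s = frozenset(t.name for t in node.tips())
            if 2 <= len(s) <= len(labels) - 2:
                their_splits.add(min(s, all_l - s,
                                     key=lambda x: (len(x), tuple(sorted(x)))))
        assert _bipartitions(ours) == their_splits


class TestBootstrapAndRooting:
    def test_separating_edge_gets_full_support(self):
        # two tight 3-leaf clusters, very distant from each other
        rows = ["AAAAAAAAAACCCCCCCCCC", "AAAAAAAAAACCCCCCCCCC",
                "AAAAAAAAAACCCCCCCCCD", "WWWWWWWWGGGGCCCCCCCC",
                "WWWWWWWWGGGGCCCCCCCG", "WWWWWWWWGGGGCCCCCCCC"]
        labels = [f"s{i}" for i in range(6)]
        tree = bootstrap_support(labels, rows, n_reps=100, seed=21)
        split = frozenset(labels[:3])
        supports = {frozenset(t.name for t in c.get_terminals()): c.confidence
                    for c in tree.get_nonterminals()}
        matched = [v for k, v in supports.items()
                   if k in (split, frozenset(labels[3:]))]
        assert matched and all(v == 100 for v in matched)

    def test_fixed_seed_reproducible(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKV", "ACDEFGWIKL", "MCDEFGHIKL",
                "ACPEFGHIKL"]
        labels = list("abcde")
        t1 = bootstrap_support(labels, rows, n_reps=50, seed=4)
        t2 = bootstrap_support(labels, rows, n_reps=50, seed=4)
        assert to_newick(t1) == to_newick(t2)

    def test_rooting_preserves_leaves_and_monophyly(self):
        tree = from_newick("((a:1,b:1):1,(c:1,d:1):1,o:5);")
        rooted = root_with_outgroup(tree, "o")
        assert {t.name for t in rooted.get_terminals()} == set("abcdo")
        assert is_monophyletic(rooted, {"a", "b"})
        assert not is_monophyletic(rooted, {"a", "c"})

    def test_missing_outgroup_rejected(self):
        tree = from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(KeyError):
            root_with_outgroup(tree, "zz")
        with pytest.raises(KeyError):
            is_monophyletic(tree, {"a", "zz"})

    def test_newick_round_trip(self):
        text = "((a:1.500000000,b:2.000000000)90:0.700000000,(c:1.000000000,d:1.200000000)75:0.300000000,e:2.200000000):0.000000000;"
        tree = from_newick(text)
        back = from_newick(to_newick(tree))
        assert _bipartitions(back) == _bipartitions(tree)
        d1, d2 = _tree_distances(to_newick(tree)), _tree_distances(text)
        for k in d2:
            assert d1[k] == pytest.approx(d2[k], abs=1e-9)
        sup = {frozenset(t.name for t in c.get_terminals()): c.confidence
               for c in back.get_nonterminals() if c.confidence is not None}
        assert sup[frozenset({"a", "b"})] == 90
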