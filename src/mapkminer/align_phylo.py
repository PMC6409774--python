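"""Pairwise alignment, distances, neighbor-joining with bootstrap, rooting.

Pairwise alignment (Needleman-Wunsch / Smith-Waterman with BLOSUM62 and
affine gaps) drives the top-hit orthology search; trees are built by
Saitou-Nei neighbor joining on Poisson-corrected p-distances, a distance
stand-in for likelihood inference.  Trees are Bio.Phylo objects, so newick
round-trips, outgroup rooting and traversal use the standard toolkit.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from Bio import Phylo
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Phylo.BaseTree import Clade, Tree


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap protein scoring (BLAST-like defaults)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_fraction: float


def _aligner(scheme: ScoringScheme, mode: str) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = scheme.matrix()
    al.open_gap_score = scheme.gap_open
    al.extend_gap_score = scheme.gap_extend
    return al


def _seq(x) -> str:
    return x.sequence if hasattr(x, "sequence") else str(x)


def global_align(a, b, scheme: ScoringScheme = ScoringScheme()) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch alignment under affine gaps."""
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(scheme, "global").align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    comparable = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    return PairwiseAlignment(aligned_a=ga, aligned_b=gb, score=float(aln.score),
                             identity_fraction=ident / comparable if comparable else 0.0)


def local_score(a, b, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Smith-Waterman score (used by the top-hit search)."""
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    return float(_aligner(scheme, "local").score(sa, sb))


def top_hits(query, database, scheme: ScoringScheme = ScoringScheme(),
             k: int = 10) -> list[tuple[str, float]]:
    """The k best local-alignment hits of ``query`` in ``database``,
    descending score, database order breaking ties.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not database:
        raise ValueError("database is empty")
    scored = [(rec.id, local_score(query, rec, scheme)) for rec in database]
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][1], i))
    return [scored[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# distances

def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing sites over comparable (gap-free) columns."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    comparable = mismatch = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-." or y in "-.":
            continue
        comparable += 1
        if x != y:
            mismatch += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return mismatch / comparable


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p)."""
    if p >= 1.0:
        raise ValueError("p-distance of 1 gives infinite corrected distance")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and nonnegative")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def distance_matrix_from_alignment(labels: list[str], rows: list[str]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances with pairwise gap deletion."""
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_correct(p_distance(rows[i], rows[j]))
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.  Negative branch lengths are clamped to
    zero with the deficit transferred to the sibling branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.d.copy()
    nodes: list[Clade] = [Clade(name=lab) for lab in dm.labels]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        ca, cb = nodes[a], nodes[b]
        ca.branch_length = li
        cb.branch_length = lj
        parent = Clade(clades=[ca, cb])
        nodes.append(parent)
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (a, b):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[a, k] + d[b, k] - dij)
        active = [k for k in active if k not in (a, b)] + [new]

    a, b = active
    nodes[b].branch_length = max(d[a, b], 0.0)
    root = nodes[a]
    if root.is_terminal():
        # make the remaining leaf the root's sibling under a trifurcation-safe root
        root = Clade(clades=[nodes[a], nodes[b]])
        nodes[a].branch_length = 0.0
    else:
        root.clades.append(nodes[b])
        root.branch_length = None
    return Tree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap

def _bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial leaf-set splits, canonicalized to the smaller side
    (ties broken lexicographically)."""
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    out = set()
    for clade in tree.get_nonterminals():
        leaves = frozenset(t.name for t in clade.get_terminals())
        other = all_leaves - leaves
        if len(leaves) < 2 or len(other) < 2:
            continue
        canon = min(leaves, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def bootstrap_support(labels: list[str], rows: list[str], n_reps: int = 100,
                      seed: int = 0) -> Tree:
    """NJ tree on the full alignment with internal-edge supports from
    ``n_reps`` column-resampled replicates (replicate frequency x 100).
    """
    if len(rows) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment")
    full = nj_tree(distance_matrix_from_alignment(labels, rows))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        res_rows = ["".join(r[c] for c in cols) for r in rows]
        try:
            rep = nj_tree(distance_matrix_from_alignment(labels, res_rows))
        except ValueError:
            continue   # replicate produced a saturated (p=1) pair
        for bp in _bipartitions(rep):
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = frozenset(labels)
    for clade in full.get_nonterminals():
        leaves = frozenset(t.name for t in clade.get_terminals())
        other = all_leaves - leaves
        if len(leaves) < 2 or len(other) < 2:
            continue
        canon = min(leaves, other, key=lambda s: (len(s), tuple(sorted(s))))
        clade.confidence = int(round(100.0 * counts.get(canon, 0) / n_reps))
    return full


# ---------------------------------------------------------------------------
# rooting / monophyly / newick

def root_with_outgroup(tree: Tree, label: str) -> Tree:
    if not any(t.name == label for t in tree.get_terminals()):
        raise KeyError(f"outgroup label {label!r} not in tree")
    tree.root_with_outgroup({"name": label})
    return tree


def is_monophyletic(tree: Tree, labels: set[str]) -> bool:
    """True iff ``labels`` is exactly the leaf set of one clade (on the
    unrooted tree: either side of some edge).
    """
    leaves = {t.name for t in tree.get_terminals()}
    missing = set(labels) - leaves
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    target = frozenset(labels)
    if len(target) in (1, len(leaves)):
        return True
    complement = frozenset(leaves - target)
    for clade in tree.find_clades():
        cl = frozenset(t.name for t in clade.get_terminals())
        if cl == target or cl == complement:
            return True
    return False


def to_newick(tree: Tree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%.9f")
    return buf.getvalue().strip()


def from_newick(text: str) -> Tree:
    return Phylo.read(io.StringIO(text), "newick")
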