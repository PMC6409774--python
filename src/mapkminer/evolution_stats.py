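"""Tajima's relative rate test on triplets and Tajima's D neutrality test.

Both run on residue alignments of any alphabet.  The relative rate test
counts lineage-unique substitutions against an outgroup and applies a
1-df chi-square test; the neutrality test compares mean pairwise
diversity with the segregating-site expectation after a site-coverage
filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2

GAP_CHARS = set("-.")
AMBIGUOUS = set("X?*")


class NoPolymorphismError(ValueError):
    pass


def _clean(ch: str) -> bool:
    return ch not in GAP_CHARS and ch not in AMBIGUOUS


def coverage_filter(msa: list[str], min_coverage: float = 0.95) -> list[int]:
    """Indices of columns whose fraction of unambiguous, non-gap residues
    is at least ``min_coverage``.
    """
    if not msa:
        raise ValueError("empty alignment")
    ncol = len(msa[0])
    if any(len(s) != ncol for s in msa):
        raise ValueError("ragged alignment")
    n = len(msa)
    kept = [
        c for c in range(ncol)
        if sum(1 for s in msa if _clean(s[c])) / n >= min_coverage
    ]
    if not kept:
        raise ValueError("no columns survive the coverage filter")
    return kept


def chi2_upper_tail(x: float, df: int = 1) -> float:
    """Upper-tail chi-square probability."""
    if x < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    return float(_chi2.sf(x, df))


@dataclass(frozen=True)
class TripletRateTest:
    n_sites_used: int
    m_a: int
    m_b: int
    chi2: float
    p: float


def relative_rate_test(a: str, b: str, outgroup: str) -> TripletRateTest:
    """Tajima's relative rate test on an aligned triplet.

    Sites with any gap or ambiguity in the triplet are excluded.  m_a
    counts sites where only lineage a differs (a != b, a != outgroup,
    b == outgroup); m_b symmetrically.  chi2 = (m_a - m_b)^2 / (m_a + m_b)
    on 1 df; with no lineage-unique sites, chi2 = 0 and p = 1.
    """
    if not (len(a) == len(b) == len(outgroup)):
        raise ValueError("triplet sequences must have equal lengths")
    m_a = m_b = used = 0
    for x, y, o in zip(a.upper(), b.upper(), outgroup.upper()):
        if not (_clean(x) and _clean(y) and _clean(o)):
            continue
        used += 1
        if x != y:
            if y == o:
                m_a += 1
            elif x == o:
                m_b += 1
    if m_a + m_b == 0:
        return TripletRateTest(used, 0, 0, 0.0, 1.0)
    stat = (m_a - m_b) ** 2 / (m_a + m_b)
    return TripletRateTest(used, m_a, m_b, stat, chi2_upper_tail(stat, df=1))


@dataclass(frozen=True)
class NeutralityResult:
    n_sequences: int
    n_sites_used: int
    S: int
    pi: float            # mean pairwise difference count
    pi_per_site: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float


def tajima_coefficients(n: int) -> dict[str, float]:
    """The closed-form normalization coefficients of Tajima's D for sample
    size ``n``."""
    if n < 2:
        raise ValueError("need >= 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_D(msa: list[str], min_coverage: float = 0.95) -> NeutralityResult:
    """Tajima's neutrality test on an alignment (any residue alphabet).

    Columns failing the coverage filter are dropped; a segregating site is
    any kept column with >= 2 observed states; pi is the mean per-pair
    mismatch count with pairwise deletion inside kept columns.  D is on
    the count scale consistently with S.
    """
    n = len(msa)
    if n < 4:
        raise ValueError("neutrality test needs >= 4 sequences")
    cols = coverage_filter(msa, min_coverage)
    seqs = [s.upper() for s in msa]

    S = 0
    for c in cols:
        states = {s[c] for s in seqs if _clean(s[c])}
        if len(states) >= 2:
            S += 1
    if S == 0:
        raise NoPolymorphismError("no segregating sites; D is undefined")

    total = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(
                1 for c in cols
                if _clean(seqs[i][c]) and _clean(seqs[j][c])
                and seqs[i][c] != seqs[j][c]
            )
            total += diff
            pairs += 1
    pi = total / pairs

    k = tajima_coefficients(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = (pi - S / k["a1"]) / np.sqrt(var)
    return NeutralityResult(
        n_sequences=n, n_sites_used=len(cols), S=S, pi=pi,
        pi_per_site=pi / len(cols), D=float(D), **k)
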