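"""Profile hidden Markov model screening of a proteome.

A Plan-7-style profile (match/insert/delete states, local alignment with
free entry/exit at match states) is estimated from a reference multiple
alignment, scored by Viterbi in log2-odds against a background null, and
calibrated to e-values by fitting a Gumbel distribution to scores of
background-sampled sequences.  Scoring is Viterbi-only so that an exact
brute-force path-enumeration oracle exists for small models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gumbel_r

from .io_model import AMINO_ACIDS, ProteinRecord

NEG_INF = float("-inf")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class DegenerateModelError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """Profile HMM over the 20-letter amino-acid alphabet.

    All parameter arrays hold probabilities; scoring converts to log2 odds
    against ``background``.  ``match_emissions`` is (L, 20); transition
    vectors are indexed by source match state j = 0..L where state 0 is the
    begin state (`t_mm[j]` is M_j -> M_{j+1}; insert states exist between
    matches, delete states parallel the matches).
    """

    length: int
    match_emissions: np.ndarray          # (L, 20)
    insert_emissions: np.ndarray         # (20,)
    background: np.ndarray               # (20,)
    t_mm: np.ndarray                     # (L,)  M_j -> M_{j+1}, j=0..L-1
    t_mi: np.ndarray                     # (L,)  M_j -> I_j
    t_md: np.ndarray                     # (L,)  M_j -> D_{j+1}
    t_im: np.ndarray                     # (L,)  I_j -> M_{j+1}
    t_ii: np.ndarray                     # (L,)  I_j -> I_j
    t_dm: np.ndarray                     # (L,)  D_j -> M_{j+1}
    t_dd: np.ndarray                     # (L,)  D_j -> D_{j+1}

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DegenerateModelError("profile needs >= 1 match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not math.isclose(float(self.insert_emissions.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("insert emissions must sum to 1")

    # cached log2-odds scores, built lazily; zero probabilities are floored
    # at IMPOSSIBLE instead of -inf so the DP never forms nan = inf - inf
    IMPOSSIBLE = -1.0e5

    def _floor(self, arr: np.ndarray) -> np.ndarray:
        arr[np.isneginf(arr)] = self.IMPOSSIBLE
        return arr

    def _scores(self):
        if not hasattr(self, "_cache"):
            with np.errstate(divide="ignore"):
                ms = self._floor(np.log2(self.match_emissions)
                                 - np.log2(self.background))
                iscore = self._floor(np.log2(self.insert_emissions)
                                     - np.log2(self.background))
                trans = {k: self._floor(np.log2(getattr(self, k)))
                         for k in ("t_mm", "t_mi", "t_md", "t_im", "t_ii",
                                   "t_dm", "t_dd")}
            self._cache = (ms, iscore, trans)
        return self._cache

    def to_json(self, path) -> None:
        doc = {"format": "mapkminer-profile-hmm", "version": 1,
               "length": self.length,
               "alphabet": AMINO_ACIDS,
               "match_emissions": self.match_emissions.tolist(),
               "insert_emissions": self.insert_emissions.tolist(),
               "background": self.background.tolist()}
        for k in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            doc[k] = getattr(self, k).tolist()
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "mapkminer-profile-hmm":
            raise ValueError(f"{path}: not a profile document")
        kwargs = {k: np.asarray(doc[k]) for k in
                  ("match_emissions", "insert_emissions", "background",
                   "t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")}
        return cls(length=doc["length"], **kwargs)


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel (mu, lambda) fitted to null Viterbi scores."""

    mu: float
    lam: float
    database_size: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise CalibrationError("lambda must be positive")

    def evalue(self, bit_score: float) -> float:
        # Gumbel upper tail: P(S > s) = 1 - exp(-exp(-lam (s - mu)))
        tail = gumbel_r.sf(bit_score, loc=self.mu, scale=1.0 / self.lam)
        return float(self.database_size * tail)


@dataclass(frozen=True)
class HmmHit:
    protein_id: str
    bit_score: float
    e_value: float
    passes: bool


def build_profile(msa: list[str], match_rule: float = 0.5,
                  pseudocount: float = 1.0,
                  background: np.ndarray | None = None) -> ProfileHMM:
    """Estimate a profile from a rectangular gapped alignment.

    Columns whose gap fraction is < ``match_rule`` become match states;
    Laplace pseudocounts are added to emission and transition counts.
    """
    if len(msa) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    ncol = len(msa[0])
    if any(len(s) != ncol for s in msa):
        raise ValueError("ragged alignment")
    msa = [s.upper() for s in msa]
    n = len(msa)
    if background is None:
        background = np.full(20, 1.0 / 20)

    gap_frac = [sum(1 for s in msa if s[c] in "-.") / n for c in range(ncol)]
    match_cols = [c for c in range(ncol) if gap_frac[c] < match_rule]
    L = len(match_cols)
    if L == 0:
        raise DegenerateModelError("no columns qualify as match states")

    emis = np.full((L, 20), pseudocount, dtype=float)
    for j, c in enumerate(match_cols):
        for s in msa:
            ch = s[c]
            if ch in _AA_INDEX:
                emis[j, _AA_INDEX[ch]] += 1.0
    row_sums = emis.sum(axis=1)
    if np.any(row_sums == 0):
        raise DegenerateModelError("match column with zero counts and zero pseudocount")
    emis /= row_sums[:, None]

    # transition counts from each sequence's path through the profile
    cm = np.full((3, L + 1), pseudocount, dtype=float)   # from M: M,I,D
    ci = np.full((2, L + 1), pseudocount, dtype=float)   # from I: M,I
    cd = np.full((2, L + 1), pseudocount, dtype=float)   # from D: M,D
    match_set = set(match_cols)
    for s in msa:
        state, idx = "M", 0          # begin state is M_0
        for c in range(ncol):
            ch = s[c]
            is_gap = ch in "-."
            if c in match_set:
                nxt = "D" if is_gap else "M"
                if state == "M":
                    cm[{"M": 0, "D": 2}[nxt], idx] += 1
                elif state == "I":
                    if nxt == "M":
                        ci[0, idx] += 1
                    else:                       # I -> D not modelled; treat as I->M
                        ci[0, idx] += 1
                else:
                    cd[{"M": 0, "D": 1}[nxt], idx] += 1
                state, idx = nxt, idx + 1
            elif not is_gap:                    # insert column residue
                if state == "M":
                    cm[1, idx] += 1
                elif state == "I":
                    ci[1, idx] += 1
                state = "I" if state != "D" else "D"

    def _norm(counts):
        tot = counts.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(tot > 0, counts / np.where(tot > 0, tot, 1.0), 0.0)
        return out

    pm = _norm(cm)
    pi_ = _norm(ci)
    pd_ = _norm(cd)
    # rows where all counts were zero (pseudocount 0, unvisited): make M->M certain
    dead = cm.sum(axis=0) == 0
    pm[0, dead] = 1.0
    dead_i = ci.sum(axis=0) == 0
    pi_[0, dead_i] = 1.0
    dead_d = cd.sum(axis=0) == 0
    pd_[0, dead_d] = 1.0

    return ProfileHMM(
        length=L,
        match_emissions=emis,
        insert_emissions=background.copy(),
        background=background,
        t_mm=pm[0, :L].copy(), t_mi=pm[1, :L].copy(), t_md=pm[2, :L].copy(),
        t_im=pi_[0, :L].copy(), t_ii=pi_[1, :L].copy(),
        t_dm=pd_[0, :L].copy(), t_dd=pd_[1, :L].copy(),
    )


def viterbi_score(hmm: ProfileHMM, seq: ProteinRecord | str) -> float:
    """Max log2-odds of any local alignment path (free entry/exit at match
    states) versus the background null.  X residues cannot be emitted by a
    match/insert state, so runs of X are skipped by locality.
    """
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq.upper()
    if not sequence:
        raise ValueError("empty sequence")
    if set(sequence) == {"X"}:
        raise ValueError("sequence of only ambiguity letters has no defined score")
    ms, iscore, t = hmm._scores()
    L = hmm.length
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in sequence])

    # j axis: 1..L (index 0 is a -inf sentinel)
    VM = np.full(L + 1, NEG_INF)
    VI = np.full(L + 1, NEG_INF)
    VD = np.full(L + 1, NEG_INF)
    # c[k-1] = sum of D-chain transitions t_dd[2..k] (D_2 -> ... -> D_{k+1})
    if L > 1:
        c = np.concatenate([[0.0], np.cumsum(t["t_dd"][2:L])])  # len L-1
    best = NEG_INF
    for a in idx:
        newM = np.full(L + 1, NEG_INF)
        newI = np.full(L + 1, NEG_INF)
        newD = np.full(L + 1, NEG_INF)
        if a >= 0:
            # transitions into M_j (j=2..L) from M/I/D at j-1; j=1 only by entry
            prevM = np.concatenate([[NEG_INF], VM[1:L] + t["t_mm"][1:L]])
            prevI = np.concatenate([[NEG_INF], VI[1:L] + t["t_im"][1:L]])
            prevD = np.concatenate([[NEG_INF], VD[1:L] + t["t_dm"][1:L]])
            entry = np.zeros(L)                         # free entry at any M_j
            stay = np.maximum.reduce([entry, prevM, prevI, prevD])
            newM[1:] = ms[:, a] + stay
            # inserts I_j, j=1..L-1
            newI[1:L] = iscore[a] + np.maximum(VM[1:L] + t["t_mi"][1:L],
                                               VI[1:L] + t["t_ii"][1:L])
        # deletes (no emission) chain within this row from newM:
        # newD[j] = c[j-2] + max_{k<j} (newM[k] + t_md[k] - c[k-1])
        if L > 1:
            u = newM[1:L] + t["t_md"][1:L]              # enter D_{k+1} from M_k
            run = np.maximum.accumulate(u - c)
            newD[2:] = run + c
        VM, VI, VD = newM, newI, newD
        m = float(np.max(VM[1:]))
        if m > best:
            best = m
    return best


def calibrate(hmm: ProfileHMM, n_null: int = 1000,
              lengths: list[int] | None = None, seed: int = 0,
              database_size: int = 1) -> EvalueCalibration:
    """Fit a Gumbel to Viterbi scores of background-sampled null sequences."""
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = [max(50, 2 * hmm.length)]
    scores = np.empty(n_null)
    letters = np.array(list(AMINO_ACIDS))
    for i in range(n_null):
        n = int(rng.choice(lengths))
        s = "".join(rng.choice(letters, size=n, p=hmm.background))
        scores[i] = viterbi_score(hmm, s)
    if np.std(scores) < 1e-12:
        raise CalibrationError("null score distribution is degenerate")
    loc, scale = gumbel_r.fit(scores)
    return EvalueCalibration(mu=float(loc), lam=float(1.0 / scale),
                             database_size=database_size)


def search_proteome(hmm: ProfileHMM, proteome: list[ProteinRecord],
                    calibration: EvalueCalibration,
                    evalue_max: float = 0.01) -> list[HmmHit]:
    """Score every protein, attach e-values (scaled to the proteome size),
    and sort ascending by e-value.  ``passes`` marks e_value <= evalue_max.
    """
    cal = EvalueCalibration(mu=calibration.mu, lam=calibration.lam,
                            database_size=max(len(proteome), 1))
    hits = []
    for rec in proteome:
        try:
            s = viterbi_score(hmm, rec)
        except ValueError:
            continue
        e = cal.evalue(s)
        hits.append(HmmHit(protein_id=rec.id, bit_score=s, e_value=e,
                           passes=e <= evalue_max))
    hits.sort(key=lambda h: (h.e_value, h.protein_id))
    return hits


def hits_to_tsv(hits: list[HmmHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tbit_score\te_value\tpasses\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.bit_score:.4f}\t{h.e_value:.6g}\t{h.passes}\n")
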