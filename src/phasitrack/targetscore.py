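"""Small-RNA : target-transcript duplex scoring and site search.

Plant miRNA/ta-siRNA target recognition is well predicted by a simple
penalty scheme over the antiparallel duplex: each mismatch costs 1, each
G:U wobble 0.5, each bulged nucleotide 1, and every penalty is doubled
when it falls in the 5'-proximal core of the small RNA (positions 2-13
counted from the sRNA 5' end). AGO-catalysed cleavage occurs on the
target opposite sRNA positions 10/11; the predicted cleavage position
reported here is the transcript nucleotide paired to sRNA position 10
(the first nucleotide of the 3' cleavage fragment).

The search slides the reverse complement of the sRNA along the
transcript exhaustively, additionally enumerating all single-nucleotide
bulge placements on either strand of the duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MAX_SCORE = 4.5
CORE_START, CORE_END = 2, 13  # inclusive sRNA positions with doubled penalty
CLEAVAGE_SRNA_POS = 10

MATCH = "match"
MISMATCH = "mismatch"
GU = "GU"
BULGE_SRNA = "bulge_srna"
BULGE_TARGET = "bulge_target"

_STATES = {MATCH, MISMATCH, GU, BULGE_SRNA, BULGE_TARGET}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_DNA_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters {bad}")
    return s


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (T accepted as U on input)."""
    return "".join(_COMP[b] for b in reversed(_rna(seq)))


def reverse_complement_dna(seq: str) -> str:
    return "".join(_DNA_COMP[b] for b in reversed(seq.upper().replace("U", "T")))


def _pair_state(srna_base: str, target_base: str) -> str:
    """Pairing state of one duplex column (bases given 5'->3' each)."""
    if _COMP[srna_base] == target_base:
        return MATCH
    if (srna_base, target_base) in (("G", "U"), ("U", "G")):
        return GU
    return MISMATCH


def score_duplex(states: Sequence[str]) -> float:
    """Penalty score of a duplex from its column states, sRNA 5'->3'.

    ``states`` lists duplex columns from the sRNA 5' end. Match costs 0,
    G:U 0.5, mismatch 1, each bulged nucleotide 1; penalties double in the
    core (sRNA positions 2-13). A target bulge does not consume an sRNA
    position; its penalty is doubled when the next sRNA position lies in
    the core.
    """
    score = 0.0
    pos = 0  # current sRNA position (1-based after increment)
    for state in states:
        if state not in _STATES:
            raise ValueError(f"unknown pairing state {state!r}")
        if state == BULGE_TARGET:
            anchor = pos + 1
        else:
            pos += 1
            anchor = pos
        penalty = {MATCH: 0.0, GU: 0.5, MISMATCH: 1.0, BULGE_SRNA: 1.0, BULGE_TARGET: 1.0}[state]
        if CORE_START <= anchor <= CORE_END:
            penalty *= 2.0
        score += penalty
    return score


@dataclass(frozen=True)
class TargetHit:
    """A scored sRNA binding site on a transcript."""

    srna_id: str
    transcript_id: str
    start: int  # transcript coordinates, 0-based half-open
    end: int
    score: float
    cleavage: int  # transcript nt paired to sRNA position 10
    states: tuple[str, ...]  # duplex columns, sRNA 5'->3'

    @property
    def passes(self) -> bool:
        return self.score <= MAX_SCORE


def _states_ungapped(srna: str, site: str) -> list[str]:
    # sRNA position i (1-based) pairs the site base i from the site 3' end
    L = len(srna)
    return [_pair_state(srna[i], site[L - 1 - i]) for i in range(L)]


def _states_target_bulge(srna: str, site: str, bulge_col: int) -> list[str]:
    """Duplex with one unpaired target nucleotide; site length = L+1.

    ``bulge_col`` (1..L-1) is the number of sRNA positions paired before
    the bulged target base (counting from the sRNA 5' end).
    """
    L = len(srna)
    states: list[str] = []
    t = len(site) - 1  # walk the site from its 3' end
    for i in range(L):
        if i == bulge_col:
            states.append(BULGE_TARGET)
            t -= 1
        states.append(_pair_state(srna[i], site[t]))
        t -= 1
    return states


def _states_srna_bulge(srna: str, site: str, bulge_pos: int) -> list[str]:
    """Duplex with one unpaired sRNA nucleotide; site length = L-1.

    ``bulge_pos`` (1-based, 2..L-1) is the bulged sRNA position.
    """
    L = len(srna)
    states: list[str] = []
    t = len(site) - 1
    for i in range(L):
        if i + 1 == bulge_pos:
            states.append(BULGE_SRNA)
        else:
            states.append(_pair_state(srna[i], site[t]))
            t -= 1
    return states


def _cleavage_from_states(states: Sequence[str], site_start: int, site_end: int) -> int:
    """Transcript coordinate paired to sRNA position 10.

    Duplex columns run from the sRNA 5' end, i.e. from the site's 3' end;
    each non-BULGE_SRNA column consumes one transcript nucleotide.
    """
    pos = 0
    t = site_end - 1
    for state in states:
        consumed_target = state != BULGE_SRNA
        if state != BULGE_TARGET:
            pos += 1
        if pos == CLEAVAGE_SRNA_POS and state != BULGE_TARGET:
            return t
        if consumed_target:
            t -= 1
    raise ValueError("sRNA shorter than the cleavage-defining position")


_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}


def _penalty_matrix(q: str, tx: str) -> "np.ndarray":
    """A[i, t]: penalty of sRNA position i+1 paired with transcript base t.

    Base penalty is 0 for a Watson-Crick pair (codes sum to 3), 0.5 for a
    G:U wobble (codes sum to 5), 1 otherwise; doubled in the core.
    """
    qa = np.fromiter((_ENC[b] for b in q), dtype=np.int8, count=len(q))
    ta = np.fromiter((_ENC[b] for b in tx), dtype=np.int8, count=len(tx))
    s = qa[:, None].astype(np.int16) + ta[None, :]
    A = np.where(s == 3, 0.0, np.where(s == 5, 0.5, 1.0))
    mult = np.where((np.arange(1, len(q) + 1) >= CORE_START) & (np.arange(1, len(q) + 1) <= CORE_END), 2.0, 1.0)
    return A * mult[:, None]


def find_sites(
    srna: str,
    transcript: str,
    srna_id: str = "sRNA",
    transcript_id: str = "tx",
    max_score: float = MAX_SCORE,
    max_bulges: int = 1,
) -> list[TargetHit]:
    """All binding sites of an sRNA on a transcript with score <= max_score.

    Exhaustive ungapped sliding of the reverse-complemented sRNA, plus all
    single-nucleotide bulge placements on either strand when
    ``max_bulges`` >= 1. Only the best alignment per site interval is
    kept; hits are sorted by (score, start).

    The scan is vectorized: every alignment's score is a partial diagonal
    sum of the position-penalty matrix, so candidate configurations are
    located with numpy and their duplex states rebuilt only for reported
    hits.
    """
    q = _rna(srna)
    tx = _rna(transcript)
    L, N = len(q), len(tx)
    if N < L:
        return []
    nS = N - L + 1
    A = _penalty_matrix(q, tx)
    # D[i, c]: A[i, s' + L - 1 - i] for shifted starts s' = c - 1 in [-1, nS]
    D = np.zeros((L, nS + 2))
    for i in range(L):
        t = np.arange(-1, nS + 1) + (L - 1 - i)
        valid = (t >= 0) & (t < N)
        D[i, valid] = A[i, t[valid]]
    colsum = D.sum(axis=0)
    cum = np.vstack([np.zeros(nS + 2), np.cumsum(D, axis=0)])  # cum[b] = sum_{i<b}
    suf = colsum[None, :] - cum

    hits: list[TargetHit] = []

    def consider(start: int, end: int, states: list[str]) -> None:
        sc = score_duplex(states)
        if sc <= max_score:
            hits.append(
                TargetHit(
                    srna_id, transcript_id, start, end, sc,
                    _cleavage_from_states(states, start, end), tuple(states),
                )
            )

    un = colsum[1 : nS + 1]  # ungapped score at start s = column s+1
    for s in np.nonzero(un <= max_score)[0]:
        consider(int(s), int(s) + L, _states_ungapped(q, tx[s : s + L]))

    if max_bulges >= 1 and L >= 2:
        pos = np.arange(1, L + 1)
        core = (pos >= CORE_START) & (pos <= CORE_END)
        if nS >= 2:
            # target bulge at column b: prefix pairs at shift s+1, suffix at s
            b = np.arange(1, L)
            btpen = np.where((b + 1 >= CORE_START) & (b + 1 <= CORE_END), 2.0, 1.0)
            s_idx = np.arange(nS - 1)  # s in 0 .. N-L-1
            tb = cum[b][:, s_idx + 2] + suf[b][:, s_idx + 1] + btpen[:, None]
            for bi, s in zip(*np.nonzero(tb <= max_score)):
                s = int(s)
                site = tx[s : s + L + 1]
                consider(s, s + L + 1, _states_target_bulge(q, site, int(b[bi])))
        # sRNA bulge at position bp: prefix pairs at shift s-1, suffix at s
        bp = np.arange(2, L)
        if bp.size:
            bspen = np.where(core[bp - 1], 2.0, 1.0)
            s_idx = np.arange(nS + 1)  # s in 0 .. N-L+1
            sb = cum[bp - 1][:, s_idx] + suf[bp][:, s_idx + 1] + bspen[:, None]
            for bi, s in zip(*np.nonzero(sb <= max_score)):
                s = int(s)
                site = tx[s : s + L - 1]
                consider(s, s + L - 1, _states_srna_bulge(q, site, int(bp[bi])))

    # keep the best alignment per site interval
    best: dict[tuple[int, int], TargetHit] = {}
    for h in hits:
        key = (h.start, h.end)
        if key not in best or h.score < best[key].score:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.score, h.start, h.end))


@dataclass(frozen=True)
class TwoHit:
    """A dual trigger-sRNA site pair on one transcript (two-hit topology)."""

    site5: TargetHit
    site3: TargetHit
    cleavage: int  # cleavage position of the 3' site

    @property
    def combined_score(self) -> float:
        return self.site5.score + self.site3.score


def detect_two_hit(
    transcript: str,
    trigger: str,
    transcript_id: str = "tx",
    trigger_id: str = "trigger",
    max_score: float = MAX_SCORE,
) -> TwoHit | None:
    """Best pair of non-overlapping trigger sites on a transcript, or None.

    Among all qualifying sites the non-overlapping pair with the smallest
    combined score is returned, ordered by transcript coordinate; the
    phase-setting cleavage is that of the 3' site.
    """
    sites = find_sites(trigger, transcript, trigger_id, transcript_id, max_score)
    best: TwoHit | None = None
    for i in range(len(sites)):
        for j in range(len(sites)):
            a, b = sites[i], sites[j]
            if a.end <= b.start:  # non-overlapping, a upstream of b
                cand = TwoHit(a, b, b.cleavage)
                if best is None or cand.combined_score < best.combined_score:
                    best = cand
    return best


def alignment_string(srna: str, transcript: str, hit: TargetHit) -> str:
    """Three-line duplex rendering (target 5'->3' on top, sRNA 3'->5' below)."""
    q = _rna(srna)
    site = _rna(transcript)[hit.start : hit.end]
    top, mid, bot = [], [], []
    qi, ti = 0, len(site) - 1
    for state in hit.states:
        if state == BULGE_SRNA:
            top.append("-")
            mid.append(" ")
            bot.append(q[qi])
            qi += 1
        elif state == BULGE_TARGET:
            top.append(site[ti])
            mid.append(" ")
            bot.append("-")
            ti -= 1
        else:
            top.append(site[ti])
            mid.append("|" if state == MATCH else ("o" if state == GU else " "))
            bot.append(q[qi])
            qi += 1
            ti -= 1
    # render with the target 5'->3'
    return "\n".join(
        ["5' " + "".join(reversed(top)) + " 3'  (target)",
         "   " + "".join(reversed(mid)),
         "3' " + "".join(reversed(bot)) + " 5'  (sRNA)"]
    )
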