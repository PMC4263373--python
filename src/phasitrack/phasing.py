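"""Phased siRNA cluster discovery via a phasing score.

Secondary siRNAs produced by processive DCL4 cleavage from a defined
register appear at genomic positions that are congruent modulo the phase
length k (21, 22, or 24 nt). Plus- and minus-strand reads of one duplex
are merged onto a single phase coordinate by shifting minus-strand 5'
ends +2 nt, compensating the 2-nt 3' overhang DICER leaves on each
strand. A 500-bp window is scored

    score = (n - 2) * ln(1 + 10 * P / (1 + U))        (n >= 3, else 0)

where n is the number of occupied phase-cycle positions out of the C =
floor(window / k) cycles fitting in the window (23, 22, and 20 for k =
21, 22, 24), P the pooled normalized abundance on the register's phase
positions, and U the out-of-phase abundance in the window. Windows with
at least 5 in-register reads are candidates; score >= 25 qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .srio import AlignmentRecord, Library

PHASE_WINDOW = 500
PHASE_STEP = 250
MIN_INPHASE_READS = 5
SCORE_THRESHOLD = 25.0
OVERHANG = 2  # DICER 2-nt 3' overhang


def cycles_per_window(window_len: int = PHASE_WINDOW, k: int = 21) -> int:
    """Number of phase cycles C fitting in a window (23/22/20 for 21/22/24)."""
    if window_len < k:
        raise ValueError("window_len must be >= phase length")
    return window_len // k


class PositionMap:
    """Pooled per-position abundance (RPM) and raw counts at phase coordinates."""

    def __init__(self) -> None:
        self.abundance: dict[str, dict[int, float]] = {}
        self.count: dict[str, dict[int, int]] = {}

    def add(self, chrom: str, pos: int, rpm: float, copies: int) -> None:
        self.abundance.setdefault(chrom, {})[pos] = (
            self.abundance.get(chrom, {}).get(pos, 0.0) + rpm
        )
        self.count.setdefault(chrom, {})[pos] = (
            self.count.get(chrom, {}).get(pos, 0) + copies
        )

    def chroms(self) -> list[str]:
        return sorted(self.abundance)


def phase_position(record: AlignmentRecord) -> int:
    """Duplex-merged phase coordinate of a read.

    Plus-strand reads map at their leftmost coordinate; minus-strand reads
    at leftmost + 2, so both strands of one DCL4 duplex share a position.
    """
    return record.start if record.strand == "+" else record.start + OVERHANG


def merge_strands(
    records_by_library: Mapping[str, Sequence[AlignmentRecord]],
    libraries: Mapping[str, Library],
    size_class: int = 21,
) -> PositionMap:
    """Pool libraries, normalize to RPM, and merge strands onto phase positions."""
    pm = PositionMap()
    for lib, records in records_by_library.items():
        total = libraries[lib].genome_matched_total
        for r in records:
            if r.length != size_class:
                continue
            pm.add(r.chrom, phase_position(r), r.copies * 1e6 / total, r.copies)
    return pm


def phasing_score(P: float, U: float, n: int) -> float:
    """Phasing score (n-2)*ln(1 + 10P/(1+U)); zero below 3 occupied cycles."""
    if P < 0 or U < 0 or n < 0:
        raise ValueError("P, U and n must be non-negative")
    if n < 3:
        return 0.0
    return (n - 2) * math.log1p(10.0 * P / (1.0 + U))


@dataclass
class PhaseWindow:
    """One scored 500-bp phase analysis at its best register."""

    chrom: str
    start: int
    window_len: int
    k: int
    register: int  # residue class mod k, in genomic coordinates
    n: int  # occupied phase-cycle positions
    P: float  # in-phase abundance (RPM)
    U: float  # out-of-phase abundance (RPM)
    score: float
    inphase_reads: int  # raw pooled in-register read count
    qualifies: bool = False

    @property
    def end(self) -> int:
        return self.start + self.window_len


def score_window(
    posmap: PositionMap, chrom: str, wstart: int, k: int, window_len: int = PHASE_WINDOW
) -> PhaseWindow:
    """Score one window at its best register (ties -> smaller register offset).

    P, U, and n are computed per register over the C phase positions
    ``wstart + r + k*i``; U is the remaining size-k abundance in the full
    window. The reported register is the residue ``(wstart + r) mod k``.
    """
    C = cycles_per_window(window_len, k)
    ab = posmap.abundance.get(chrom, {})
    ct = posmap.count.get(chrom, {})
    positions = [p for p in ab if wstart <= p < wstart + window_len]
    total = sum(ab[p] for p in positions)
    best = None
    for r in range(k):
        P = n = reads = 0
        Pa = 0.0
        for i in range(C):
            p = wstart + r + k * i
            a = ab.get(p)
            if a:
                Pa += a
                n += 1
                reads += ct[p]
        U = total - Pa
        s = phasing_score(Pa, max(U, 0.0), n)
        if best is None or s > best[0]:
            best = (s, r, n, Pa, max(U, 0.0), reads)
    s, r, n, Pa, U, reads = best
    return PhaseWindow(
        chrom=chrom,
        start=wstart,
        window_len=window_len,
        k=k,
        register=(wstart + r) % k,
        n=n,
        P=Pa,
        U=U,
        score=s,
        inphase_reads=reads,
    )


def scan_windows(
    posmap: PositionMap,
    k: int = 21,
    window_len: int = PHASE_WINDOW,
    step: int = PHASE_STEP,
    min_inphase_reads: int = MIN_INPHASE_READS,
    threshold: float = SCORE_THRESHOLD,
) -> list[PhaseWindow]:
    """Slide windows over every occupied region and keep candidate windows.

    Returns candidate windows (raw in-register reads >= min_inphase_reads
    at the best register); ``qualifies`` marks those with score >=
    threshold.
    """
    if window_len < k:
        raise ValueError("window_len must be >= phase length k")
    out: list[PhaseWindow] = []
    for chrom in posmap.chroms():
        positions = sorted(posmap.abundance[chrom])
        if not positions:
            continue
        starts: set[int] = set()
        for p in positions:
            first = max(0, (p - window_len + step) // step * step)
            for w in range(first, p + 1, step):
                starts.add(w)
        for w in sorted(starts):
            pw = score_window(posmap, chrom, w, k, window_len)
            if pw.inphase_reads >= min_inphase_reads:
                pw.qualifies = pw.score >= threshold
                out.append(pw)
    return out


@dataclass
class PhasedCluster:
    """Merged run of overlapping/abutting qualifying windows of one size class."""

    chrom: str
    start: int
    end: int
    k: int
    score: float  # best constituent window score
    register: int  # register of the best window
    n: int
    P: float
    U: float
    lbl1_dependent: bool | None = None  # None = no differential data


def merge_clusters(windows: Iterable[PhaseWindow]) -> list[PhasedCluster]:
    """Merge overlapping/abutting qualifying windows sharing k into clusters."""
    qual = sorted(
        (w for w in windows if w.qualifies), key=lambda w: (w.k, w.chrom, w.start)
    )
    clusters: list[PhasedCluster] = []
    cur: list[PhaseWindow] = []
    for w in qual:
        if cur and w.chrom == cur[-1].chrom and w.k == cur[-1].k and w.start <= cur[-1].end:
            cur.append(w)
        else:
            if cur:
                clusters.append(_finish_cluster(cur))
            cur = [w]
    if cur:
        clusters.append(_finish_cluster(cur))
    return clusters


def _finish_cluster(ws: list[PhaseWindow]) -> PhasedCluster:
    best = max(ws, key=lambda w: w.score)
    return PhasedCluster(
        chrom=ws[0].chrom,
        start=min(w.start for w in ws),
        end=max(w.end for w in ws),
        k=ws[0].k,
        score=best.score,
        register=best.register,
        n=best.n,
        P=best.P,
        U=best.U,
    )


def flag_lbl1_dependent(
    clusters: Sequence[PhasedCluster], diff_calls: pd.DataFrame | None, window_len: int = 500
) -> list[PhasedCluster]:
    """Flag clusters overlapping a window called significantly down in mutant."""
    if diff_calls is None or diff_calls.empty:
        for c in clusters:
            c.lbl1_dependent = None
        return list(clusters)
    down = diff_calls[(diff_calls["passes"]) & (diff_calls["direction"] == "down_in_mutant")]
    for c in clusters:
        c.lbl1_dependent = any(
            row.chrom == c.chrom and c.start < row.start + window_len and row.start < c.end
            for row in down.itertuples()
        )
    return list(clusters)


def clusters_to_frame(clusters: Sequence[PhasedCluster]) -> pd.DataFrame:
    """BED-like TSV table of clusters."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "k": c.k,
                "register": c.register,
                "n": c.n,
                "P": round(c.P, 4),
                "U": round(c.U, 4),
                "score": round(c.score, 4),
                "lbl1_dependent": "NA" if c.lbl1_dependent is None else c.lbl1_dependent,
            }
            for c in clusters
        ]
    )
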