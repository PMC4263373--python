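"""Characterization of two-hit TAS loci.

A two-hit TAS transcript carries two trigger-miRNA (miR390) binding
sites; cleavage at the 3' site sets the phase register and phased 21-nt
ta-siRNAs are produced upstream of the cut, between the two sites. The
ta-siRNAs are indexed D1, D2, ... in 21-nt steps counting 5'-ward from
the cleavage position, on each strand: D_i(+) occupies
[cleavage - 21*i, cleavage - 21*(i-1)) on the sense strand and its
duplex partner D_i(-) is offset -2 nt (the DICER 2-nt 3' overhang).

Loci here live on the sense strand of a reference sequence (genome or
precursor transcript); coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phasing import OVERHANG, phase_position
from .srio import AlignmentRecord, Library
from .targetscore import TwoHit, find_sites, reverse_complement_dna

logger = logging.getLogger("phasitrack")

PHASE_LEN = 21
TASIARF_MAX_SCORE = 3.0


@dataclass(frozen=True)
class TasiRna:
    """One predicted phased ta-siRNA of a TAS locus."""

    d_index: int  # ordinal distance from the 3' cleavage site, in phase steps
    strand: str
    start: int  # leftmost coordinate on the reference
    sequence: str  # 5'->3' on its own strand (DNA alphabet)

    @property
    def label(self) -> str:
        return f"D{self.d_index}({self.strand})"


@dataclass
class TasLocus:
    """A characterized two-hit locus."""

    locus_id: str
    chrom: str
    start: int
    end: int
    two_hit: TwoHit
    cleavage: int  # phase-setting cut: 3'-site position paired to trigger pos 10
    register: int  # cleavage mod 21
    tasirnas: list[TasiRna] = field(default_factory=list)
    tasiarf_flags: dict[str, bool] = field(default_factory=dict)


def enumerate_tasirnas(
    sequence: str,
    two_hit: TwoHit,
    phase_len: int = PHASE_LEN,
) -> list[TasiRna]:
    """D-indexed ta-siRNA table between the two trigger sites.

    D1(+) is the first complete phase-length-mer immediately 5' of the 3'
    cleavage position; enumeration proceeds 5'-ward and stops at the last
    complete cycle that clears the 5' site. Each D_i(+) has one
    antisense partner D_i(-) whose leftmost coordinate is offset -2 nt.
    """
    c = two_hit.cleavage
    upstream_limit = two_hit.site5.end
    n_cycles = (c - upstream_limit) // phase_len
    if n_cycles < 1:
        return []
    out: list[TasiRna] = []
    for i in range(1, n_cycles + 1):
        s = c - phase_len * i
        plus_seq = sequence[s : s + phase_len].upper()
        minus_start = s - OVERHANG
        minus_seq = reverse_complement_dna(
            sequence[minus_start : minus_start + phase_len]
        )
        out.append(TasiRna(i, "+", s, plus_seq))
        out.append(TasiRna(i, "-", minus_start, minus_seq))
    return out


def classify_reads(
    locus: TasLocus,
    records_by_library: Mapping[str, Sequence[AlignmentRecord]],
    libraries: Mapping[str, Library],
    phase_len: int = PHASE_LEN,
    sizes: Sequence[int] = tuple(range(18, 27)),
) -> dict:
    """Split locus reads into in-phase / out-of-phase abundance and sizes.

    A read is in phase iff its duplex-adjusted 5' position is congruent
    with the locus register modulo the phase length. Only size-phase_len
    reads can be in phase; the size profile covers all lengths 18-26.
    Returns per-position RPM vectors, per-library totals, and the size
    profile (mean RPM across libraries, per genotype).
    """
    in_phase: dict[int, float] = {}
    out_phase: dict[int, float] = {}
    per_lib = {lib: {"in_phase": 0.0, "out_of_phase": 0.0} for lib in records_by_library}
    size_profile: dict[str, dict[int, float]] = {}
    for lib, records in records_by_library.items():
        total = libraries[lib].genome_matched_total
        geno = libraries[lib].genotype
        prof = size_profile.setdefault(geno, {k: 0.0 for k in sizes})
        for r in records:
            if r.chrom != locus.chrom or not (locus.start <= r.five_prime < locus.end):
                continue
            rpm = r.copies * 1e6 / total
            if r.length in prof:
                prof[r.length] += rpm
            pos = phase_position(r)
            if r.length == phase_len and pos % phase_len == locus.register:
                in_phase[pos] = in_phase.get(pos, 0.0) + rpm
                per_lib[lib]["in_phase"] += rpm
            else:
                out_phase[pos] = out_phase.get(pos, 0.0) + rpm
                per_lib[lib]["out_of_phase"] += rpm
    n_by_geno = {g: sum(1 for l in libraries.values() if l.genotype == g) for g in size_profile}
    for g, prof in size_profile.items():
        for k in prof:
            prof[k] /= max(n_by_geno[g], 1)
    return {
        "in_phase": in_phase,
        "out_of_phase": out_phase,
        "per_library": per_lib,
        "size_profile": size_profile,
    }


def flag_tasirarfs(
    tasirnas: Sequence[TasiRna],
    arf_transcripts: Mapping[str, str],
    max_score: float = TASIARF_MAX_SCORE,
) -> dict[str, bool]:
    """Flag ta-siRNAs with a qualifying site in any ARF3-like transcript."""
    if not arf_transcripts:
        logger.warning("no ARF3-like transcripts provided; no tasiR-ARF flags set")
        return {t.label: False for t in tasirnas}
    flags = {}
    for t in tasirnas:
        flags[t.label] = any(
            find_sites(t.sequence, tx, t.label, tx_id, max_score=max_score)
            for tx_id, tx in arf_transcripts.items()
        )
    return flags


def summarize_locus(
    locus: TasLocus,
    classified: dict,
    libraries: Mapping[str, Library],
    phase_score: float | None = None,
    diff_log2fc: float | None = None,
    diff_significant: bool | None = None,
) -> dict:
    """One Table-style summary row for a locus.

    Reports the predicted ta-siRNA count (both strands), tasiR-ARF count,
    best phasing score, total wild-type locus reads (raw pooled), and the
    wild-type / mutant fold change (0.5 pseudo-count on normalized means).
    """
    per_lib = classified["per_library"]
    wt_libs = [n for n, l in libraries.items() if l.genotype == "wildtype"]
    mut_libs = [n for n, l in libraries.items() if l.genotype == "mutant"]

    def lib_total_reads(names):
        tot = 0.0
        for n in names:
            rpm = per_lib[n]["in_phase"] + per_lib[n]["out_of_phase"]
            tot += rpm * libraries[n].genome_matched_total / 1e6
        return tot

    def mean_rpm(names):
        if not names:
            return float("nan")
        return float(
            np.mean([per_lib[n]["in_phase"] + per_lib[n]["out_of_phase"] for n in names])
        )

    wt_over_mut = (mean_rpm(wt_libs) + 0.5) / (mean_rpm(mut_libs) + 0.5)
    row = {
        "locus": locus.locus_id,
        "chrom": locus.chrom,
        "start": locus.start,
        "end": locus.end,
        "n_tasirnas": len(locus.tasirnas),
        "n_tasiarfs": sum(
            1
            for t in locus.tasirnas
            if locus.tasiarf_flags.get(t.label, False)
        ),
        "phasing_score": float("nan") if phase_score is None else round(phase_score, 2),
        "wt_reads": int(round(lib_total_reads(wt_libs))),
        "fold_change_wt_over_mut": round(wt_over_mut, 2),
        "significant": "NA" if diff_significant is None else diff_significant,
    }
    if diff_log2fc is not None:
        row["log2fc_mut_vs_wt"] = round(diff_log2fc, 3)
    missing = [k for k, v in row.items() if v is None]
    if missing:
        logger.warning("locus %s summary missing fields %s", locus.locus_id, missing)
    return row
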