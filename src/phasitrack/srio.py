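"""Small-RNA alignment ingest, filtering, and normalization.

All genomic coordinates in this package are 0-based, half-open. The
strand-aware 5' end of a read is its leftmost coordinate on the plus
strand and ``start + length - 1`` on the minus strand.

Collapsed read counts ("copies") follow the common sRNA-seq convention of
encoding the number of identical sequenced reads in the read name as a
``_xN`` suffix (SAM) or in the BED score column.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger("phasitrack")

_COPIES_RE = re.compile(r"_x(\d+)$")

#: default retention filters: read length bounds (nt) and the cap on the
#: number of genomic alignments a read may have and still be reported
MIN_LEN = 18
MAX_LEN = 26
MAX_HITS = 20


@dataclass(frozen=True, order=True)
class AlignmentRecord:
    """One small-RNA read alignment on the genome."""

    chrom: str
    start: int  # 0-based leftmost
    length: int  # read length in nt
    strand: str  # '+' or '-'
    copies: int = 1  # identical reads collapsed onto this alignment
    n_hits: int = 1  # genomic alignments of this read sequence
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.copies < 1 or self.n_hits < 1:
            raise ValueError("copies and n_hits must be >= 1")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' end coordinate."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Library:
    """One sequenced sRNA library and its normalization denominator."""

    name: str
    genotype: str  # 'wildtype' or 'mutant'
    replicate: int
    genome_matched_total: float

    def __post_init__(self) -> None:
        if self.genome_matched_total <= 0:
            raise ValueError("genome_matched_total must be > 0")


class Blacklist:
    """Genomic intervals annotated as structural RNA (rRNA/tRNA/sn/snoRNA).

    Reads overlapping any interval by >= 1 nt are removed from sRNA
    analyses.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int]] = (),
        known_chroms: Sequence[str] | None = None,
    ) -> None:
        self._trees: dict[str, IntervalTree] = {}
        known = set(known_chroms) if known_chroms is not None else None
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval [{start},{end})")
            if known is not None and chrom not in known:
                logger.warning(
                    "blacklist interval on unknown sequence %r ignored", chrom
                )
                continue
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(
        cls, path: str | Path, known_chroms: Sequence[str] | None = None
    ) -> "Blacklist":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls(ivs, known_chroms=known_chroms)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def _sam_n_hits(path: str | Path) -> Counter:
    """Count alignments per read name for files lacking NH tags."""
    counts: Counter = Counter()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if not rec.is_unmapped:
                counts[rec.query_name] += 1
    return counts


def load_alignments(
    path: str | Path,
    fmt: str | None = None,
    max_hits: int = MAX_HITS,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    require_perfect: bool = False,
    report: dict | None = None,
) -> list[AlignmentRecord]:
    """Load and filter small-RNA alignments from SAM/BAM or BED.

    Parameters
    ----------
    path
        Alignment file. Format is inferred from the suffix unless ``fmt``
        ("sam", "bam", or "bed") is given.
    max_hits, min_len, max_len
        Retention filters: a record is kept iff
        ``min_len <= length <= max_len`` and ``n_hits <= max_hits``.
    require_perfect
        Drop SAM records with mismatches or indels (NM tag > 0 or a
        non-pure-match CIGAR); dropped records are tallied in ``report``.
    report
        Optional dict populated with filtering tallies.

    Returns
    -------
    list of AlignmentRecord in 0-based half-open coordinates.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    tally = Counter()
    if fmt in ("sam", "bam"):
        records = _load_sam(path, max_hits, min_len, max_len, require_perfect, tally)
    elif fmt == "bed":
        records = _load_bed(path, max_hits, min_len, max_len, tally)
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if report is not None:
        report.update(tally)
    logger.info("loaded %d alignments from %s (%s)", len(records), path, dict(tally))
    return records


def _load_sam(path, max_hits, min_len, max_len, require_perfect, tally):
    records: list[AlignmentRecord] = []
    pending: list[tuple] = []
    name_hits: Counter | None = None
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for i, rec in enumerate(af.fetch(until_eof=True), 1):
            if rec.is_unmapped:
                tally["unmapped"] += 1
                continue
            if rec.cigartuples is None or rec.reference_start is None:
                raise ValueError(f"unparseable SAM record at line {i}: {rec.query_name}")
            if require_perfect:
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                pure = all(op == 0 for op, _ in rec.cigartuples)
                if nm > 0 or not pure:
                    tally["imperfect_dropped"] += 1
                    continue
            length = rec.query_length or rec.infer_query_length()
            name = rec.query_name or ""
            m = _COPIES_RE.search(name)
            copies = int(m.group(1)) if m else 1
            if rec.has_tag("NH"):
                n_hits = int(rec.get_tag("NH"))
            else:
                if name_hits is None:
                    name_hits = _sam_n_hits(path)
                n_hits = name_hits[name]
            pending.append(
                (
                    rec.reference_name,
                    rec.reference_start,  # pysam is already 0-based
                    length,
                    "-" if rec.is_reverse else "+",
                    copies,
                    n_hits,
                    name,
                )
            )
    for chrom, start, length, strand, copies, n_hits, name in pending:
        if not (min_len <= length <= max_len):
            tally["length_filtered"] += 1
            continue
        if n_hits > max_hits:
            tally["multihit_filtered"] += 1
            continue
        records.append(
            AlignmentRecord(chrom, start, length, strand, copies, n_hits, name)
        )
    return records


def _load_bed(path, max_hits, min_len, max_len, tally):
    rows = []
    name_counts: Counter = Counter()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 and f[3] != "." else ""
                copies = int(float(f[4])) if len(f) > 4 and f[4] != "." else 1
                strand = f[5] if len(f) > 5 else "+"
            except (IndexError, ValueError) as exc:
                raise ValueError(f"unparseable BED record at line {i}") from exc
            rows.append((chrom, start, end - start, strand, max(copies, 1), name))
            if name:
                name_counts[name] += 1
    records = []
    for chrom, start, length, strand, copies, name in rows:
        n_hits = max(name_counts[name], 1) if name else 1
        if not (min_len <= length <= max_len):
            tally["length_filtered"] += 1
            continue
        if n_hits > max_hits:
            tally["multihit_filtered"] += 1
            continue
        records.append(
            AlignmentRecord(chrom, start, length, strand, copies, n_hits, name)
        )
    return records


def write_bed(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records as 6-column BED (copies in the score column)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{r.copies}\t{r.strand}\n"
            )


def apply_blacklist(
    records: Iterable[AlignmentRecord], blacklist: Blacklist
) -> list[AlignmentRecord]:
    """Remove records overlapping a structural-RNA interval by >= 1 nt."""
    kept, removed = [], 0
    for r in records:
        if blacklist.overlaps(r.chrom, r.start, r.end):
            removed += 1
        else:
            kept.append(r)
    if removed:
        logger.info("blacklist removed %d alignments", removed)
    return kept


def normalize_rpm(
    records: Sequence[AlignmentRecord], library: Library
) -> np.ndarray:
    """Per-record abundance in reads per million genome-matched reads.

    ``abundance_i = copies_i * 1e6 / genome_matched_total``; summed over a
    whole genome-matched library (before blacklist removal) this is 1e6.
    """
    if library.genome_matched_total <= 0:
        raise ValueError("genome_matched_total must be > 0")
    copies = np.array([r.copies for r in records], dtype=float)
    return copies * 1e6 / library.genome_matched_total
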