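"""PARE/degradome validation of predicted cleavage sites.

PARE sequencing captures the 5' ends of uncapped RNA fragments, so a
genuine small-RNA-guided cleavage leaves a sharp pile-up of tag 5' ends
precisely at the predicted cut. A site is validated when the tag
abundance in a small window around the cleavage position (+-2 nt, 5 nt
wide) dominates the abundance in a large flanking window (+-15 nt, 31 nt
wide): W_S / W_L >= 0.75 with an absolute floor W_S >= 4 tags. Tags are
pooled across PARE libraries before windowing; the thresholds apply to
raw tag counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .targetscore import TargetHit

logger = logging.getLogger("phasitrack")

SMALL_HALF_WIDTH = 2  # W_S: cleavage +-2 nt -> 5-nt window
LARGE_HALF_WIDTH = 15  # W_L: cleavage +-15 nt -> 31-nt window
MIN_RATIO = 0.75
MIN_WS = 4

#: per transcript: position -> pooled 5'-end tag count
PareTagMap = Mapping[str, Mapping[int, float]]


def load_tags(path: str | Path) -> dict[str, dict[int, float]]:
    """Read a tag table (transcript, position, count) TSV into a PareTagMap.

    A header line is detected and skipped; counts at duplicate positions
    are summed (pooling across libraries).
    """
    tags: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                pos, count = int(f[1]), float(f[2])
            except ValueError:
                continue  # header
            tx = tags.setdefault(f[0], {})
            tx[pos] = tx.get(pos, 0.0) + count
    return tags


def window_abundance(
    tag_map: Mapping[int, float],
    position: int,
    half_width: int,
    transcript_length: int | None = None,
) -> float:
    """Summed tag count over [position - half_width, position + half_width].

    The window is inclusive at both ends (2*half_width + 1 positions) and
    is truncated, with a warning, where it runs off the transcript.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    lo, hi = position - half_width, position + half_width
    if lo < 0 or (transcript_length is not None and hi >= transcript_length):
        logger.warning(
            "PARE window [%d,%d] truncated at transcript boundary", lo, hi
        )
        lo = max(lo, 0)
        if transcript_length is not None:
            hi = min(hi, transcript_length - 1)
    return float(sum(tag_map.get(p, 0.0) for p in range(lo, hi + 1)))


@dataclass
class PareValidation:
    """Degradome support for one predicted cleavage site."""

    hit: TargetHit | None
    transcript_id: str
    cleavage: int
    ws: float  # tag abundance, cleavage +-2 nt
    wl: float  # tag abundance, cleavage +-15 nt
    ratio: float | None  # ws/wl; None when wl == 0
    validated: bool


def validate_site(
    hit: TargetHit,
    tags: PareTagMap,
    min_ratio: float = MIN_RATIO,
    min_ws: float = MIN_WS,
    transcript_length: int | None = None,
) -> PareValidation:
    """Apply the W_S/W_L ratio and W_S floor to one predicted site."""
    return validate_position(
        tags, hit.transcript_id, hit.cleavage, min_ratio, min_ws,
        transcript_length, hit=hit,
    )


def validate_position(
    tags: PareTagMap,
    transcript_id: str,
    cleavage: int,
    min_ratio: float = MIN_RATIO,
    min_ws: float = MIN_WS,
    transcript_length: int | None = None,
    hit: TargetHit | None = None,
) -> PareValidation:
    tag_map = tags.get(transcript_id, {})
    ws = window_abundance(tag_map, cleavage, SMALL_HALF_WIDTH, transcript_length)
    wl = window_abundance(tag_map, cleavage, LARGE_HALF_WIDTH, transcript_length)
    ratio = ws / wl if wl > 0 else None
    validated = ratio is not None and ratio >= min_ratio and ws >= min_ws
    return PareValidation(hit, transcript_id, cleavage, ws, wl, ratio, validated)


def validations_to_frame(validations) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript": v.transcript_id,
                "cleavage": v.cleavage,
                "W_S": v.ws,
                "W_L": v.wl,
                "ratio": float("nan") if v.ratio is None else round(v.ratio, 4),
                "validated": v.validated,
            }
            for v in validations
        ]
    )
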