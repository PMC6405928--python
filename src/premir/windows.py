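"""Precursor-scale candidate windows from homology loci.

A homology hit is flanked (default 500 nt up/downstream on its own strand),
then fragmented with multi-size sliding windows (default 90/100/110/120 nt,
step 10).  Fragmentation collapses exact positional sequence duplicates;
cross-locus redundancy removal is a separate explicit call (``dedupe``).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .homology import HomologyHit
from .seqio import GenomicInterval, SequenceRecord, extract

__all__ = [
    "CandidateWindow",
    "FlankedLocus",
    "WindowConfig",
    "extract_flanked_locus",
    "fragment",
    "dedupe",
]

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (90, 100, 110, 120)
DEFAULT_STEP = 10
MATURE_ANCHOR_MAX = 24


@dataclass(frozen=True)
class WindowConfig:
    flank_up: int = 500
    flank_down: int = 500
    sizes: tuple[int, ...] = DEFAULT_SIZES
    step: int = DEFAULT_STEP
    dedupe_identity: float = 1.0


@dataclass(frozen=True)
class FlankedLocus:
    """A hit plus flanks, oriented along the hit strand."""

    record: SequenceRecord  # strand-oriented sequence of the locus
    interval: GenomicInterval  # genomic (+ strand coordinates, strand of hit)
    hit: HomologyHit


@dataclass(frozen=True)
class CandidateWindow:
    origin: GenomicInterval
    seq: str
    size: int
    source_hit: HomologyHit
    mature_anchor: GenomicInterval | None = None


def extract_flanked_locus(
    hit: HomologyHit,
    genome: Sequence[SequenceRecord] | dict[str, SequenceRecord],
    up: int = 500,
    down: int = 500,
) -> FlankedLocus:
    """Extract [hit - up, hit + down) on the hit's strand, clipped to bounds.

    "Upstream" is 5' of the hit on its own strand, so on the '-' strand the
    upstream flank extends toward higher forward-strand coordinates.
    """
    if up < 0 or down < 0:
        raise ValueError("flank lengths must be >= 0")
    if not isinstance(genome, dict):
        genome = {rec.id: rec for rec in genome}
    rec = genome[hit.interval.seq_id]
    iv = hit.interval
    if iv.strand == "+":
        start, end = iv.start - up, iv.end + down
    else:
        start, end = iv.start - down, iv.end + up
    clipped_start, clipped_end = max(0, start), min(rec.length, end)
    if (clipped_start, clipped_end) != (start, end):
        logger.info(
            "locus for %s clipped to [%d,%d)", hit.query_id, clipped_start, clipped_end
        )
    interval = GenomicInterval(iv.seq_id, clipped_start, clipped_end, iv.strand)
    seq = extract(interval, genome)
    locus_id = f"{hit.query_id}|{iv.seq_id}:{clipped_start}-{clipped_end}({iv.strand})"
    return FlankedLocus(SequenceRecord(locus_id, seq), interval, hit)


def _window_genomic_interval(locus: FlankedLocus, offset: int, size: int) -> GenomicInterval:
    iv = locus.interval
    if iv.strand == "+":
        return GenomicInterval(iv.seq_id, iv.start + offset, iv.start + offset + size, "+")
    return GenomicInterval(iv.seq_id, iv.end - offset - size, iv.end - offset, "-")


def fragment(
    locus: FlankedLocus,
    sizes: Sequence[int] = DEFAULT_SIZES,
    step: int = DEFAULT_STEP,
) -> list[CandidateWindow]:
    """Sliding windows of each size at offsets 0, step, 2*step, ...

    Windows carry genomic coordinates; exact duplicate sequences within the
    locus are collapsed keeping the first occurrence.  Deterministic and
    order-stable (sizes in given order, then offsets ascending).  When the
    stride does not land exactly on the locus end a final flush window at
    offset len(locus) - size is added so the tail is always covered.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = locus.record.seq
    hit_iv = locus.hit.interval
    seen: set[str] = set()
    out: list[CandidateWindow] = []
    for size in sizes:
        offsets = list(range(0, len(seq) - size + 1, step))
        if offsets and offsets[-1] != len(seq) - size:
            offsets.append(len(seq) - size)
        for offset in offsets:
            wseq = seq[offset : offset + size]
            if wseq in seen:
                continue
            seen.add(wseq)
            origin = _window_genomic_interval(locus, offset, size)
            anchor = origin.intersect(
                GenomicInterval(hit_iv.seq_id, hit_iv.start, hit_iv.end, origin.strand)
            )
            if anchor is not None and anchor.length > MATURE_ANCHOR_MAX:
                # mature arms are at most 24 nt; trim from the 3' end
                if origin.strand == "+":
                    anchor = GenomicInterval(
                        anchor.seq_id, anchor.start, anchor.start + MATURE_ANCHOR_MAX, "+"
                    )
                else:
                    anchor = GenomicInterval(
                        anchor.seq_id, anchor.end - MATURE_ANCHOR_MAX, anchor.end, "-"
                    )
            out.append(
                CandidateWindow(
                    origin=origin,
                    seq=wseq,
                    size=size,
                    source_hit=locus.hit,
                    mature_anchor=anchor,
                )
            )
    return out


def _ungapped_identity(a: str, b: str) -> float:
    """Best ungapped-offset matches between two sequences / longer length."""
    if len(a) < len(b):
        a, b = b, a
    best = 0
    for off in range(len(a) - len(b) + 1):
        matches = sum(1 for x, y in zip(a[off : off + len(b)], b) if x == y)
        if matches > best:
            best = matches
    return best / len(a)


def dedupe(
    seqs: Iterable[str], identity_threshold: float = 1.0
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy length-descending redundancy removal (CD-HIT style).

    A sequence joins the first existing representative with global identity
    (matches over the longer length) >= threshold; otherwise it founds a new
    cluster.  Representatives are returned in input order of their first
    occurrence, with a representative -> members cluster map.
    """
    if not (0.5 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0.5, 1.0]")
    items = list(seqs)
    order = sorted(range(len(items)), key=lambda i: (-len(items[i]), i))
    reps: "OrderedDict[int, list[str]]" = OrderedDict()
    exact: dict[str, int] = {}
    for idx in order:
        s = items[idx]
        if s in exact:
            reps[exact[s]].append(s)
            continue
        assigned = False
        for rep_idx in reps:
            if _ungapped_identity(items[rep_idx], s) >= identity_threshold:
                reps[rep_idx].append(s)
                assigned = True
                break
        if not assigned:
            reps[idx] = []
            exact[s] = idx
    rep_indices = sorted(reps.keys())
    representatives = [items[i] for i in rep_indices]
    cluster_map = {items[i]: reps[i] for i in rep_indices}
    return representatives, cluster_map
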