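"""Computational validation of predicted miRNAs.

Three operators: star-sequence detection within a folded precursor
(Dicer-duplex convention, 2-nt 3' overhang, bounded unpaired positions),
exact matching against small-RNA read sets (100% identity and coverage, no
mismatches or gaps by construction), and homology lookup of candidate
matures against a user-supplied reference miRNA collection.  Degradome
validation reuses the exact-match operator on a mature+star table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import homology
from .seqio import SequenceRecord, revcomp
from .structure import FoldResult, parse_pairs

__all__ = [
    "StarCall",
    "find_star",
    "match_exact",
    "homology_lookup",
    "LookupResult",
]


@dataclass(frozen=True)
class StarCall:
    """Star-arm interval paired to a mature arm within one precursor.

    Intervals are 0-based half-open positions within the precursor.  The
    star interval includes the conventional 3' overhang extension.
    """

    star_interval: tuple[int, int]
    mature_interval: tuple[int, int]
    n_paired: int
    n_gaps: int
    offset_3p: int


def find_star(
    precursor_seq: str,
    fold: FoldResult,
    mature_interval: tuple[int, int],
    max_unpaired: int = 4,
    overhang: int = 2,
) -> StarCall | None:
    """Locate the star sequence pairing with the mature arm.

    The star spans the positions paired to the mature region in the
    dot-bracket, extended by ``overhang`` nt at its 3' end.  Returns None
    when the mature arm is unpaired or the duplex carries more than
    ``max_unpaired`` unpaired/gapped positions across both arms.
    """
    m_start, m_end = mature_interval
    n = len(precursor_seq)
    if not (0 <= m_start < m_end <= n):
        raise ValueError("mature interval outside precursor")
    if len(fold.dotbracket) != n:
        raise ValueError("fold does not match precursor length")
    partner = {}
    for i, j in parse_pairs(fold.dotbracket):
        partner[i] = j
        partner[j] = i
    partners = [partner[p] for p in range(m_start, m_end) if p in partner]
    if not partners:
        return None
    core_lo, core_hi = min(partners), max(partners) + 1
    if not (core_hi <= m_start or core_lo >= m_end):
        return None  # mature pairs with itself (e.g. sits across the loop)
    n_paired = len(partners)
    unpaired_mature = (m_end - m_start) - n_paired
    unpaired_star = (core_hi - core_lo) - n_paired
    n_gaps = unpaired_mature + unpaired_star
    if n_gaps > max_unpaired:
        return None
    star_hi = min(core_hi + overhang, n)
    star = (core_lo, star_hi)
    if not (star[1] <= m_start or star[0] >= m_end):
        star = (core_lo, core_hi)  # overhang would run into the mature arm
    return StarCall(
        star_interval=star,
        mature_interval=(m_start, m_end),
        n_paired=n_paired,
        n_gaps=n_gaps,
        offset_3p=overhang,
    )


def match_exact(
    query_seq: str,
    read_set: Sequence[SequenceRecord],
    substring: bool = True,
    both_strands: bool = True,
) -> list[str]:
    """Read ids matching the query exactly (zero mismatches/gaps, full query
    coverage).

    A read matches when it equals the query or (when ``substring``) contains
    it verbatim; the reverse complement is also searched when
    ``both_strands`` is set.  Ids are returned in read-set order.
    """
    q = query_seq.upper().replace("U", "T")
    targets = [q]
    if both_strands:
        rc = revcomp(q)
        if rc != q:
            targets.append(rc)
    out: list[str] = []
    for read in read_set:
        s = read.seq
        for t in targets:
            hit = (t in s) if substring else (t == s)
            if hit:
                out.append(read.id)
                break
    return out


@dataclass(frozen=True)
class LookupResult:
    query_id: str
    status: str  # "known" or "novel"
    best_hits: tuple[homology.HomologyHit, ...]


def homology_lookup(
    mature_set: Sequence[SequenceRecord],
    reference_mirnas: Sequence[SequenceRecord],
    max_mismatches: int = 4,
    word_len: int = 7,
    exhaustive: bool = True,
) -> list[LookupResult]:
    """Label each candidate mature as known (>=1 homologous reference hit
    within ``max_mismatches``) or novel.

    Reuses the seed-and-extend engine with the reference collection as the
    target; exhaustive scan is the default since reference sets are small.
    """
    index = homology.build_word_index(reference_mirnas, word_len)
    results: list[LookupResult] = []
    for rec in mature_set:
        hits = homology.seed_and_extend(
            rec, index, max_mismatches=max_mismatches, exhaustive=exhaustive
        )
        status = "known" if hits else "novel"
        results.append(LookupResult(rec.id, status, tuple(hits[:5])))
    return results
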