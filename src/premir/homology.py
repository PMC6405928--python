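"""Seeded homology search of short queries (mature miRNAs) against a genome.

Ungapped full-coverage model: a hit is a placement of the entire query on
either strand with at most ``max_mismatches`` substitutions.  Candidate
placements are generated from exact shared words of length ``word_len``
(default 7) and verified by Hamming distance, which guarantees completeness
for any placement retaining at least one intact word (always true for
<= floor(L/word_len) - 1 mismatches by pigeonhole).  An ``exhaustive`` mode
scans every offset on both strands for small genomes.

No E-value is computed: the conventional permissive cutoff (E=10 at word
length 7) admits every word-seeded candidate at this scale, so filtering is
by mismatch count alone.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .seqio import GenomicInterval, SequenceRecord, revcomp

__all__ = [
    "HomologyHit",
    "WordIndex",
    "build_word_index",
    "seed_and_extend",
    "select_hits",
    "read_blast_tabular",
]

DEFAULT_WORD_LEN = 7
DEFAULT_TOP_K = 10
DEFAULT_MAX_MISMATCHES = 4


@dataclass(frozen=True)
class HomologyHit:
    """A full-length ungapped placement of a query on the genome."""

    query_id: str
    interval: GenomicInterval
    mismatches: int
    aligned_len: int
    score: float
    rank: int = 0

    def sort_key(self):
        return (
            self.mismatches,
            -self.score,
            self.interval.seq_id,
            self.interval.start,
            self.interval.strand,
        )


class WordIndex:
    """Exact-word lookup over the forward strand of a sequence collection.

    Reverse-strand placements are found by searching the reverse complement
    of the query against this same forward index.
    """

    def __init__(self, records: Sequence[SequenceRecord], word_len: int):
        if word_len < 4:
            raise ValueError(f"word_len must be >= 4, got {word_len}")
        self.word_len = word_len
        self.records = {rec.id: rec for rec in records}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rec in records:
            seq = rec.seq
            for pos in range(len(seq) - word_len + 1):
                word = seq[pos : pos + word_len]
                if "N" not in word:
                    self._index[word].append((rec.id, pos))

    def lookup(self, word: str) -> list[tuple[str, int]]:
        """All (seq_id, position) occurrences of an exact word (+ strand)."""
        if len(word) != self.word_len:
            raise ValueError(
                f"word length {len(word)} != index word_len {self.word_len}"
            )
        return list(self._index.get(word, ()))


def build_word_index(
    genome: Sequence[SequenceRecord], word_len: int = DEFAULT_WORD_LEN
) -> WordIndex:
    return WordIndex(genome, word_len)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _placements_for_oriented_query(
    q: str, index: WordIndex, max_mismatches: int
) -> set[tuple[str, int]]:
    """Candidate (seq_id, start) placements of oriented query q seeded by any
    shared exact word."""
    w = index.word_len
    starts: set[tuple[str, int]] = set()
    for off in range(len(q) - w + 1):
        for seq_id, pos in index.lookup(q[off : off + w]):
            start = pos - off
            rec = index.records[seq_id]
            if 0 <= start and start + len(q) <= rec.length:
                starts.add((seq_id, start))
    return starts


def seed_and_extend(
    query: SequenceRecord,
    index: WordIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    exhaustive: bool = False,
) -> list[HomologyHit]:
    """All full-length placements of the query with <= max_mismatches.

    Placements are seeded by exact shared words unless ``exhaustive`` is set,
    in which case every offset on both strands is scanned (complete for any
    mismatch count; use for small genomes).  Hits are sorted by (mismatches
    asc, score desc, seq_id, start, strand) and ranked 1..n.
    """
    q = query.seq
    if set(q) - set("ACGT"):
        raise ValueError(f"query {query.id!r} contains ambiguous residues")
    if index.word_len > len(q):
        raise ValueError(
            f"word_len {index.word_len} exceeds query length {len(q)}"
        )
    hits: list[HomologyHit] = []
    for strand, oriented in (("+", q), ("-", revcomp(q))):
        if exhaustive:
            cands = {
                (rec.id, start)
                for rec in index.records.values()
                for start in range(rec.length - len(q) + 1)
            }
        else:
            cands = _placements_for_oriented_query(oriented, index, max_mismatches)
        for seq_id, start in cands:
            target = index.records[seq_id].seq[start : start + len(q)]
            mm = _hamming(oriented, target)
            if mm <= max_mismatches:
                hits.append(
                    HomologyHit(
                        query_id=query.id,
                        interval=GenomicInterval(seq_id, start, start + len(q), strand),
                        mismatches=mm,
                        aligned_len=len(q),
                        score=float(len(q) - 2 * mm),
                    )
                )
    hits.sort(key=HomologyHit.sort_key)
    return [replace(h, rank=i + 1) for i, h in enumerate(hits)]


def select_hits(
    hits: Iterable[HomologyHit],
    top_k: int = DEFAULT_TOP_K,
    max_mismatches_exclusive: int = 5,
) -> list[HomologyHit]:
    """Per query: drop hits with >= max_mismatches_exclusive mismatches, then
    keep the best top_k (hits assumed pre-sorted per query)."""
    per_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        if h.mismatches < max_mismatches_exclusive:
            per_query[h.query_id].append(h)
    out: list[HomologyHit] = []
    for qid in per_query:
        kept = sorted(per_query[qid], key=HomologyHit.sort_key)[:top_k]
        out.extend(replace(h, rank=i + 1) for i, h in enumerate(kept))
    return out


def read_blast_tabular(path, query_lengths: dict[str, int]) -> list[HomologyHit]:
    """Adapter: parse BLAST outfmt-6 rows into HomologyHits.

    Only full-coverage ungapped rows are convertible; others are skipped.
    Intended for users running an external blastn (word_size 7, evalue 10).
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            length, mm, gaps = int(f[3]), int(f[4]), int(f[5])
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            qlen = query_lengths.get(qid)
            if qlen is None or gaps or length != qlen or qstart != 1 or qend != qlen:
                continue
            strand = "+" if send >= sstart else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            hits.append(
                HomologyHit(
                    query_id=qid,
                    interval=GenomicInterval(sid, lo - 1, hi, strand),
                    mismatches=mm,
                    aligned_len=length,
                    score=float(length - 2 * mm),
                )
            )
    hits.sort(key=HomologyHit.sort_key)
    return [replace(h, rank=i + 1) for i, h in enumerate(hits)]
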