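"""Sequence I/O and coordinate bookkeeping.

All internal coordinates are 0-based, half-open.  Conversion to 1-based
inclusive happens only in the GFF3 writer.  Sequences are stored in DNA
space (U normalized to T); the folding backend converts to RNA space
transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "extract",
    "revcomp",
    "to_rna",
    "to_dna",
    "write_gff3",
    "write_bed",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA_ALPHABET = frozenset("ACGTN")
UNAMBIGUOUS = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised on malformed FASTA/FASTQ input; message carries the line number."""


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U treated as T's complement partner A)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence.

    ``seq`` is upper-case DNA space over {A,C,G,T,N}; ``length`` always equals
    ``len(seq)``.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", to_dna(self.seq.upper()))
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence with a strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must be > start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.seq_id,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand,
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, *, allow_n: bool = True) -> list[SequenceRecord]:
    """Read a (optionally gzipped) FASTA file into SequenceRecords.

    Records are returned in file order with sequences upper-cased and U
    normalized to T.  Duplicate ids, empty sequences, and residues before the
    first header are rejected with the offending line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_parts: list[str] = []
    header_line = 0

    def _flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_parts)
        if not seq:
            raise FastaFormatError(
                f"{path}: empty sequence for {cur_id!r} (header at line {header_line})"
            )
        records.append(SequenceRecord(cur_id, seq))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FastaFormatError(
                        f"{path}: empty FASTA header at line {lineno}"
                    )
                if cur_id in seen:
                    raise FastaFormatError(
                        f"{path}: duplicate id {cur_id!r} at line {lineno}"
                    )
                seen.add(cur_id)
                cur_parts = []
                header_line = lineno
            else:
                if cur_id is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                cur_parts.append(line)
    _flush()
    if not allow_n:
        for rec in records:
            if "N" in rec.seq:
                raise FastaFormatError(
                    f"{path}: record {rec.id!r} contains ambiguous residues (N)"
                )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Minimal FASTQ reader (qualities discarded)."""
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) % 4 != 0:
        raise FastaFormatError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FastaFormatError(f"{path}: malformed FASTQ record at line {i + 1}")
        if len(qual) != len(seq):
            raise FastaFormatError(
                f"{path}: quality/sequence length mismatch at line {i + 1}"
            )
        records.append(SequenceRecord(head[1:].split()[0], seq))
    return records


def as_mapping(records: Sequence[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {rec.id: rec for rec in records}


def extract(interval: GenomicInterval, records) -> str:
    """Extract the interval's sequence; reverse complement on the '-' strand.

    ``records`` may be a list of SequenceRecords or an id->record mapping.
    """
    if not isinstance(records, dict):
        records = as_mapping(records)
    try:
        rec = records[interval.seq_id]
    except KeyError:
        raise KeyError(f"unknown seq_id {interval.seq_id!r}") from None
    if interval.end > rec.length:
        raise ValueError(
            f"interval [{interval.start},{interval.end}) exceeds length "
            f"{rec.length} of {interval.seq_id!r}"
        )
    sub = rec.seq[interval.start : interval.end]
    return revcomp(sub) if interval.strand == "-" else sub


@dataclass
class Prediction:
    """A located prediction for writers: interval plus id, score, attributes."""

    id: str
    interval: GenomicInterval
    score: float
    attributes: dict = field(default_factory=dict)


def write_gff3(predictions: Iterable[Prediction], path, source: str = "premir") -> None:
    """GFF3 (1-based inclusive), feature type pre_miRNA, score = SVM decision."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for p in predictions:
            attrs = ";".join(
                [f"ID={p.id}"]
                + [f"{k}={v}" for k, v in sorted(p.attributes.items())]
            )
            fh.write(
                "\t".join(
                    [
                        p.interval.seq_id,
                        source,
                        "pre_miRNA",
                        str(p.interval.start + 1),
                        str(p.interval.end),
                        f"{p.score:.6g}",
                        p.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(predictions: Iterable[Prediction], path) -> None:
    """BED6 (0-based half-open), score column carries the SVM decision value."""
    with _open_text(path, "wt") as fh:
        for p in predictions:
            fh.write(
                "\t".join(
                    [
                        p.interval.seq_id,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.id,
                        f"{p.score:.6g}",
                        p.interval.strand,
                    ]
                )
                + "\n"
            )


def read_gff3_intervals(path) -> list[Prediction]:
    """Read back GFF3 rows written by :func:`write_gff3` (convenience)."""
    out: list[Prediction] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            out.append(
                Prediction(
                    id=attrs.get("ID", "."),
                    interval=GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]),
                    score=float(f[5]) if f[5] != "." else 0.0,
                    attributes=attrs,
                )
            )
    return out
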