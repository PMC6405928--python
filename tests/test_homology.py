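"""Seed-and-extend against a brute-force Hamming oracle."""

import random

import pytest

from premir.homology import (
    HomologyHit,
    build_word_index,
    read_blast_tabular,
    seed_and_extend,
    select_hits,
)
from premir.seqio import SequenceRecord, revcomp

from conftest import random_dna


def brute_force_hits(query: str, records, max_mismatches: int):
    """Exhaustive Hamming scan over all offsets and both strands."""
    found = set()
    for rec in records:
        for strand, oriented in (("+", query), ("-", revcomp(query))):
            for start in range(rec.length - len(query) + 1):
                window = rec.seq[start : start + len(query)]
                mm = sum(1 for a, b in zip(oriented, window) if a != b)
                if mm <= max_mismatches:
                    found.add((rec.id, start, strand, mm))
    return found


def as_tuples(hits):
    return {
        (h.interval.seq_id, h.interval.start, h.interval.strand, h.mismatches)
        for h in hits
    }


class TestWordIndex:
    def test_positions(self):
        idx = build_word_index([SequenceRecord("g", "ACGTACGT")], word_len=4)
        assert sorted(p for _, p in idx.lookup("ACGT")) == [0, 4]

    def test_absent_word(self):
        idx = build_word_index([SequenceRecord("g", "ACGTACGT")], word_len=4)
        assert idx.lookup("GGGG") == []

    def test_word_len_validation(self):
        with pytest.raises(ValueError):
            build_word_index([SequenceRecord("g", "ACGT")], word_len=3)

    def test_palindrome_minus_strand_counts(self):
        # ACGT is its own revcomp: searching the revcomp query against the
        # forward index must find the same positions as a brute-force scan
        genome = [SequenceRecord("g", "ACGTACGT")]
        query = SequenceRecord("q", "ACGT")
        idx = build_word_index(genome, word_len=4)
        hits = seed_and_extend(query, idx, max_mismatches=0)
        oracle = brute_force_hits("ACGT", genome, 0)
        assert as_tuples(hits) == oracle
        assert sum(1 for h in hits if h.interval.strand == "-") == 2


class TestSeedAndExtend:
    def _genome_with_plant(self, rng, planted, length=2000, at=900):
        bg = random_dna(rng, length)
        seq = bg[:at] + planted + bg[at + len(planted):]
        return [SequenceRecord("g", seq)]

    def test_exact_planted_copy(self, rng):
        q = random_dna(rng, 21)
        genome = self._genome_with_plant(rng, q)
        idx = build_word_index(genome, 7)
        hits = seed_and_extend(SequenceRecord("q", q), idx, 0)
        exact = [h for h in hits if h.mismatches == 0 and h.interval.strand == "+"]
        assert len(exact) == 1
        assert exact[0].interval.start == 900
        assert exact[0].aligned_len == 21
        assert exact[0].score == 21

    def test_three_scattered_substitutions(self, rng):
        q = random_dna(rng, 21)
        mutated = list(q)
        for pos in (2, 10, 18):  # no 7-mer window destroyed
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        genome = self._genome_with_plant(rng, "".join(mutated))
        idx = build_word_index(genome, 7)
        hits = seed_and_extend(SequenceRecord("q", q), idx, 4)
        oracle = brute_force_hits(q, genome, 4)
        assert as_tuples(hits) == oracle
        assert any(h.mismatches == 3 for h in hits)

    def test_six_substitutions_not_reported(self, rng):
        q = random_dna(rng, 21)
        mutated = list(q)
        for pos in (0, 4, 8, 12, 16, 20):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        genome = self._genome_with_plant(rng, "".join(mutated))
        idx = build_word_index(genome, 7)
        hits = seed_and_extend(SequenceRecord("q", q), idx, 4)
        assert all(h.interval.start != 900 or h.interval.strand == "-" for h in hits)

    def test_ambiguous_query_rejected(self, rng):
        genome = self._genome_with_plant(rng, random_dna(rng, 21))
        idx = build_word_index(genome, 7)
        with pytest.raises(ValueError, match="ambiguous"):
            seed_and_extend(SequenceRecord("q", "ACGTNACGTACGTACGTACGT"), idx, 0)

    def test_sorted_and_ranked(self, rng):
        genome = [SequenceRecord("g", random_dna(rng, 8000))]
        idx = build_word_index(genome, 7)
        q = genome[0].seq[100:121]
        hits = seed_and_extend(SequenceRecord("q", q), idx, 4)
        assert [h.rank for h in hits] == list(range(1, len(hits) + 1))
        keys = [h.sort_key() for h in hits]
        assert keys == sorted(keys)

    def test_hits_within_bounds(self, rng):
        genome = [SequenceRecord("g", random_dna(rng, 500))]
        idx = build_word_index(genome, 7)
        q = genome[0].seq[480:500]  # at the boundary
        hits = seed_and_extend(SequenceRecord("q", q), idx, 2)
        for h in hits:
            assert 0 <= h.interval.start and h.interval.end <= 500

    def test_minus_strand_hit_revcomp_verified(self, rng):
        q = random_dna(rng, 21)
        genome = self._genome_with_plant(rng, revcomp(q))
        idx = build_word_index(genome, 7)
        hits = seed_and_extend(SequenceRecord("q", q), idx, 0)
        minus = [h for h in hits if h.interval.strand == "-"]
        assert len(minus) == 1
        g = genome[0].seq
        iv = minus[0].interval
        assert revcomp(g[iv.start : iv.end]) == q

    @pytest.mark.parametrize("trial", range(8))
    def test_oracle_equivalence_le2_mismatches(self, trial):
        rng = random.Random(1000 + trial)
        genome = [SequenceRecord("g", random_dna(rng, rng.randint(2000, 10000)))]
        q = random_dna(rng, 21)
        idx = build_word_index(genome, 7)
        got = as_tuples(seed_and_extend(SequenceRecord("q", q), idx, 2))
        assert got == brute_force_hits(q, genome, 2)

    def test_exhaustive_mode_complete_at_high_mismatch(self, rng):
        genome = [SequenceRecord("g", random_dna(rng, 3000))]
        q = random_dna(rng, 21)
        idx = build_word_index(genome, 7)
        got = as_tuples(
            seed_and_extend(SequenceRecord("q", q), idx, 6, exhaustive=True)
        )
        assert got == brute_force_hits(q, genome, 6)


def _mk_hit(qid, mm, start, rank=0):
    from premir.seqio import GenomicInterval

    return HomologyHit(
        query_id=qid,
        interval=GenomicInterval("g", start, start + 21),
        mismatches=mm,
        aligned_len=21,
        score=float(21 - 2 * mm),
        rank=rank,
    )


class TestSelectHits:
    def test_top_10_of_12(self):
        hits = [_mk_hit("q", mm, 100 * i) for i, mm in enumerate([0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 4, 4])]
        kept = select_hits(hits, top_k=10, max_mismatches_exclusive=5)
        assert len(kept) == 10
        assert [h.rank for h in kept] == list(range(1, 11))

    def test_all_at_5_mismatches_dropped(self):
        hits = [_mk_hit("q", 5, 100 * i) for i in range(4)]
        assert select_hits(hits) == []

    def test_fewer_than_top_k_all_kept(self):
        hits = [_mk_hit("q", 1, 100 * i) for i in range(3)]
        assert len(select_hits(hits, top_k=10)) == 3

    def test_per_query_grouping(self):
        hits = [_mk_hit("a", 0, 0), _mk_hit("b", 0, 50), _mk_hit("b", 1, 90)]
        kept = select_hits(hits, top_k=1)
        assert {h.query_id for h in kept} == {"a", "b"}
        assert len(kept) == 2


def test_blast_tabular_adapter(tmp_path):
    p = tmp_path / "hits.tsv"
    # full-coverage ungapped 21-mer hits, one forward one reverse
    p.write_text(
        "q1\tchr1\t100.0\t21\t0\t0\t1\t21\t501\t521\t1e-5\t42.0\n"
        "q1\tchr1\t90.5\t21\t2\t0\t1\t21\t800\t780\t1e-3\t30.0\n"
        "q1\tchr1\t90.5\t18\t2\t0\t1\t18\t900\t917\t1e-3\t30.0\n"  # partial: skipped
    )
    hits = read_blast_tabular(p, {"q1": 21})
    assert len(hits) == 2
    assert hits[0].interval.start == 500 and hits[0].interval.strand == "+"
    assert hits[1].interval.strand == "-"
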