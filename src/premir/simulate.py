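"""Synthetic fixtures with known ground truth.

Generates genomes with planted filter-passing hairpin precursors, decoy
intervals (dinucleotide-shuffled hairpins and ORF-like stretches), companion
known-mature FASTA records for the homology stage, pseudo-hairpin training
negatives, and Gaussian feature clouds for classifier tests.  Everything is
seeded and reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import features as feat_mod
from .seqio import (
    GenomicInterval,
    Prediction,
    SequenceRecord,
    revcomp,
    write_bed,
    write_fasta,
    write_gff3,
)
from .structure import FilterConfig, HairpinCandidate, fold, hairpin_metrics, passes_filter

__all__ = [
    "PlantedPrecursor",
    "PlantedTruth",
    "make_hairpin",
    "dinucleotide_shuffle",
    "make_genome",
    "make_feature_cloud",
    "make_training_set",
]

MATURE_LEN = 21


def _rng(seed) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


def _random_seq(rng: random.Random, n: int, gc: float = 0.5) -> str:
    return "".join(
        (rng.choice("GC") if rng.random() < gc else rng.choice("AT")) for _ in range(n)
    )


def make_hairpin(
    seed,
    arm_len: int,
    loop_len: int,
    gc_target: float = 0.5,
    bulges: int = 0,
    gc_tol: float = 0.05,
) -> str:
    """arm + loop + reverse complement of arm, with ``bulges`` random
    unpaired insertions in the 3' arm.

    Realized GC fraction is within ``gc_tol`` of ``gc_target`` (resampled up
    to a bounded number of attempts).  By construction the maximum-pairing
    structure contains a stem of at least arm_len - bulges pairs.
    """
    if not (15 <= arm_len <= 60):
        raise ValueError("arm_len must be in [15, 60]")
    if not (3 <= loop_len <= 20):
        raise ValueError("loop_len must be in [3, 20]")
    rng = _rng(seed)
    total = 2 * arm_len + loop_len + bulges
    for _attempt in range(500):
        arm = _random_seq(rng, arm_len, gc_target)
        loop = _random_seq(rng, loop_len, gc_target)
        arm3 = list(revcomp(arm))
        for _ in range(bulges):
            pos = rng.randrange(1, len(arm3))  # keep closing pair intact
            arm3.insert(pos, rng.choice("ACGT"))
        seq = arm + loop + "".join(arm3)
        gc = (seq.count("G") + seq.count("C")) / total
        if abs(gc - gc_target) <= gc_tol:
            return seq
    raise ValueError(
        f"could not realize GC {gc_target:.2f} +/- {gc_tol:.2f} for this composition"
    )


def dinucleotide_shuffle(seq: str, seed) -> str:
    """Altschul-Erikson shuffle preserving the exact dinucleotide multiset."""
    rng = _rng(seed)
    if len(seq) < 3:
        return seq
    # adjacency lists of the dinucleotide walk
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random last edge per vertex forming a tree into `last`
    for _attempt in range(200):
        lasts: dict[str, str] = {}
        for v, targets in edges.items():
            if v != last:
                lasts[v] = rng.choice(targets)
        # check connectivity of the "last edge" graph to `last`
        ok = True
        for v in edges:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = lasts.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        rest: dict[str, list[str]] = {}
        for v, targets in edges.items():
            pool = list(targets)
            if v in lasts:
                pool.remove(lasts[v])
            rng.shuffle(pool)
            rest[v] = pool
        out = [seq[0]]
        counters = {v: 0 for v in edges}
        cur = seq[0]
        total_edges = len(seq) - 1
        for _ in range(total_edges):
            pool = rest[cur]
            if counters[cur] < len(pool):
                nxt = pool[counters[cur]]
                counters[cur] += 1
            else:
                nxt = lasts[cur]
            out.append(nxt)
            cur = nxt
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")


_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _orf_like(rng: random.Random, n_codons: int) -> str:
    return "ATG" + "".join(rng.choice(_CODONS) for _ in range(n_codons)) + rng.choice(
        sorted(_STOPS)
    )


@dataclass(frozen=True)
class PlantedPrecursor:
    interval: GenomicInterval
    arm_len: int
    loop_len: int
    gc: float
    mature_interval: GenomicInterval
    seq: str


@dataclass
class PlantedTruth:
    genome: list[SequenceRecord]
    precursors: list[PlantedPrecursor]
    decoys: list[GenomicInterval]
    known_matures: list[SequenceRecord] = field(default_factory=list)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "truth": outdir / "truth.gff3",
            "known": outdir / "known_mirnas.fasta",
            "decoys": outdir / "decoys.bed",
        }
        write_fasta(self.genome, paths["genome"])
        write_fasta(self.known_matures, paths["known"])
        write_gff3(
            [
                Prediction(
                    id=f"plant{i}",
                    interval=p.interval,
                    score=0.0,
                    attributes={
                        "arm_len": p.arm_len,
                        "loop_len": p.loop_len,
                        "mature_start": p.mature_interval.start,
                        "mature_end": p.mature_interval.end,
                    },
                )
                for i, p in enumerate(self.precursors)
            ],
            paths["truth"],
            source="simulate",
        )
        write_bed(
            [
                Prediction(id=f"decoy{i}", interval=iv, score=0.0)
                for i, iv in enumerate(self.decoys)
            ],
            paths["decoys"],
        )
        return paths


POS_PARAMS = dict(arm_range=(22, 38), loop_range=(4, 8), gc_range=(0.48, 0.66), bulge_range=(0, 1))
NEG_PARAMS = dict(arm_range=(26, 36), loop_range=(10, 18), gc_range=(0.30, 0.46), bulge_range=(2, 5))


def _sample_filter_passing_hairpin(
    rng: random.Random,
    params: dict,
    filter_cfg: FilterConfig,
    backend: str = "thermo",
    max_tries: int = 200,
) -> tuple[str, int, int, float]:
    """Draw hairpin parameters until the folded hairpin passes the filter."""
    for _ in range(max_tries):
        arm = rng.randint(*params["arm_range"])
        loop = rng.randint(*params["loop_range"])
        gc = rng.uniform(*params["gc_range"])
        bulges = rng.randint(*params["bulge_range"])
        try:
            seq = make_hairpin(rng, arm, loop, gc, bulges)
        except ValueError:
            continue
        m = hairpin_metrics(seq, fold(seq, backend=backend))
        ok, _failed = passes_filter(m, filter_cfg)
        if ok:
            return seq, arm, loop, gc
    raise RuntimeError("could not sample a filter-passing hairpin")


def make_genome(
    n_precursors: int = 20,
    n_decoys: int = 10,
    bg_len: int = 50_000,
    seed: int = 0,
    filter_cfg: FilterConfig | None = None,
    backend: str = "thermo",
    seq_id: str = "chrSim",
) -> PlantedTruth:
    """A uniform-background genome with planted hairpin precursors and decoys.

    Every planted precursor is verified to pass the pseudo-hairpin filter at
    generation time; its first 21 nt (the 5' mature arm) is emitted as a
    known-mature query so the homology stage has honest seeds.
    """
    min_len = 10 * (n_precursors + n_decoys) * 150
    if bg_len < min_len:
        raise ValueError(f"bg_len must be >= {min_len} for this many plants")
    rng = random.Random(seed)
    filter_cfg = filter_cfg or FilterConfig()
    genome = list(_random_seq(rng, bg_len))
    placed: list[tuple[int, int]] = []

    def _place(length: int) -> int:
        for _ in range(1000):
            start = rng.randrange(0, bg_len - length)
            if all(start + length + 50 <= s or e + 50 <= start for s, e in placed):
                placed.append((start, start + length))
                return start
        raise RuntimeError("placement collision after bounded retries")

    precursors: list[PlantedPrecursor] = []
    matures: list[SequenceRecord] = []
    for i in range(n_precursors):
        seq, arm, loop, gc = _sample_filter_passing_hairpin(
            rng, POS_PARAMS, filter_cfg, backend
        )
        start = _place(len(seq))
        genome[start : start + len(seq)] = list(seq)
        iv = GenomicInterval(seq_id, start, start + len(seq), "+")
        mature_iv = GenomicInterval(seq_id, start, start + MATURE_LEN, "+")
        precursors.append(
            PlantedPrecursor(iv, arm, loop, gc, mature_iv, seq)
        )
        matures.append(SequenceRecord(f"mat{i}", seq[:MATURE_LEN]))

    decoys: list[GenomicInterval] = []
    for i in range(n_decoys):
        if i % 2 == 0:
            hp, *_ = _sample_filter_passing_hairpin(
                rng, NEG_PARAMS, filter_cfg, backend
            )
            dseq = dinucleotide_shuffle(hp, rng)
        else:
            dseq = _orf_like(rng, rng.randint(40, 90))
        start = _place(len(dseq))
        genome[start : start + len(dseq)] = list(dseq)
        decoys.append(GenomicInterval(seq_id, start, start + len(dseq), "+"))

    return PlantedTruth(
        genome=[SequenceRecord(seq_id, "".join(genome))],
        precursors=precursors,
        decoys=decoys,
        known_matures=matures,
    )


def make_feature_cloud(
    n_per_class: int,
    dim: int = 10,
    shift: float = 0.0,
    seed: int = 0,
    n_informative: int | None = None,
) -> feat_mod.LabeledSet:
    """Two unit-variance Gaussian classes separated by ``shift`` sigma on the
    informative dimensions (all of them by default)."""
    rng = np.random.default_rng(seed)
    k = dim if n_informative is None else n_informative
    mu = np.zeros(dim)
    mu[:k] = shift / 2.0
    X_pos = rng.normal(size=(n_per_class, dim)) + mu
    X_neg = rng.normal(size=(n_per_class, dim)) - mu
    catalog = feat_mod.FeatureCatalog(
        tuple((f"f{i}", "NORMALIZED", "synthetic gaussian feature") for i in range(dim))
    )
    vectors = [
        feat_mod.FeatureVector(f"pos{i}", tuple(map(float, row)))
        for i, row in enumerate(X_pos)
    ] + [
        feat_mod.FeatureVector(f"neg{i}", tuple(map(float, row)))
        for i, row in enumerate(X_neg)
    ]
    labels = [1] * n_per_class + [-1] * n_per_class
    return feat_mod.LabeledSet(vectors=vectors, labels=labels, catalog=catalog)


def make_training_set(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    window_sizes=(90, 100, 110, 120),
    catalog: feat_mod.FeatureCatalog | None = None,
    backend: str = "thermo",
    filter_cfg: FilterConfig | None = None,
) -> feat_mod.LabeledSet:
    """Precursor-like positives vs pseudo-hairpin negatives, each embedded in
    a random window of a configured size, folded and featurized.

    Mirrors the distribution the genome scan sees, so a model trained here
    transfers to planted-genome recovery.
    """
    rng = random.Random(seed)
    catalog = catalog or feat_mod.default_catalog()
    filter_cfg = filter_cfg or FilterConfig()
    vectors: list[feat_mod.FeatureVector] = []
    labels: list[int] = []
    for label, count, params in ((1, n_pos, POS_PARAMS), (-1, n_neg, NEG_PARAMS)):
        made = 0
        while made < count:
            hp, *_ = _sample_filter_passing_hairpin(rng, params, filter_cfg, backend)
            size = rng.choice([s for s in window_sizes if s >= len(hp)] or [max(window_sizes)])
            pad = max(0, size - len(hp))
            left = rng.randint(0, pad)
            win = _random_seq(rng, left) + hp + _random_seq(rng, pad - left)
            fr = fold(win, backend=backend)
            fv = feat_mod.compute_features(win, fr, catalog)
            vectors.append(
                feat_mod.FeatureVector(
                    f"{'pos' if label == 1 else 'neg'}{made}", fv.values, fv.flags
                )
            )
            labels.append(label)
            made += 1
    return feat_mod.LabeledSet(vectors=vectors, labels=labels, catalog=catalog)
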