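"""Per-candidate feature vectors, significance-based selection, and the
CDS-derived negative training set.

The default catalog is an explicit reconstruction of the classic plant
pre-miRNA feature families:

* COMP        - mono-, di- and trinucleotide frequencies plus GC% (85)
* TRIPLET     - 32 paired/unpaired triplet elements (centre nucleotide x 8
                pairing patterns of a 3-nt window, normalised over windows)
* MFE_DERIVED - MFE, AMFE = 100*MFE/len, MFEI1 = AMFE/GC%,
                MFEI2 = MFE/n_stems, MFEI3 = MFE/n_hairpin_loops,
                MFEI4 = MFE/n_bp (6)
* TOPOLOGY    - n_bp, n_stems, n_hairpin_loops, stem_len,
                terminal_loop_len, dP = n_bp/len (6)
* NORMALIZED  - per-length variants of the topology counts (4)

133 features in total.  Zero denominators yield feature value 0 and are
flagged in the returned provenance.  Users with an exact published feature
list can register a custom catalog; models record a catalog hash and refuse
to score against a mismatched one.
"""

from __future__ import annotations

import hashlib
import itertools
import random
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .structure import (
    FilterConfig,
    FoldResult,
    HairpinCandidate,
    fold,
    hairpin_metrics,
    passes_filter,
)

__all__ = [
    "FeatureCatalog",
    "FeatureVector",
    "LabeledSet",
    "default_catalog",
    "compute_features",
    "select_features",
    "build_negative_set",
    "NegativeSetError",
]

NUCS = "ACGU"
FAMILIES = ("COMP", "TRIPLET", "MFE_DERIVED", "TOPOLOGY", "NORMALIZED")


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, named feature definitions grouped into families."""

    entries: tuple[tuple[str, str, str], ...]  # (name, family, formula_doc)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def families(self) -> list[str]:
        return [e[1] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def digest(self) -> str:
        h = hashlib.sha256()
        for name, family, doc in self.entries:
            h.update(f"{name}\t{family}\n".encode())
        return h.hexdigest()[:16]

    def subset(self, names: list[str]) -> "FeatureCatalog":
        keep = set(names)
        return FeatureCatalog(tuple(e for e in self.entries if e[0] in keep))


@dataclass(frozen=True)
class FeatureVector:
    candidate_id: str
    values: tuple[float, ...]
    flags: tuple[str, ...] = ()  # names of zero-guarded features

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class LabeledSet:
    vectors: list[FeatureVector]
    labels: list[int]
    catalog: FeatureCatalog

    def __post_init__(self) -> None:
        if len(self.vectors) != len(self.labels):
            raise ValueError("vectors and labels length mismatch")
        if any(lab not in (-1, 1) for lab in self.labels):
            raise ValueError("labels must be +1/-1")

    def matrix(self) -> np.ndarray:
        return np.array([v.values for v in self.vectors], dtype=float)

    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)


def default_catalog() -> FeatureCatalog:
    entries: list[tuple[str, str, str]] = []
    for n in NUCS:
        entries.append((f"freq_{n}", "COMP", f"count({n})/len"))
    for a, b in itertools.product(NUCS, repeat=2):
        entries.append((f"freq_{a}{b}", "COMP", f"count({a}{b})/(len-1)"))
    for a, b, c in itertools.product(NUCS, repeat=3):
        entries.append((f"freq_{a}{b}{c}", "COMP", f"count({a}{b}{c})/(len-2)"))
    entries.append(("gc_percent", "COMP", "100*(G+C)/len"))
    for n in NUCS:
        for pat in range(8):
            bits = format(pat, "03b").replace("0", ".").replace("1", "(")
            entries.append(
                (f"triplet_{n}_{bits}", "TRIPLET",
                 f"freq of centre {n} with pairing pattern {bits} over 3-nt windows")
            )
    entries += [
        ("mfe", "MFE_DERIVED", "minimum folding energy (kcal/mol)"),
        ("amfe", "MFE_DERIVED", "100*MFE/len"),
        ("mfei1", "MFE_DERIVED", "AMFE/GC%"),
        ("mfei2", "MFE_DERIVED", "MFE/n_stems"),
        ("mfei3", "MFE_DERIVED", "MFE/n_hairpin_loops"),
        ("mfei4", "MFE_DERIVED", "MFE/n_bp"),
        ("n_bp", "TOPOLOGY", "total base pairs"),
        ("n_stems", "TOPOLOGY", "maximal contiguous helices"),
        ("n_hairpin_loops", "TOPOLOGY", "hairpin loop count"),
        ("stem_len", "TOPOLOGY", "base pairs in longest bridged stem"),
        ("terminal_loop_len", "TOPOLOGY", "terminal loop size of longest stem"),
        ("dP", "TOPOLOGY", "n_bp/len"),
        ("n_stems_per_nt", "NORMALIZED", "n_stems/len"),
        ("n_loops_per_nt", "NORMALIZED", "n_hairpin_loops/len"),
        ("stem_len_per_nt", "NORMALIZED", "stem_len/len"),
        ("terminal_loop_per_nt", "NORMALIZED", "terminal_loop_len/len"),
    ]
    return FeatureCatalog(tuple(entries))


def compute_features(
    seq: str, fold_result: FoldResult, catalog: FeatureCatalog | None = None
) -> FeatureVector:
    """Pure function (seq, fold, catalog) -> ordered feature values."""
    catalog = catalog or default_catalog()
    rna = seq.upper().replace("T", "U")
    n = len(rna)
    db = fold_result.dotbracket
    if len(db) != n:
        raise ValueError("fold does not match sequence")
    metrics = hairpin_metrics(seq, fold_result)

    mono = {c: rna.count(c) / n for c in NUCS}
    di = {}
    for a, b in itertools.product(NUCS, repeat=2):
        di[a + b] = (
            sum(1 for i in range(n - 1) if rna[i] == a and rna[i + 1] == b) / (n - 1)
            if n > 1
            else 0.0
        )
    tri = {}
    if n > 2:
        counts: dict[str, int] = {}
        for i in range(n - 2):
            counts[rna[i : i + 3]] = counts.get(rna[i : i + 3], 0) + 1
        for k in itertools.product(NUCS, repeat=3):
            key = "".join(k)
            tri[key] = counts.get(key, 0) / (n - 2)
    else:
        tri = {"".join(k): 0.0 for k in itertools.product(NUCS, repeat=3)}

    paired = ["(" if c in "()" else "." for c in db]
    triplet: dict[str, float] = {}
    n_windows = n - 2
    if n_windows > 0:
        for i in range(1, n - 1):
            pat = paired[i - 1] + paired[i] + paired[i + 1]
            key = f"{rna[i]}_{pat}"
            triplet[key] = triplet.get(key, 0) + 1
        triplet = {k: v / n_windows for k, v in triplet.items()}

    flags: list[str] = []

    def safe_div(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    mfe = metrics.mfe
    amfe = 100.0 * mfe / n
    derived = {
        "mfe": mfe,
        "amfe": amfe,
        "mfei1": safe_div(amfe, metrics.gc_percent, "mfei1"),
        "mfei2": safe_div(mfe, metrics.n_stems, "mfei2"),
        "mfei3": safe_div(mfe, metrics.n_hairpin_loops, "mfei3"),
        "mfei4": safe_div(mfe, metrics.n_bp, "mfei4"),
        "n_bp": float(metrics.n_bp),
        "n_stems": float(metrics.n_stems),
        "n_hairpin_loops": float(metrics.n_hairpin_loops),
        "stem_len": float(metrics.stem_len),
        "terminal_loop_len": float(metrics.terminal_loop_len),
        "dP": metrics.n_bp / n,
        "n_stems_per_nt": metrics.n_stems / n,
        "n_loops_per_nt": metrics.n_hairpin_loops / n,
        "stem_len_per_nt": metrics.stem_len / n,
        "terminal_loop_per_nt": metrics.terminal_loop_len / n,
        "gc_percent": metrics.gc_percent,
    }

    values: list[float] = []
    for name, family, _doc in catalog.entries:
        if name.startswith("freq_"):
            k = name[5:]
            src = {1: mono, 2: di, 3: tri}[len(k)]
            values.append(src[k])
        elif name.startswith("triplet_"):
            nuc, pat = name[8:].split("_")
            values.append(triplet.get(f"{nuc}_{pat}", 0.0))
        elif name in derived:
            values.append(derived[name])
        else:
            raise KeyError(f"catalog feature {name!r} is not computable")
    arr = np.asarray(values)
    if not np.all(np.isfinite(arr)):
        raise AssertionError("non-finite feature value produced")
    return FeatureVector(
        candidate_id="", values=tuple(float(v) for v in values), flags=tuple(flags)
    )


@dataclass
class SelectionReport:
    names: list[str]
    statistic: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray
    retained: list[str]

    def to_rows(self) -> list[tuple[str, float, float, float, bool]]:
        keep = set(self.retained)
        return [
            (n, float(u), float(p), float(q), n in keep)
            for n, u, p, q in zip(self.names, self.statistic, self.pvalue, self.qvalue)
        ]


def select_features(
    train: LabeledSet, alpha: float = 0.05
) -> tuple[FeatureCatalog, SelectionReport]:
    """Per-feature two-sided Mann-Whitney U between classes with
    Benjamini-Hochberg control at FDR ``alpha``; constant features get p=1.

    Returns the retained sub-catalog (original order preserved) and a full
    per-feature report.
    """
    X = train.matrix()
    y = train.y()
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) < 20 or len(neg) < 20:
        raise ValueError("need >= 20 members per class for selection")
    names = train.catalog.names
    u_stats = np.zeros(X.shape[1])
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        a, b = pos[:, j], neg[:, j]
        if np.ptp(X[:, j]) == 0:
            u_stats[j] = len(a) * len(b) / 2.0
            pvals[j] = 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        u_stats[j] = res.statistic
        pvals[j] = res.pvalue
    qvals = stats.false_discovery_control(pvals, method="bh")
    retained = [names[j] for j in range(len(names)) if qvals[j] < alpha]
    report = SelectionReport(
        names=names, statistic=u_stats, pvalue=pvals, qvalue=qvals, retained=retained
    )
    return train.catalog.subset(retained), report


class NegativeSetError(RuntimeError):
    def __init__(self, message: str, attrition: dict[str, int]):
        super().__init__(message)
        self.attrition = attrition


def build_negative_set(
    cds_records,
    n_required: int,
    filter_cfg: FilterConfig | None = None,
    window_sizes=(90, 100, 110, 120),
    window_step: int = 10,
    seed: int = 0,
    backend: str = "thermo",
) -> list[HairpinCandidate]:
    """Filter-passing pseudo-hairpin windows drawn from coding sequences.

    Windows of the configured sizes are enumerated over every CDS record,
    visited in seeded random order, folded and filtered; the first
    ``n_required`` passers are returned.  Raises NegativeSetError with an
    attrition table per criterion when the supply is insufficient.
    """
    filter_cfg = filter_cfg or FilterConfig()
    if not cds_records:
        raise ValueError("cds_records is empty")
    windows: list[tuple[str, int, int]] = []  # (rec_id, offset, size)
    seqs = {rec.id: rec.seq for rec in cds_records}
    for rec in cds_records:
        for size in window_sizes:
            for off in range(0, len(rec.seq) - size + 1, window_step):
                windows.append((rec.id, off, size))
    rng = random.Random(seed)
    rng.shuffle(windows)
    out: list[HairpinCandidate] = []
    attrition: dict[str, int] = {"total_windows": len(windows), "examined": 0}
    for rec_id, off, size in windows:
        if len(out) >= n_required:
            break
        attrition["examined"] += 1
        seq = seqs[rec_id][off : off + size]
        if "N" in seq:
            attrition["ambiguous"] = attrition.get("ambiguous", 0) + 1
            continue
        fr = fold(seq, backend=backend)
        m = hairpin_metrics(seq, fr)
        ok, failed = passes_filter(m, filter_cfg)
        if ok:
            out.append(
                HairpinCandidate(
                    id=f"neg|{rec_id}:{off}-{off + size}",
                    seq=seq,
                    fold=fr,
                    metrics=m,
                )
            )
        else:
            for crit in failed:
                attrition[crit] = attrition.get(crit, 0) + 1
    if len(out) < n_required:
        raise NegativeSetError(
            f"only {len(out)}/{n_required} filter-passing negative windows found; "
            f"attrition: {attrition}",
            attrition,
        )
    return out
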