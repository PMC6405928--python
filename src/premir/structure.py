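"""Hairpin folding, topology metrics, and pseudo-hairpin filtering.

The default folding backend is the bundled nearest-neighbour energy
minimiser (``thermo``).  A maximum-pairing reference backend is kept as a
test oracle, and an adapter for the external ViennaRNA engine is available
when its Python bindings are installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _fold_engine
from .seqio import GenomicInterval, to_rna

__all__ = [
    "FoldResult",
    "HairpinMetrics",
    "FilterConfig",
    "HairpinCandidate",
    "BackendUnavailableError",
    "fold",
    "parse_pairs",
    "pairs_to_dotbracket",
    "hairpin_metrics",
    "passes_filter",
    "gc_percent",
    "load_fold_fixtures",
    "BACKENDS",
]

BACKENDS = ("thermo", "reference", "vienna")


class BackendUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class FoldResult:
    """A secondary structure in dot-bracket notation plus its energy."""

    dotbracket: str
    mfe: float
    backend: str = "thermo"

    def __post_init__(self) -> None:
        depth = 0
        for c in self.dotbracket:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif c != ".":
                raise ValueError(f"invalid dot-bracket character {c!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")


def fold(seq: str, backend: str = "thermo") -> FoldResult:
    """Fold a sequence (DNA or RNA space) with the chosen backend.

    ``thermo``   bundled nearest-neighbour minimiser (default).
    ``reference`` bundled maximum-pairing engine (test oracle).
    ``vienna``   external ViennaRNA bindings, if installed.
    """
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} nt, need >= 10)")
    rna = to_rna(seq.upper())
    if backend == "thermo":
        db, mfe = _fold_engine.thermo_fold(rna)
    elif backend == "reference":
        db, mfe = _fold_engine.nussinov_fold(rna)
    elif backend == "vienna":
        try:
            import RNA  # type: ignore
        except ImportError:
            raise BackendUnavailableError(
                "ViennaRNA python bindings are not installed; use backend="
                "'thermo' (bundled) or recorded fold fixtures for exact-energy "
                "tests"
            ) from None
        db, mfe = RNA.fold(rna)
        mfe = float(mfe)
    else:
        raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    return FoldResult(dotbracket=db, mfe=mfe, backend=backend)


def parse_pairs(dotbracket: str) -> list[tuple[int, int]]:
    """Base-pair list (i<j, sorted by i) from a dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(dotbracket):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def pairs_to_dotbracket(pairs: list[tuple[int, int]], length: int) -> str:
    db = ["."] * length
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def gc_percent(seq: str) -> float:
    """100*(G+C)/length; N counts in the denominator only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class HairpinMetrics:
    n_bp: int
    stem_len: int
    n_hairpin_loops: int
    n_stems: int
    terminal_loop_len: int
    gc_percent: float
    mfe: float


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Maximal runs of exactly stacked pairs."""
    helices: list[list[tuple[int, int]]] = []
    pair_set = set(pairs)
    for i, j in pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # not a helix start
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pair_set:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        helices.append(run)
    return helices


def _merge_stems(
    helices: list[list[tuple[int, int]]], max_bridge: int = 3
) -> list[list[list[tuple[int, int]]]]:
    """Merge directly nested helices separated by <= max_bridge unpaired nt
    on both strands into stems (bulges/internal loops bridged)."""
    stems: list[list[list[tuple[int, int]]]] = []
    used = [False] * len(helices)
    # index helices by outermost pair for nesting lookup
    for idx, h in enumerate(helices):
        if used[idx]:
            continue
        stem = [h]
        used[idx] = True
        while True:
            a, b = stem[-1][-1]  # innermost pair of current stem
            nxt = None
            for jdx, h2 in enumerate(helices):
                if used[jdx]:
                    continue
                c, d = h2[0]
                if a < c and d < b and (c - a - 1) <= max_bridge and (b - d - 1) <= max_bridge:
                    nxt = jdx
                    break
            if nxt is None:
                break
            stem.append(helices[nxt])
            used[nxt] = True
        stems.append(stem)
    return stems


def hairpin_metrics(seq: str, fold_result: FoldResult) -> HairpinMetrics:
    """Topology metrics of a fold.

    A *helix* is a maximal run of stacked pairs; a *stem* merges directly
    nested helices with at most 3 intervening unpaired nt on either strand.
    ``stem_len`` counts base pairs in the longest stem.  The terminal loop
    length is the hairpin-loop size closing the longest stem (0 when that
    stem ends in a multiloop).
    """
    if len(seq) != len(fold_result.dotbracket):
        raise ValueError("fold does not match sequence length")
    pairs = parse_pairs(fold_result.dotbracket)
    n_bp = len(pairs)
    paired = set()
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
    hairpin_loops = [
        (i, j)
        for i, j in pairs
        if not any(p in paired for p in range(i + 1, j))
    ]
    helices = _helices(pairs)
    stems = _merge_stems(helices)
    stem_sizes = [sum(len(h) for h in stem) for stem in stems]
    if stems:
        best = max(range(len(stems)), key=lambda s: stem_sizes[s])
        stem_len = stem_sizes[best]
        a, b = stems[best][-1][-1]  # innermost pair of the longest stem
        terminal = next(((i, j) for i, j in hairpin_loops if (i, j) == (a, b)), None)
        terminal_loop_len = (terminal[1] - terminal[0] - 1) if terminal else 0
    else:
        stem_len = 0
        terminal_loop_len = 0
    return HairpinMetrics(
        n_bp=n_bp,
        stem_len=stem_len,
        n_hairpin_loops=len(hairpin_loops),
        n_stems=len(helices),
        terminal_loop_len=terminal_loop_len,
        gc_percent=gc_percent(seq),
        mfe=fold_result.mfe,
    )


@dataclass(frozen=True)
class FilterConfig:
    """Pseudo-hairpin removal thresholds (all ranges inclusive)."""

    stem_min: int = 20
    stem_max: int = 50
    gc_min: float = 24.0
    gc_max: float = 82.0
    mfe_min: float = -60.0
    mfe_max: float = -20.0
    require_single_hairpin: bool = True

    def __post_init__(self) -> None:
        if self.stem_min > self.stem_max:
            raise ValueError("stem_min > stem_max")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min > gc_max")
        if self.mfe_min > self.mfe_max:
            raise ValueError("mfe_min > mfe_max")


def passes_filter(
    metrics: HairpinMetrics, cfg: FilterConfig | None = None
) -> tuple[bool, list[str]]:
    """Apply the pseudo-hairpin filter; returns (pass, failed criteria)."""
    cfg = cfg or FilterConfig()
    failed: list[str] = []
    if not (cfg.stem_min <= metrics.stem_len <= cfg.stem_max):
        failed.append("stem")
    if not (cfg.gc_min <= metrics.gc_percent <= cfg.gc_max):
        failed.append("gc")
    if not (cfg.mfe_min <= metrics.mfe <= cfg.mfe_max):
        failed.append("mfe")
    if cfg.require_single_hairpin and metrics.n_hairpin_loops != 1:
        failed.append("single_hairpin")
    return (not failed, failed)


@dataclass
class HairpinCandidate:
    """A candidate window with its fold, metrics and genomic provenance."""

    id: str
    seq: str
    fold: FoldResult
    metrics: HairpinMetrics
    origin: GenomicInterval | None = None
    mature_anchor: GenomicInterval | None = None
    extras: dict = field(default_factory=dict)


def load_fold_fixtures(path) -> list[tuple[str, str, str, float]]:
    """Read a fold-fixture TSV of (id, seq, dotbracket, mfe) rows."""
    rows: list[tuple[str, str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, seq, db, mfe = line.split("\t")
            rows.append((rid, seq, db, float(mfe)))
    return rows
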