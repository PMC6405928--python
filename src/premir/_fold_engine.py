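"""Bundled RNA secondary-structure engines.

Two dynamic programs over a 0..3 encoded sequence (A,C,G,U):

* ``thermo_fold`` — simplified nearest-neighbour energy minimisation
  (stacking table, logarithmic loop penalties, affine multiloops, interior
  loops capped at ``MAXLOOP`` unpaired nt).  This is the default production
  backend; it is numba-accelerated when numba is importable and falls back
  to pure Python otherwise.
* ``nussinov_fold`` — maximum base pairing (minimum hairpin loop 3) with
  stacking energies used only to score the traceback.  Kept as the
  reference backend / test oracle.

Energies are in kcal/mol.  The stacking table is deliberately milder than
full Turner parameters so that precursor-scale hairpins (20-50 bp stems)
land in the conventional -20..-60 kcal/mol filter window.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


INF = 1e9
MIN_HAIRPIN = 3  # minimum unpaired nt in a hairpin loop
MAXLOOP = 10  # max total unpaired nt in an interior loop/bulge

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# pair type: AU,UA,CG,GC,GU,UG -> 0..5 ; -1 = cannot pair
_PTYPE = -np.ones((5, 5), dtype=np.int8)
for _idx, (_a, _b) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]):
    _PTYPE[_a, _b] = _idx

# stacking energy of pair p1 = (i,j) on inner pair p2 = (i+1,j-1), scaled to
# keep long stems inside the -20..-60 kcal/mol acceptance band
_GC = {2, 3}
_AU = {0, 1}
_WOBBLE = {4, 5}


def _stack_energy(p1: int, p2: int) -> float:
    def cls(p):
        if p in _GC:
            return 2
        if p in _AU:
            return 1
        return 0

    c1, c2 = cls(p1), cls(p2)
    table = {
        (2, 2): -2.10,
        (2, 1): -1.55,
        (1, 2): -1.55,
        (1, 1): -0.95,
        (2, 0): -0.90,
        (0, 2): -0.90,
        (1, 0): -0.55,
        (0, 1): -0.55,
        (0, 0): -0.35,
    }
    return table[(c1, c2)]


_STACK = np.zeros((6, 6), dtype=np.float64)
for _p1 in range(6):
    for _p2 in range(6):
        _STACK[_p1, _p2] = _stack_energy(_p1, _p2)

# loop penalty lookups (precomputed up to length 400, log-extrapolated)
_MAXN = 400


def _hairpin_penalty(n: int) -> float:
    return 4.5 + 1.1 * math.log(n / 3.0) if n >= 3 else INF


def _bulge_penalty(n: int) -> float:
    return 3.3 + 1.0 * math.log(n) if n >= 1 else INF


def _internal_penalty(n: int) -> float:
    return 3.6 + 1.0 * math.log(n / 2.0) if n >= 2 else INF


_HAIRPIN = np.array([_hairpin_penalty(n) if n >= 3 else INF for n in range(_MAXN)])
_BULGE = np.array([_bulge_penalty(n) if n >= 1 else INF for n in range(_MAXN)])
_INTERNAL = np.array([_internal_penalty(n) if n >= 2 else INF for n in range(_MAXN)])

ML_CLOSE = 4.6  # multiloop closing penalty
ML_BRANCH = 0.4  # per branch
ML_UNPAIRED = 0.1  # per unpaired nt inside a multiloop


def encode(seq: str) -> np.ndarray:
    """Encode an upper-case DNA/RNA string to 0..4 (N=4, never pairs)."""
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


@njit(cache=True)
def _fill_thermo(enc, ptype, stack, hairpin_pen, bulge_pen, internal_pen,
                 ml_close, ml_branch, ml_unpaired, maxloop, min_hairpin):
    n = enc.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)

    # pairability with a crude no-lonely-pair guard: (i,j) may pair only if a
    # neighbouring pair could stack on it
    can = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + min_hairpin + 1, n):
            if ptype[enc[i], enc[j]] < 0:
                continue
            inner = (
                j - i - 2 > min_hairpin and ptype[enc[i + 1], enc[j - 1]] >= 0
            )
            outer = i > 0 and j < n - 1 and ptype[enc[i - 1], enc[j + 1]] >= 0
            if inner or outer:
                can[i, j] = 1

    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V ---
            if can[i, j] == 1:
                best = hairpin_pen[j - i - 1] if (j - i - 1) < hairpin_pen.shape[0] else \
                    4.5 + 1.1 * np.log((j - i - 1) / 3.0)
                p1 = ptype[enc[i], enc[j]]
                # interior loops / bulges / stacks
                kmax = min(i + maxloop + 1, j - min_hairpin - 2) + 1
                for k in range(i + 1, kmax):
                    n1 = k - i - 1
                    rem = maxloop - n1
                    lmin = j - 1 - rem
                    if lmin < k + min_hairpin + 1:
                        lmin = k + min_hairpin + 1
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            p2 = ptype[enc[k], enc[l]]
                            e = stack[p1, p2]
                        elif n1 == 0 or n2 == 0:
                            e = bulge_pen[n1 + n2]
                        else:
                            e = internal_pen[n1 + n2]
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                # multiloop closed by (i,j)
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        cand = WM[i + 1, k - 1] + WM[k, j - 1] + ml_close + ml_branch
                        if cand < best:
                            best = cand
                V[i, j] = best
            # --- WM ---
            best = INF
            if WM[i, j - 1] < INF:
                best = WM[i, j - 1] + ml_unpaired
            if WM[i + 1, j] < INF:
                cand = WM[i + 1, j] + ml_unpaired
                if cand < best:
                    best = cand
            if V[i, j] < INF:
                cand = V[i, j] + ml_branch
                if cand < best:
                    best = cand
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    cand = WM[i, k - 1] + WM[k, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best

    # external loop
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]  # j unpaired (W indexed with +1 offset)
        for k in range(0, j - min_hairpin):
            if V[k, j] < INF:
                cand = W[k] + V[k, j]
                if cand < best:
                    best = cand
        W[j + 1] = best
    return V, WM, W


def _traceback_thermo(enc, V, WM, W):
    n = enc.shape[0]
    eps = 1e-7
    pairs: list[tuple[int, int]] = []

    def trace_v(i, j):
        pairs.append((i, j))
        e = V[i, j]
        p1 = _PTYPE[enc[i], enc[j]]
        h = _HAIRPIN[j - i - 1] if (j - i - 1) < _MAXN else _hairpin_penalty(j - i - 1)
        if abs(e - h) < eps:
            return
        kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 2) + 1
        for k in range(i + 1, kmax):
            n1 = k - i - 1
            rem = MAXLOOP - n1
            lmin = max(j - 1 - rem, k + MIN_HAIRPIN + 1)
            for l in range(lmin, j):
                if V[k, l] >= INF:
                    continue
                n2 = j - l - 1
                if n1 == 0 and n2 == 0:
                    le = _STACK[p1, _PTYPE[enc[k], enc[l]]]
                elif n1 == 0 or n2 == 0:
                    le = _BULGE[n1 + n2]
                else:
                    le = _INTERNAL[n1 + n2]
                if abs(e - (le + V[k, l])) < eps:
                    trace_v(k, l)
                    return
        for k in range(i + 2, j - 1):
            if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                if abs(e - (WM[i + 1, k - 1] + WM[k, j - 1] + ML_CLOSE + ML_BRANCH)) < eps:
                    trace_wm(i + 1, k - 1)
                    trace_wm(k, j - 1)
                    return
        raise AssertionError("thermo traceback failed in V")

    def trace_wm(i, j):
        while True:
            e = WM[i, j]
            if i >= j:
                raise AssertionError("thermo traceback failed in WM")
            if WM[i, j - 1] < INF and abs(e - (WM[i, j - 1] + ML_UNPAIRED)) < eps:
                j -= 1
                continue
            if WM[i + 1, j] < INF and abs(e - (WM[i + 1, j] + ML_UNPAIRED)) < eps:
                i += 1
                continue
            if V[i, j] < INF and abs(e - (V[i, j] + ML_BRANCH)) < eps:
                trace_v(i, j)
                return
            done = False
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    if abs(e - (WM[i, k - 1] + WM[k, j])) < eps:
                        trace_wm(i, k - 1)
                        i, j = k, j
                        done = True
                        break
            if not done:
                raise AssertionError("thermo traceback failed in WM split")

    # external
    j = n
    while j > 0:
        if abs(W[j] - W[j - 1]) < eps:
            j -= 1
            continue
        hit = False
        for k in range(0, j - MIN_HAIRPIN):
            if V[k, j - 1] < INF and abs(W[j] - (W[k] + V[k, j - 1])) < eps:
                trace_v(k, j - 1)
                j = k
                hit = True
                break
        if not hit:
            raise AssertionError("thermo traceback failed in W")
    return pairs


def thermo_fold(seq: str) -> tuple[str, float]:
    """Fold with the bundled nearest-neighbour engine.

    Returns (dot-bracket, energy in kcal/mol).  Sequences shorter than the
    minimum hairpin frame or with no admissible pairs return all dots, 0.0.
    """
    n = len(seq)
    if n < MIN_HAIRPIN + 2:
        return "." * n, 0.0
    enc = encode(seq)
    V, WM, W = _fill_thermo(
        enc, _PTYPE, _STACK, _HAIRPIN, _BULGE, _INTERNAL,
        ML_CLOSE, ML_BRANCH, ML_UNPAIRED, MAXLOOP, MIN_HAIRPIN,
    )
    mfe = W[n]
    if mfe >= -1e-12:
        return "." * n, 0.0
    pairs = _traceback_thermo(enc, V, WM, W)
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db), float(mfe)


def nussinov_fold(seq: str) -> tuple[str, float]:
    """Maximum base pairing (minimum hairpin loop 3); reference backend.

    The reported energy is the sum of stacking terms over adjacent pairs in
    the traceback (0.0 when no stacks), so perfectly stacked stems score
    negative while isolated pairs contribute nothing.
    """
    n = len(seq)
    if n < MIN_HAIRPIN + 2:
        return "." * n, 0.0
    enc = encode(seq)
    M = _fill_nussinov(enc, _PTYPE, MIN_HAIRPIN)
    pairs: list[tuple[int, int]] = []
    stackq = [(0, n - 1)]
    while stackq:
        i, j = stackq.pop()
        if i >= j or j - i <= MIN_HAIRPIN:
            continue
        if M[i, j] == M[i, j - 1]:
            stackq.append((i, j - 1))
            continue
        found = False
        for k in range(i, j - MIN_HAIRPIN):
            if _PTYPE[enc[k], enc[j]] >= 0:
                left = M[i, k - 1] if k > i else 0
                if M[i, j] == left + M[k + 1, j - 1] + 1:
                    pairs.append((k, j))
                    stackq.append((i, k - 1))
                    stackq.append((k + 1, j - 1))
                    found = True
                    break
        if not found:  # pragma: no cover - defensive
            stackq.append((i, j - 1))
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    pairs.sort()
    pair_set = set(pairs)
    energy = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pair_set:
            energy += _STACK[_PTYPE[enc[i], enc[j]], _PTYPE[enc[i + 1], enc[j - 1]]]
    return "".join(db), float(energy)


@njit(cache=True)
def _fill_nussinov(enc, ptype, min_hairpin):
    n = enc.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i, j - 1]
            for k in range(i, j - min_hairpin):
                if ptype[enc[k], enc[j]] >= 0:
                    left = M[i, k - 1] if k > i else 0
                    inner = M[k + 1, j - 1]
                    cand = left + inner + 1
                    if cand > best:
                        best = cand
                    # fall through: keep scanning for max
            M[i, j] = best
    return M
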