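"""Low-level array kernels for cluster classification.

The greedy strand-break pairing rule lives here in a flat, batch form so the
same code path serves single clusters, multi-million cluster populations and
the calibration geometry tables.  When numba is importable the batch kernel
is JIT-compiled; otherwise a pure-Python fallback (identical code) is used.
"""

from __future__ import annotations

import numpy as np

# damage-class codes (order matches the conventional yield-table columns)
EMPTY = 0
BD = 1
SSB = 2
SSBP = 3  # SSB+
SSB2 = 4  # 2SSB
DSB = 5
DSBP = 6  # DSB+
DSBPP = 7  # DSB++

CLASS_NAMES = ("EMPTY", "BD", "SSB", "SSB+", "2SSB", "DSB", "DSB+", "DSB++")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _classify_flat(positions, strands, is_break, offsets, max_pair_bp, out):
    """Classify each cluster of a flat lesion population.

    ``positions``/``strands``/``is_break`` are parallel lesion arrays sorted
    by (cluster, position, strand); ``offsets[c]:offsets[c+1]`` delimits
    cluster ``c``.  Writes a class code per cluster into ``out``.
    """
    for c in range(offsets.size - 1):
        i0 = offsets[c]
        i1 = offsets[c + 1]
        n = i1 - i0
        if n == 0:
            out[c] = EMPTY
            continue
        b = 0
        for i in range(i0, i1):
            if is_break[i]:
                b += 1
        if b == 0:
            out[c] = BD
            continue
        if b == 1:
            out[c] = SSB
            continue
        bpos = np.empty(b, dtype=np.int64)
        bstr = np.empty(b, dtype=np.int64)
        k = 0
        for i in range(i0, i1):
            if is_break[i]:
                bpos[k] = positions[i]
                bstr[k] = strands[i]
                k += 1
        paired = np.zeros(b, dtype=np.bool_)
        d = 0
        for i in range(b):
            if paired[i]:
                continue
            best = -1
            best_dist = max_pair_bp + 1
            best_pos = 0
            for j in range(b):
                if j == i or paired[j] or bstr[j] == bstr[i]:
                    continue
                dist = bpos[j] - bpos[i]
                if dist < 0:
                    dist = -dist
                if dist > max_pair_bp:
                    continue
                # nearest partner; ties broken toward the leftmost one
                if dist < best_dist or (dist == best_dist and bpos[j] < best_pos):
                    best = j
                    best_dist = dist
                    best_pos = bpos[j]
            if best >= 0:
                paired[i] = True
                paired[best] = True
                d += 1
        if d >= 2:
            out[c] = DSBPP
        elif d == 1:
            leftover = b - 2 * d
            out[c] = DSBP if leftover > 0 else DSB
        else:
            both = False
            for i in range(1, b):
                if bstr[i] != bstr[0]:
                    both = True
                    break
            out[c] = SSB2 if both else SSBP
    return out


def classify_flat(positions, strands, is_break, offsets, max_pair_bp=10):
    """Vectorised cluster classification over a flat lesion layout."""
    out = np.empty(offsets.size - 1, dtype=np.int8)
    _classify_flat(
        np.ascontiguousarray(positions, dtype=np.int64),
        np.ascontiguousarray(strands, dtype=np.int64),
        np.ascontiguousarray(is_break, dtype=np.bool_),
        np.ascontiguousarray(offsets, dtype=np.int64),
        max_pair_bp,
        out,
    )
    return out


def classify_breaks_batch(positions, strands, max_pair_bp=10):
    """Classify ``(n, b)`` arrays of break-only clusters (b >= 1 each)."""
    n, b = positions.shape
    flat_pos = positions.reshape(-1)
    flat_str = strands.reshape(-1)
    order = np.lexsort(
        (flat_str, flat_pos, np.repeat(np.arange(n), b))
    )
    offsets = np.arange(0, n * b + 1, b, dtype=np.int64)
    return classify_flat(
        flat_pos[order],
        flat_str[order],
        np.ones(n * b, dtype=bool),
        offsets,
        max_pair_bp,
    )
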