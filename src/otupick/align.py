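"""Pairwise percent identity under semi-global (free end gap) alignment.

Greedy OTU clustering needs one primitive: the percent identity between a
read and a candidate centroid. The convention used throughout this package
is

* semi-global alignment: gaps before the first aligned column and after the
  last aligned column are free on both sequences;
* the alignment maximises ``matches - gaps`` (match +1, mismatch 0, gap -1,
  linear gap cost), which prefers a substitution over an insertion/deletion
  pair and never pads the alignment with cost-free columns;
* identity = matched columns / alignment columns, where terminal gap columns
  are excluded and ``N`` aligns like any base but never counts as a match.

Ties between equal-scoring alignments are broken deterministically
(diagonal > up > left during traceback, first-best end cell), and the pair
is canonically ordered before alignment so that identity is exactly
symmetric in its two arguments.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode", "pairwise_identity", "identity_statistics"]

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i
    _LUT[_c + 32] = _i
_LUT[ord("N")] = 4
_LUT[ord("n")] = 4

#: code for the ambiguous base N; aligns but never matches
N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string over {A,C,G,T,N} (any case) as a uint8 array."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size == 0:
        raise ValueError("cannot align an empty sequence")
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"invalid DNA character {bad!r}")
    return arr


@njit(cache=False)
def _semi_global(a, b):  # pragma: no cover - exercised via pairwise_identity
    """Return (matches, columns) of the optimal free-end-gap alignment.

    Score: match +1, mismatch 0, gap -1; leading/trailing gaps free.
    Traceback prefers diagonal, then up (gap in b), then left (gap in a).
    """
    m = a.shape[0]
    n = b.shape[0]
    score = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        ai = a[i - 1]
        row = score[i]
        prev = score[i - 1]
        for j in range(1, n + 1):
            s = 1 if (ai == b[j - 1] and ai != 4) else 0
            best = prev[j - 1] + s
            up = prev[j] - 1
            if up > best:
                best = up
            left = row[j - 1] - 1
            if left > best:
                best = left
            row[j] = best

    # best end cell over last row then last column; first best kept
    ei = m
    ej = 0
    bs = score[m, 0]
    for j in range(1, n + 1):
        if score[m, j] > bs:
            bs = score[m, j]
            ei = m
            ej = j
    for i in range(0, m + 1):
        if score[i, n] > bs:
            bs = score[i, n]
            ei = i
            ej = n

    matches = 0
    columns = 0
    i = ei
    j = ej
    while i > 0 and j > 0:
        s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else 0
        if score[i, j] == score[i - 1, j - 1] + s:
            matches += s
            columns += 1
            i -= 1
            j -= 1
        elif score[i, j] == score[i - 1, j] - 1:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return matches, columns


def identity_statistics(a, b) -> tuple[int, int]:
    """(matches, columns) for the canonical alignment of two sequences.

    Accepts strings or uint8-encoded arrays. The pair is ordered
    canonically first, so the result is symmetric.
    """
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    # canonical order => exact symmetry regardless of traceback tie-breaks
    ka = ea.tobytes()
    kb = eb.tobytes()
    if (len(ka), ka) > (len(kb), kb):
        ea, eb = eb, ea
    m, c = _semi_global(ea, eb)
    return int(m), int(c)


def pairwise_identity(a, b) -> float:
    """Percent identity (0..1) between two sequences or SequenceRecords."""
    sa = a.seq if hasattr(a, "seq") else a
    sb = b.seq if hasattr(b, "seq") else b
    m, c = identity_statistics(sa, sb)
    if c == 0:
        return 0.0
    return m / c
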