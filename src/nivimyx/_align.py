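"""Numba kernel for free-end-gap global alignment identity.

Scoring: match +1, mismatch 0, internal gap -1 per column; terminal gaps
are free (zero first DP row/column, best cell taken over the last row and
column) and excluded from the aligned length. Among score-optimal
alignments the one with the most matches and then the fewest columns is
reported, which makes the (matches, aligned_length) pair symmetric in the
argument order: the lexicographic optimum of (score, matches, -columns) is
invariant under transposing the DP. No traceback is needed - the triple is
propagated directly.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# Base codes: A,C,G,T -> 0..3; every IUPAC ambiguity code -> >=4 and never a
# match, even against itself (conservative for Sanger barcodes).
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
for _j, _c in enumerate("RYSWKMBDHVN"):
    _CODE[ord(_c)] = 4 + _j

GAP = -1  # linear, per internal gap column


@njit(cache=True)
def _nw_counts(x, y):  # pragma: no cover - exercised via nw_identity
    """(matches, aligned_columns) of the optimal free-end-gap alignment."""
    la = x.shape[0]
    lb = y.shape[0]
    # per-cell lexicographic optimum (score, matches, -columns) over all
    # paths entering from the free boundary
    hs = np.zeros((la + 1, lb + 1), dtype=np.int32)
    hm = np.zeros((la + 1, lb + 1), dtype=np.int32)
    hc = np.zeros((la + 1, lb + 1), dtype=np.int32)
    for i in range(1, la + 1):
        xi = x[i - 1]
        for j in range(1, lb + 1):
            m = 1 if (xi == y[j - 1] and xi < 4) else 0
            bs = hs[i - 1, j - 1] + m
            bm = hm[i - 1, j - 1] + m
            bc = hc[i - 1, j - 1] - 1
            s = hs[i - 1, j] + GAP
            mm = hm[i - 1, j]
            c = hc[i - 1, j] - 1
            if s > bs or (s == bs and (mm > bm or (mm == bm and c > bc))):
                bs, bm, bc = s, mm, c
            s = hs[i, j - 1] + GAP
            mm = hm[i, j - 1]
            c = hc[i, j - 1] - 1
            if s > bs or (s == bs and (mm > bm or (mm == bm and c > bc))):
                bs, bm, bc = s, mm, c
            hs[i, j] = bs
            hm[i, j] = bm
            hc[i, j] = bc
    # best end cell over the last row and column (free terminal gaps)
    bs, bm, bc = hs[la, lb], hm[la, lb], hc[la, lb]
    for i in range(1, la):
        s, mm, c = hs[i, lb], hm[i, lb], hc[i, lb]
        if s > bs or (s == bs and (mm > bm or (mm == bm and c > bc))):
            bs, bm, bc = s, mm, c
    for j in range(1, lb):
        s, mm, c = hs[la, j], hm[la, j], hc[la, j]
        if s > bs or (s == bs and (mm > bm or (mm == bm and c > bc))):
            bs, bm, bc = s, mm, c
    return bm, -bc


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase IUPAC DNA string; raises on other characters."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({seq[k] for k in np.nonzero(arr < 0)[0]})
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return arr.astype(np.int8)


def nw_identity(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """(matches, aligned_columns) between two encoded sequences."""
    m, c = _nw_counts(x, y)
    return int(m), int(c)
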