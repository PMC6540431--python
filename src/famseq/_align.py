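"""Numba-compiled dynamic-programming kernels for pairwise alignment.

Two kernels live here:

* a Gotoh local aligner with affine gaps over an arbitrary integer-encoded
  alphabet and substitution matrix (used by the translated homology search);
* a global match-count recurrence with unit match scoring (used by the
  clustering identity measure).

Tie-breaking in the local aligner is deterministic: among equal-scoring
cells the one with the lowest subject end, then lowest query end wins, and
the traceback prefers diagonal moves over gaps.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from Bio.Align import substitution_matrices

# BLOSUM62 alphabet order as shipped by biopython: "ARNDCQEGHILKMFPSTWYVBZX*"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
BLOSUM62_ALPHABET: str = "".join(_BLOSUM62.alphabet)
BLOSUM62: np.ndarray = np.asarray(_BLOSUM62, dtype=np.int64)

_AA_CODE = np.full(128, BLOSUM62_ALPHABET.index("X"), dtype=np.int64)
for _i, _c in enumerate(BLOSUM62_ALPHABET):
    _AA_CODE[ord(_c)] = _i

_NT_CODE = np.full(128, 4, dtype=np.int64)  # 4 == N / anything else
for _i, _c in enumerate("ACGT"):
    _NT_CODE[ord(_c)] = _i


def encode_aa(seq: str) -> np.ndarray:
    """Encode a peptide as BLOSUM62 row indices; unknown letters map to X."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)
    return _AA_CODE[arr]


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as {A,C,G,T}->0..3, anything else->4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)
    return _NT_CODE[arr]


@njit(cache=True)
def sw_affine(q, s, matrix, gap_open, gap_extend):  # pragma: no cover - jit
    """Optimal local alignment score and end cell under affine gaps.

    Gap of length L costs gap_open + L * gap_extend. Returns
    (score, q_end, s_end) where the ends are exclusive (half-open) and the
    earliest (lowest s_end, then lowest q_end) maximal cell is reported.
    """
    m, n = len(q), len(s)
    NEG = -10_000_000
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    best_i = 0
    best_j = 0
    for j in range(1, n + 1):
        diag = 0  # H[i-1][j-1]
        F = NEG
        sj = s[j - 1]
        for i in range(1, m + 1):
            E[i] = max(E[i] - gap_extend, H[i] - gap_open - gap_extend)
            F = max(F - gap_extend, H[i - 1] - gap_open - gap_extend)
            h = diag + matrix[q[i - 1], sj]
            if E[i] > h:
                h = E[i]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[i]
            H[i] = h
            if h > best:
                best = h
                best_i = i
                best_j = j
    return best, best_i, best_j


@njit(cache=True)
def sw_affine_traceback(q, s, matrix, gap_open, gap_extend, end_i, end_j):  # pragma: no cover - jit
    """Recompute the DP over the prefix and trace the winning local path.

    Returns (q_start, s_start, matches, columns): half-open starts of the
    alignment ending at (end_i, end_j), the number of identity columns and
    the total alignment columns (including gap columns).
    """
    m, n = end_i, end_j
    NEG = -10_000_000
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open - gap_extend)
            h = H[i - 1, j - 1] + matrix[q[i - 1], s[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
    i, j = m, n
    matches = 0
    columns = 0
    state = 0  # 0 = H, 1 = E (gap in query), 2 = F (gap in subject)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + matrix[q[i - 1], s[j - 1]]
            if H[i, j] == diag:
                if q[i - 1] == s[j - 1]:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
    return i, j, matches, columns


_NW_BASE = np.int64(1) << np.int64(24)


@njit(cache=True)
def global_match_count(a, b):  # pragma: no cover - jit
    """Identity columns in the optimal end-gap-free global alignment.

    Unit scoring: match +1, mismatch -1, internal gap -2; terminal gaps on
    either sequence are free (dovetail convention), so a short sequence is
    compared against its best contiguous placement in a longer one instead
    of being threaded through it. Among co-optimal alignments the one with
    the most identity columns is counted, which is well defined because
    both objectives are additive along a path (score and match count are
    packed lexicographically into one integer per cell).
    """
    m, n = len(a), len(b)
    B = _NW_BASE  # packs value = score * B + matches, 0 <= matches < B
    GAP = 2 * B
    prev = np.zeros(n + 1, dtype=np.int64)  # free leading gaps
    cur = np.zeros(n + 1, dtype=np.int64)
    v = prev[n]  # covers the m == 0 edge and the last column at i == 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        cur[0] = 0  # free leading gaps in `a`
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                best = prev[j - 1] + B + 1
            else:
                best = prev[j - 1] - B
            up = prev[j] - GAP
            left = cur[j - 1] - GAP
            if up > best:
                best = up
            if left > best:
                best = left
            cur[j] = best
        if cur[n] > v:  # free trailing gaps in `a`: last column
            v = cur[n]
        prev, cur = cur, prev
    for j in range(n + 1):  # free trailing gaps in `b`: last row
        if prev[j] > v:
            v = prev[j]
    return v - B * (v // B)
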